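"""Y-STR haplotype comparison and the false-paternity exposure model.

Patrilineal relatives share a Y-chromosome STR haplotype up to stepwise
mutation — unless a false-paternity event broke the recorded line.  This
module compares haplotypes locus by locus, partitions a putative patriline
into a consistent core and excluded outliers (haplogroup discordance takes
precedence over STR distance), and computes the probability that at least
one false paternity occurred across ``m`` recorded father-son links,
``1 - (1 - r)**m``, which is itself the evidence LR when the remains' Y does
not match the patriline (the haplotype's population frequency is the same
under both hypotheses and cancels).
"""

from __future__ import annotations

import csv
import io
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .errors import PanelError, PartitionConfigError, ValidationError


@dataclass(frozen=True)
class StrPanel:
    """Ordered STR locus panel; multi-copy loci carry a multiset of alleles."""

    loci: tuple[str, ...]
    multi_copy: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.loci) != len(set(self.loci)):
            raise PanelError("duplicate locus names in panel")
        if not self.multi_copy <= set(self.loci):
            raise PanelError("multi_copy loci must be a subset of the panel loci")


#: The 23-locus PowerPlex Y23 panel (DYS385 is a two-copy locus).
POWERPLEX_Y23 = StrPanel(
    loci=(
        "DYS576", "DYS389I", "DYS448", "DYS389II", "DYS19", "DYS391",
        "DYS481", "DYS549", "DYS533", "DYS438", "DYS437", "DYS570",
        "DYS635", "DYS390", "DYS439", "DYS392", "DYS643", "DYS393",
        "DYS458", "DYS385", "DYS456", "YGATAH4",
    ),
    multi_copy=frozenset({"DYS385"}),
)

Allele = float
AlleleValue = "Allele | tuple[Allele, ...]"  # single copy vs multiset


def _normalise_allele(locus: str, value, panel: StrPanel):
    """Validate and normalise one allele cell; multisets stored sorted."""
    if locus in panel.multi_copy:
        values = tuple(sorted(float(v) for v in value)) if not isinstance(value, (int, float)) else (float(value),)
        if any(v <= 0 for v in values):
            raise ValidationError(f"non-positive allele at {locus}")
        return values
    v = float(value)
    if v <= 0:
        raise ValidationError(f"non-positive allele at {locus}")
    return v


@dataclass(frozen=True)
class YstrHaplotype:
    """Locus → allele map over a panel, with an optional haplogroup label."""

    panel: StrPanel
    alleles: dict  # locus -> float, or tuple of floats for multi-copy loci
    haplogroup_label: Optional[str] = None
    id: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.alleles) - set(self.panel.loci)
        if unknown:
            raise PanelError(f"alleles at loci not in panel: {sorted(unknown)}")
        normalised = {
            locus: _normalise_allele(locus, value, self.panel)
            for locus, value in self.alleles.items()
            if value is not None
        }
        object.__setattr__(self, "alleles", normalised)

    def typed_loci(self) -> set[str]:
        return set(self.alleles)

    def clade(self) -> Optional[str]:
        """Top-level haplogroup clade token, before any hyphenated refinement.

        "R1b-U152" → "R1b"; "I-M170" → "I"; None if unlabelled.
        """
        if self.haplogroup_label is None:
            return None
        return self.haplogroup_label.split("-")[0].strip()


class ComparisonResult(NamedTuple):
    mismatch_loci: list[str]
    mismatch_count: int
    compared: int


def compare(h1: YstrHaplotype, h2: YstrHaplotype) -> ComparisonResult:
    """Per-locus comparison over the loci typed in both haplotypes.

    Multi-copy loci mismatch on multiset inequality.  Loci missing in either
    haplotype are excluded (reflected in ``compared``).
    """
    if h1.panel != h2.panel:
        raise PanelError("haplotypes are typed on different panels")
    shared = [l for l in h1.panel.loci if l in h1.alleles and l in h2.alleles]
    mismatches = [l for l in shared if h1.alleles[l] != h2.alleles[l]]
    return ComparisonResult(mismatches, len(mismatches), len(shared))


def default_max_mismatch(compared: int) -> int:
    """Patriline-consistency cap: 10% of compared loci, rounded up."""
    return math.ceil(0.10 * compared)


class PatrilinePartition(NamedTuple):
    core: set[str]
    excluded: set[str]


def partition_patriline(
    haps: Sequence[YstrHaplotype], max_mismatch: Optional[int] = None
) -> PatrilinePartition:
    """Split putative patrilinear relatives into a consistent core and outliers.

    An individual is excluded if its haplogroup clade differs from the modal
    clade (haplogroup discordance alone settles it), or if its minimum
    pairwise STR mismatch count against modal-clade members exceeds
    ``max_mismatch`` (default: 10% of compared loci, rounded up).
    Haplotypes are keyed by their ``id`` (positional index if unset).
    """
    if len(haps) < 2:
        raise ValidationError("patriline partition needs at least two haplotypes")
    keys = [h.id if h.id is not None else str(i) for i, h in enumerate(haps)]
    if len(keys) != len(set(keys)):
        raise ValidationError("duplicate haplotype ids")
    clades = [h.clade() for h in haps]
    labelled = [c for c in clades if c is not None]
    if not labelled and max_mismatch is None:
        raise PartitionConfigError(
            "no haplogroup labels present and no max_mismatch given"
        )
    modal = Counter(labelled).most_common(1)[0][0] if labelled else None

    modal_members = [
        (k, h) for k, h, c in zip(keys, haps, clades) if c == modal or c is None
    ]
    core: set[str] = set()
    excluded: set[str] = set()
    for key, hap, clade in zip(keys, haps, clades):
        if modal is not None and clade is not None and clade != modal:
            excluded.add(key)
            continue
        others = [h for k, h in modal_members if k != key]
        if not others:
            core.add(key)
            continue
        best = None
        for other in others:
            result = compare(hap, other)
            cap = max_mismatch if max_mismatch is not None else default_max_mismatch(result.compared)
            dist = result.mismatch_count - cap  # <= 0 means consistent with this member
            best = dist if best is None else min(best, dist)
        (core if best is not None and best <= 0 else excluded).add(key)
    return PatrilinePartition(core, excluded)


# -- false-paternity exposure ---------------------------------------------------

@dataclass(frozen=True)
class FalsePaternityParams:
    """Per-link false-paternity probability r over m recorded father-son links."""

    r: float
    m: int

    def __post_init__(self) -> None:
        if not 0 <= self.r <= 1:
            raise ValidationError("false-paternity rate must be in [0, 1]")
        if self.m < 0:
            raise ValidationError("link count must be >= 0")


def false_paternity_prob(params: FalsePaternityParams) -> float:
    """Probability of at least one false paternity in m links: 1 - (1-r)**m."""
    return 1.0 - (1.0 - params.r) ** params.m


def y_lr(params: FalsePaternityParams) -> float:
    """Evidence LR of a Y-chromosome *non*-match against the patriline.

    Under H1 the non-match requires at least one false paternity; under H2
    the remains' haplotype frequency appears in both likelihoods and cancels,
    leaving LR = P(>=1 false paternity) = 1 - (1-r)**m.  Applies only when a
    non-match was observed.
    """
    return false_paternity_prob(params)


# -- wide TSV IO -----------------------------------------------------------------

def parse_ystr_table(text: str, panel: StrPanel = POWERPLEX_Y23) -> list[YstrHaplotype]:
    """Read a wide Y-STR TSV: one row per sample, columns = id, [haplogroup], loci.

    Multi-copy allele cells are comma-separated ("11,14"); empty cells mean
    the locus was not typed.
    """
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None or "id" not in reader.fieldnames:
        raise ValidationError("Y-STR table must have an 'id' column")
    locus_cols = [c for c in reader.fieldnames if c not in ("id", "haplogroup")]
    unknown = set(locus_cols) - set(panel.loci)
    if unknown:
        raise PanelError(f"unknown loci in table: {sorted(unknown)}")
    haps = []
    for row in reader:
        alleles: dict = {}
        for locus in locus_cols:
            cell = (row[locus] or "").strip()
            if not cell:
                continue
            try:
                if locus in panel.multi_copy:
                    alleles[locus] = tuple(float(v) for v in cell.split(","))
                else:
                    alleles[locus] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric allele {cell!r} at {locus} for {row['id']!r}"
                ) from None
        haps.append(
            YstrHaplotype(
                panel=panel,
                alleles=alleles,
                haplogroup_label=(row.get("haplogroup") or "").strip() or None,
                id=row["id"],
            )
        )
    return haps


def read_ystr_table(path: str | Path, panel: StrPanel = POWERPLEX_Y23) -> list[YstrHaplotype]:
    return parse_ystr_table(Path(path).read_text(), panel)


def _format_allele(value) -> str:
    def one(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else str(v)

    if isinstance(value, tuple):
        return ",".join(one(v) for v in value)
    return one(value)


def ystr_table_to_text(haps: Sequence[YstrHaplotype]) -> str:
    if not haps:
        raise ValidationError("cannot serialise an empty haplotype list")
    panel = haps[0].panel
    with_hg = any(h.haplogroup_label for h in haps)
    columns = ["id"] + (["haplogroup"] if with_hg else []) + list(panel.loci)
    lines = ["\t".join(columns)]
    for i, h in enumerate(haps):
        if h.panel != panel:
            raise PanelError("haplotypes are typed on different panels")
        row = [h.id if h.id is not None else str(i)]
        if with_hg:
            row.append(h.haplogroup_label or "")
        for locus in panel.loci:
            row.append(_format_allele(h.alleles[locus]) if locus in h.alleles else "")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_ystr_table(haps: Sequence[YstrHaplotype], path: str | Path) -> None:
    Path(path).write_text(ystr_table_to_text(haps))
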