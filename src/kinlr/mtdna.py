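"""mtDNA haplotypes in rCRS coordinates, database matching and evidence LRs.

A haplotype is the set of differences from the revised Cambridge Reference
Sequence (rCRS) over declared position ranges, written in EMPOP-style tokens:
``16126C`` (substitution), ``315.1C`` (insertion), ``249DEL`` (deletion).
Insertions and deletions are opaque tokens compared by string equality;
substitution positions are checked against the declared ranges.

The evidence likelihood under "the remains are the target" (H1) is the
probability that no mutation occurred along the ``m`` meioses separating
the remains and a matrilineal relative, ``(1 - mu)**m``; under the
alternative (H2) it is the population match probability of the shared
haplotype, estimated conservatively from a reference database with a
pseudocount and the relative's own observation added so the ratio is biased
toward the neutral value 1.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from .errors import (
    DuplicatePositionError,
    MalformedTokenError,
    NoComparablePositionsError,
    PositionOutOfRangeError,
    SequenceError,
    ValidationError,
)

RCRS_LENGTH = 16_569

#: Control-region ranges used for the conservative database comparison.
DEFAULT_CONTROL_RANGES_TEXT = "16093-16320 73-188"

_SUBSTITUTION = re.compile(r"^(\d+)([ACGT])$")
_INSERTION = re.compile(r"^(\d+)\.(\d+)([ACGT])$")
_DELETION = re.compile(r"^(\d+)DEL$")

_IUPAC_OK = set("ACGTN")


@dataclass(frozen=True, order=True)
class PositionRange:
    """1-based inclusive range of rCRS positions."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= RCRS_LENGTH):
            raise ValidationError(f"invalid rCRS range {self.start}-{self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


def parse_ranges(text: str) -> tuple[PositionRange, ...]:
    """Parse a range declaration like ``"16093-16320 73-188"``."""
    ranges = []
    for chunk in text.replace(",", " ").split():
        m = re.match(r"^(\d+)-(\d+)$", chunk)
        if not m:
            raise ValidationError(f"malformed range {chunk!r}")
        ranges.append(PositionRange(int(m.group(1)), int(m.group(2))))
    if not ranges:
        raise ValidationError("empty range declaration")
    return tuple(ranges)


def ranges_to_text(ranges: Sequence[PositionRange]) -> str:
    return " ".join(str(r) for r in ranges)


def _covered(position: int, ranges: Sequence[PositionRange]) -> bool:
    return any(position in r for r in ranges)


def token_position(token: str) -> int:
    """Leading rCRS position of any token form."""
    m = re.match(r"^(\d+)", token)
    if not m:
        raise MalformedTokenError(f"malformed token {token!r}")
    return int(m.group(1))


def _validate_token(token: str) -> tuple[int, bool]:
    """Return (position, is_substitution); raise on malformed tokens."""
    if m := _SUBSTITUTION.match(token):
        return int(m.group(1)), True
    if m := _INSERTION.match(token):
        return int(m.group(1)), False
    if m := _DELETION.match(token):
        return int(m.group(1)), False
    raise MalformedTokenError(f"malformed variant token {token!r}")


@dataclass(frozen=True)
class MtHaplotype:
    """Named differences from the rCRS over declared position ranges."""

    variants: frozenset[str]
    ranges: tuple[PositionRange, ...]

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValidationError("haplotype must declare at least one range")
        object.__setattr__(self, "variants", frozenset(v.upper() for v in self.variants))
        seen_sub_positions: set[int] = set()
        for token in self.variants:
            pos, is_sub = _validate_token(token)
            if is_sub:
                if pos in seen_sub_positions:
                    raise DuplicatePositionError(f"two substitutions at position {pos}")
                seen_sub_positions.add(pos)
                if not _covered(pos, self.ranges):
                    raise PositionOutOfRangeError(
                        f"substitution {token} outside declared ranges"
                    )

    def restrict(self, ranges: Sequence[PositionRange]) -> frozenset[str]:
        """Tokens whose position falls inside ``ranges``."""
        return frozenset(v for v in self.variants if _covered(token_position(v), ranges))

    def covers(self, ranges: Sequence[PositionRange]) -> bool:
        """True if every queried range is contained in a declared range."""
        return all(
            any(q.start >= r.start and q.end <= r.end for r in self.ranges)
            for q in ranges
        )


def parse_variant_profile(text: str, ranges: Sequence[PositionRange]) -> MtHaplotype:
    """Build a haplotype from whitespace-separated EMPOP-style tokens.

    An empty string means "identical to the rCRS over the declared ranges".
    """
    tokens = frozenset(text.upper().split())
    return MtHaplotype(variants=tokens, ranges=tuple(ranges))


def profile_from_fasta(
    seq: str, reference: str, ranges: Sequence[PositionRange]
) -> MtHaplotype:
    """Substitution profile of an rCRS-aligned sequence against the reference.

    No realignment is performed: position i of ``seq`` corresponds to rCRS
    position i (1-based).  Positions where either base is N are ignored;
    ambiguity codes other than N are rejected rather than interpreted.
    """
    seq, reference = seq.upper(), reference.upper()
    if len(seq) != len(reference):
        raise SequenceError(
            f"sequence length {len(seq)} != reference length {len(reference)}"
        )
    for name, s in (("sequence", seq), ("reference", reference)):
        bad = set(s) - _IUPAC_OK
        if bad:
            raise SequenceError(f"{name} contains non-IUPAC characters {sorted(bad)}")
    tokens = set()
    for r in ranges:
        if r.end > len(seq):
            raise SequenceError(f"range {r} beyond sequence length {len(seq)}")
        for pos in range(r.start, r.end + 1):
            a, b = reference[pos - 1], seq[pos - 1]
            if a != b and a != "N" and b != "N":
                tokens.add(f"{pos}{b}")
    return MtHaplotype(variants=frozenset(tokens), ranges=tuple(ranges))


def _shared_ranges(
    r1: Sequence[PositionRange], r2: Sequence[PositionRange]
) -> tuple[PositionRange, ...]:
    shared = []
    for a in r1:
        for b in r2:
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            if lo <= hi:
                shared.append(PositionRange(lo, hi))
    return tuple(sorted(shared))


def diff(h1: MtHaplotype, h2: MtHaplotype) -> list[str]:
    """Tokens present in exactly one haplotype within the shared ranges.

    Empty list ⇔ the two haplotypes match over the comparable positions.
    Raises :class:`NoComparablePositionsError` on disjoint declared ranges.
    """
    shared = _shared_ranges(h1.ranges, h2.ranges)
    if not shared:
        raise NoComparablePositionsError("declared ranges do not overlap")
    sym = h1.restrict(shared) ^ h2.restrict(shared)
    return sorted(sym, key=lambda t: (token_position(t), t))


# -- haplotype databases -------------------------------------------------------

@dataclass
class HaplotypeDatabase:
    """Reference collection of (id, haplotype) records."""

    records: list[tuple[str, MtHaplotype]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate record ids in haplotype database")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n


class MatchCount(NamedTuple):
    """Database match count plus the number of records skipped for coverage."""

    matches: int
    skipped: int


def count_db_matches(
    db: HaplotypeDatabase, query: MtHaplotype, ranges: Sequence[PositionRange]
) -> MatchCount:
    """Count records identical to the query over ``ranges``.

    Records whose declared ranges do not cover the query ranges cannot be
    compared and are skipped (reported, not an error).
    """
    query_tokens = query.restrict(ranges)
    matches = skipped = 0
    for _, hap in db.records:
        if not hap.covers(ranges):
            skipped += 1
        elif hap.restrict(ranges) == query_tokens:
            matches += 1
    return MatchCount(matches, skipped)


def match_probability(
    k: int,
    n: int,
    add_relative: bool = True,
    pseudocount: int = 1,
) -> float:
    """Conservative population match probability from k matches among n.

    Returns ``(k + add_relative + pseudocount) / (n + add_relative)``.  The
    defaults add the matching relative's own observation to both counts and a
    single pseudocount to the numerator, so the estimate always exceeds the
    plain frequency k/n and the resulting LR is biased toward the neutral
    value 1.  A zero-match database of 1,831 gives 2/1,832.
    """
    if k < 0 or n < 0 or k > n:
        raise ValidationError(f"invalid match counts k={k}, n={n}")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    rel = 1 if add_relative else 0
    numer = k + rel + pseudocount
    denom = n + rel
    if denom == 0:
        raise ValidationError("match probability undefined on an empty database")
    return numer / denom


# -- evidence likelihoods ------------------------------------------------------

def no_mutation_prob(mu: float, m: int) -> float:
    """Probability of zero control-region mutations in m meioses: (1-mu)**m."""
    if not 0 <= mu < 1:
        raise ValidationError(f"mutation probability must be in [0, 1), got {mu}")
    if m < 0:
        raise ValidationError("meiosis count must be >= 0")
    return (1.0 - mu) ** m


@dataclass(frozen=True)
class MtEvidenceParams:
    """Inputs of the mtDNA likelihood ratio.

    mu is the per-meiosis control-region mutation probability (the Parsons
    genealogical estimate is 10 mutations in 327 transmissions, mu = 10/327);
    m the meioses separating remains and relative; p_match the conservative
    population match probability of the shared haplotype.  ``p_no_mutation``,
    when given, overrides the closed form (1-mu)**m with an externally
    supplied no-mutation probability.
    """

    mu: float
    m: int
    p_match: float
    p_no_mutation: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise ValidationError("mu must be in [0, 1)")
        if self.m < 0:
            raise ValidationError("m must be >= 0")
        if not 0 < self.p_match <= 1:
            raise ValidationError("p_match must be in (0, 1]")
        if self.p_no_mutation is not None and not 0 < self.p_no_mutation <= 1:
            raise ValidationError("p_no_mutation must be in (0, 1]")


def mtdna_lr(params: MtEvidenceParams) -> float:
    """LR of an observed mtDNA match: P(no mutation in m meioses) / P(chance match)."""
    numer = (
        params.p_no_mutation
        if params.p_no_mutation is not None
        else no_mutation_prob(params.mu, params.m)
    )
    return numer / params.p_match


def second_relative_lr() -> float:
    """LR contribution of a second matrilineal relative's near-match.

    Conditional on the sequence already shared with the first relative, the
    second relative's observation (here, a single-site difference) is equally
    likely whether or not the remains are the target, so it cancels: LR = 1.
    """
    return 1.0


# -- profile TSV IO ------------------------------------------------------------

def parse_profile_table(text: str) -> HaplotypeDatabase:
    """Read an EMPOP-style profile TSV: columns id, ranges, variants."""
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"id", "ranges", "variants"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValidationError(f"profile table must have columns {sorted(required)}")
    records = []
    for row in reader:
        ranges = parse_ranges(row["ranges"])
        records.append((row["id"], parse_variant_profile(row["variants"] or "", ranges)))
    return HaplotypeDatabase(records)


def read_profiles(path: str | Path) -> HaplotypeDatabase:
    return parse_profile_table(Path(path).read_text())


def profiles_to_text(db: HaplotypeDatabase) -> str:
    lines = ["id\tranges\tvariants"]
    for rid, hap in db.records:
        tokens = " ".join(sorted(hap.variants, key=lambda t: (token_position(t), t)))
        lines.append(f"{rid}\t{ranges_to_text(hap.ranges)}\t{tokens}")
    return "\n".join(lines) + "\n"


def write_profiles(db: HaplotypeDatabase, path: str | Path) -> None:
    Path(path).write_text(profiles_to_text(db))


def read_fasta_profile(
    path: str | Path, reference_path: str | Path, ranges: Sequence[PositionRange]
) -> MtHaplotype:
    """Profile the first record of an rCRS-aligned FASTA against a reference FASTA."""
    from Bio import SeqIO

    seq = str(next(SeqIO.parse(str(path), "fasta")).seq)
    ref = str(next(SeqIO.parse(str(reference_path), "fasta")).seq)
    return profile_from_fasta(seq, ref, ranges)
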