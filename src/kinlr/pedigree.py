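"""Genealogies and uniparental-lineage queries.

A :class:`Pedigree` is a validated, acyclic collection of individuals with
optional father/mother links.  The identification framework only ever needs
uniparental paths through it: the matriline (mother's mother's ...) along
which mtDNA is inherited, the patriline (father's father's ...) along which
the Y chromosome is inherited, and counts of meioses — parent-to-child
transmission events — separating two relatives on such a line.

Tables use a PED-like tab-separated dialect: a header row, columns
``id  father_id  mother_id  sex`` (optionally ``label  birth_year
death_year``), with ``"0"`` denoting an unknown parent.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import (
    DanglingParentError,
    DuplicateIndividualError,
    ParentSexError,
    PedigreeCycleError,
    UnknownIndividualError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_ALIASES = {
    "male": MALE, "m": MALE, "1": MALE,
    "female": FEMALE, "f": FEMALE, "2": FEMALE,
    "unknown": UNKNOWN, "u": UNKNOWN, "0": UNKNOWN, "": UNKNOWN,
}

PED_COLUMNS = ("id", "father_id", "mother_id", "sex")
PED_OPTIONAL_COLUMNS = ("label", "birth_year", "death_year")


@dataclass
class Individual:
    """One pedigree member; parent ids of ``None`` mean "not recorded"."""

    id: str
    sex: str = UNKNOWN
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    label: Optional[str] = None
    birth_year: Optional[int] = None
    death_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE, UNKNOWN):
            raise ValidationError(f"invalid sex {self.sex!r} for {self.id!r}")
        if not self.id or self.id == "0":
            raise ValidationError(f"invalid individual id {self.id!r}")


@dataclass(frozen=True)
class CousinTerms:
    """Cousin nomenclature for two co-descendants of a uniparental ancestor.

    ``degree`` counts cousinship ("14th cousins" → 14), ``removed`` counts the
    generation offset, and ``meioses`` the parent-child edges on the
    connecting path: meioses = 2*(degree + 1) + removed.
    """

    degree: int
    removed: int
    meioses: int

    def __post_init__(self) -> None:
        if self.meioses != 2 * (self.degree + 1) + self.removed:
            raise ValidationError("inconsistent cousin terms")

    def generations(self) -> tuple[int, int]:
        """Recover the (g_a, g_b) generation counts below the common ancestor."""
        g_a = self.degree + 1
        return g_a, g_a + self.removed


def cousin_terms(g_a: int, g_b: int) -> CousinTerms:
    """Cousin terminology for individuals ``g_a`` and ``g_b`` generations below
    their most recent common uniparental ancestor.

    Siblings are (1, 1): 0th-degree, not removed, 2 meioses.
    """
    if g_a < 1 or g_b < 1:
        raise ValidationError("generation counts must be >= 1")
    lo, hi = sorted((g_a, g_b))
    return CousinTerms(degree=lo - 1, removed=hi - lo, meioses=g_a + g_b)


class Pedigree:
    """Validated acyclic genealogy keyed by individual id."""

    def __init__(self, individuals: Iterable[Individual]):
        self._individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._individuals:
                raise DuplicateIndividualError(f"duplicate id {ind.id!r}")
            self._individuals[ind.id] = ind
        self._validate()

    # -- container protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._individuals)

    def __iter__(self):
        return iter(self._individuals.values())

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._individuals

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._individuals[ind_id]
        except KeyError:
            raise UnknownIndividualError(f"unknown individual {ind_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._individuals)

    # -- validation -----------------------------------------------------------

    def _validate(self) -> None:
        for ind in self:
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid is None:
                    continue
                parent = self._individuals.get(pid)
                if parent is None:
                    raise DanglingParentError(
                        f"{role} {pid!r} of {ind.id!r} is not in the pedigree"
                    )
                expected = MALE if role == "father" else FEMALE
                if parent.sex == UNKNOWN:
                    logger.warning(
                        "individual %r has unknown sex but appears as %s of %r",
                        pid, role, ind.id,
                    )
                elif parent.sex != expected:
                    raise ParentSexError(
                        f"{role} {pid!r} of {ind.id!r} is recorded as {parent.sex}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS over parent links
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i: WHITE for i in self._individuals}
        for root in self._individuals:
            if colour[root] != WHITE:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    colour[node] = BLACK
                    continue
                if colour[node] == BLACK:
                    continue
                if colour[node] == GREY:
                    raise PedigreeCycleError(f"{node!r} is its own ancestor")
                colour[node] = GREY
                stack.append((node, True))
                ind = self._individuals[node]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    if colour[pid] == GREY:
                        raise PedigreeCycleError(f"{pid!r} is its own ancestor")
                    if colour[pid] == WHITE:
                        stack.append((pid, False))

    # -- lineage queries ------------------------------------------------------

    def matriline(self, ind_id: str) -> list[str]:
        """[id, mother, mother's mother, ...] up to the recorded founder ancestress."""
        return self._lineage(ind_id, "mother_id")

    def patriline(self, ind_id: str) -> list[str]:
        """[id, father, father's father, ...] up to the recorded founder."""
        return self._lineage(ind_id, "father_id")

    def _lineage(self, ind_id: str, attr: str) -> list[str]:
        ind = self[ind_id]
        line = [ind.id]
        while getattr(ind, attr) is not None:
            ind = self[getattr(ind, attr)]
            line.append(ind.id)
        return line

    def meioses_between(self, a: str, b: str, lineage: str) -> Optional[int]:
        """Meioses separating ``a`` and ``b`` through their most recent common
        ancestor on the chosen uniparental line.

        Returns ``None`` when the two share no recorded ancestor on that line
        ("unrelated on this lineage" — a result, not an error).  When several
        common ancestors exist the most recent one (minimal total meioses) is
        used, matching cousin-naming convention.
        """
        if lineage == "matrilineal":
            la, lb = self.matriline(a), self.matriline(b)
        elif lineage == "patrilineal":
            la, lb = self.patriline(a), self.patriline(b)
        else:
            raise ValidationError(f"lineage must be matrilineal|patrilineal, got {lineage!r}")
        depth_a = {anc: d for d, anc in enumerate(la)}
        best = math.inf
        for d_b, anc in enumerate(lb):
            if anc in depth_a:
                best = min(best, depth_a[anc] + d_b)
        return None if best is math.inf else int(best)

    def matrilineal_network(self, ind_id: str) -> set[str]:
        """All individuals sharing ``ind_id``'s matrilineal founder ancestress —
        i.e. everyone who would carry the same inherited mtDNA absent mutation.
        """
        founder = self.matriline(ind_id)[-1]
        return {ind.id for ind in self if self.matriline(ind.id)[-1] == founder}


# -- PED-like TSV IO ----------------------------------------------------------

def _parse_parent(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in ("", "0") else value


def parse_pedigree(text: str) -> Pedigree:
    """Parse a PED-like TSV (header required; "0" = unknown parent)."""
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise ValidationError("empty pedigree table") from None
    header = [h.strip() for h in header]
    missing = [c for c in PED_COLUMNS if c not in header]
    if missing:
        raise ValidationError(f"missing pedigree columns: {missing}")
    idx = {c: header.index(c) for c in header}

    def get(row: list[str], col: str) -> str:
        i = idx.get(col)
        return row[i].strip() if i is not None and i < len(row) else ""

    individuals = []
    for row in reader:
        if not any(cell.strip() for cell in row):
            continue
        sex_raw = get(row, "sex").lower()
        if sex_raw not in _SEX_ALIASES:
            raise ValidationError(f"invalid sex value {sex_raw!r}")
        kwargs: dict = {}
        if "label" in idx and get(row, "label"):
            kwargs["label"] = get(row, "label")
        for col in ("birth_year", "death_year"):
            if col in idx and get(row, col):
                try:
                    kwargs[col] = int(get(row, col))
                except ValueError:
                    raise ValidationError(f"non-integer {col}: {get(row, col)!r}") from None
        individuals.append(
            Individual(
                id=get(row, "id"),
                sex=_SEX_ALIASES[sex_raw],
                father_id=_parse_parent(get(row, "father_id")),
                mother_id=_parse_parent(get(row, "mother_id")),
                **kwargs,
            )
        )
    return Pedigree(individuals)


def read_ped(path: str | Path) -> Pedigree:
    return parse_pedigree(Path(path).read_text())


def to_ped_text(p: Pedigree) -> str:
    """Serialise a pedigree; parse(to_ped_text(p)) is the identity."""
    has_opt = {
        col: any(getattr(ind, col) is not None for ind in p)
        for col in PED_OPTIONAL_COLUMNS
    }
    columns = list(PED_COLUMNS) + [c for c in PED_OPTIONAL_COLUMNS if has_opt[c]]
    lines = ["\t".join(columns)]
    for ind in p:
        row = [
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            ind.sex,
        ]
        for col in PED_OPTIONAL_COLUMNS:
            if has_opt[col]:
                value = getattr(ind, col)
                row.append("" if value is None else str(value))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def write_ped(p: Pedigree, path: str | Path) -> None:
    Path(path).write_text(to_ped_text(p))
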