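"""Synthetic identification cases with known ground truth.

Everything the identification pipeline consumes can be generated here with a
seeded random generator: pedigrees with tracked uniparental lines, mtDNA
transmitted down matrilines with a per-meiosis mutation probability,
Y-STR haplotypes transmitted down patrilines with per-link false-paternity
and stepwise mutation, and population haplotype databases drawn from a
stick-breaking frequency spectrum.  A :class:`CaseBundle` packages a complete
case — remains profiles, relatives, database, evidence configuration — plus
the truth record needed to score any downstream decision.

Model choices (documented, deliberately minimal):

* mtDNA mutation: at each meiosis, with probability ``mt_mu`` a single
  uniformly chosen in-range position changes state, the new state uniform
  over the four alternatives of {reference, A, C, G, T}.  At most one
  mutation per meiosis, matching the closed form ``(1 - mu)**m`` tested
  against it.
* False paternity: each recorded father-son link independently fails with
  probability ``fp_rate``; the biological father is then a random male from
  the contemporaneous population pool, so the event usually changes the
  haplogroup label.
* Y-STR stepwise mutation: each locus independently moves +-1 repeat with
  probability ``str_rate`` per meiosis, direction equiprobable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from . import evidence as ev
from .errors import ValidationError
from .mtdna import (
    DEFAULT_CONTROL_RANGES_TEXT,
    HaplotypeDatabase,
    MtHaplotype,
    PositionRange,
    count_db_matches,
    diff,
    match_probability,
    parse_ranges,
    profiles_to_text,
    ranges_to_text,
)
from .pedigree import FEMALE, MALE, Individual, Pedigree, to_ped_text
from .ystr import (
    POWERPLEX_Y23,
    FalsePaternityParams,
    StrPanel,
    YstrHaplotype,
    compare,
    false_paternity_prob,
    ystr_table_to_text,
)

_BASES = ("A", "C", "G", "T")
_REF_STATE = "R"  # "identical to the reference" state in the mutation model
_CLADE_POOL = ("R1b-U152", "I-M170", "G-P287", "E1b-M35", "J2-M172", "N1c-M46")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic case.

    Defaults mirror the real case: 0.009 per-link false paternity (the
    conservative genealogical rate that yields a 0.16 exposure over 19
    links), mtDNA mutation probability 10/327 per meiosis (the genealogical
    control-region estimate), a 1,831-record reference database over the
    control-region ranges 16093-16320 and 73-188, and the 23-locus PowerPlex
    Y23 panel with a 2e-3 per-locus stepwise rate.
    """

    seed: int = 0
    generations: int = 19
    mean_offspring: float = 2.0
    fp_rate: float = 0.009
    mt_mu: float = 10 / 327
    str_rate: float = 2e-3
    db_size: int = 1831
    db_alpha: float = 10.0
    panel: StrPanel = POWERPLEX_Y23
    mt_ranges: tuple[PositionRange, ...] = parse_ranges(DEFAULT_CONTROL_RANGES_TEXT)

    def __post_init__(self) -> None:
        for name in ("fp_rate", "mt_mu", "str_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.db_size < 0:
            raise ValidationError("db_size must be >= 0")
        if self.mean_offspring <= 0 or self.db_alpha <= 0:
            raise ValidationError("mean_offspring and db_alpha must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# -- population haplotype pools --------------------------------------------------


def _range_positions(ranges: Sequence[PositionRange]) -> np.ndarray:
    return np.concatenate([np.arange(r.start, r.end + 1) for r in ranges])


def stick_breaking_weights(
    rng: np.random.Generator, alpha: float, tol: float = 1e-6, max_atoms: int = 5000
) -> np.ndarray:
    """GEM stick-breaking weights with concentration ``alpha``, truncated and
    renormalised once the remaining stick is below ``tol``."""
    weights = []
    remaining = 1.0
    while remaining > tol and len(weights) < max_atoms:
        frac = rng.beta(1.0, alpha)
        weights.append(remaining * frac)
        remaining *= 1.0 - frac
    w = np.asarray(weights)
    return w / w.sum()


@dataclass
class MtPool:
    """Population spectrum of mtDNA haplotypes (atoms with true frequencies)."""

    atoms: list[MtHaplotype]
    freqs: np.ndarray

    def draw(self, rng: np.random.Generator) -> tuple[int, MtHaplotype]:
        i = int(rng.choice(len(self.atoms), p=self.freqs))
        return i, self.atoms[i]

    def true_frequency(self, hap: MtHaplotype, ranges: Sequence[PositionRange]) -> float:
        """True population probability of matching ``hap`` over ``ranges``."""
        target = hap.restrict(ranges)
        return float(
            sum(f for a, f in zip(self.atoms, self.freqs) if a.restrict(ranges) == target)
        )


@dataclass
class YPool:
    """Population spectrum of Y haplotypes with haplogroup labels."""

    atoms: list[YstrHaplotype]
    freqs: np.ndarray

    def draw(self, rng: np.random.Generator) -> tuple[int, YstrHaplotype]:
        i = int(rng.choice(len(self.atoms), p=self.freqs))
        return i, self.atoms[i]

    def true_frequency(self, hap: YstrHaplotype) -> float:
        return float(
            sum(
                f
                for a, f in zip(self.atoms, self.freqs)
                if a.alleles == hap.alleles and a.clade() == hap.clade()
            )
        )


def _random_mt_atom(
    rng: np.random.Generator, positions: np.ndarray, ranges: tuple[PositionRange, ...]
) -> MtHaplotype:
    n_var = int(rng.poisson(4.0))
    chosen = rng.choice(positions, size=min(n_var, len(positions)), replace=False)
    tokens = frozenset(
        f"{int(p)}{_BASES[int(rng.integers(4))]}" for p in np.sort(chosen)
    )
    return MtHaplotype(variants=tokens, ranges=ranges)


def _random_y_atom(rng: np.random.Generator, panel: StrPanel) -> YstrHaplotype:
    alleles: dict = {}
    for locus in panel.loci:
        base = int(rng.integers(9, 18))
        if locus in panel.multi_copy:
            alleles[locus] = (float(base), float(base + int(rng.integers(0, 5))))
        else:
            alleles[locus] = float(base)
    label = _CLADE_POOL[int(rng.integers(len(_CLADE_POOL)))]
    return YstrHaplotype(panel=panel, alleles=alleles, haplogroup_label=label)


def make_mt_pool(cfg: SimulationConfig, rng: np.random.Generator) -> MtPool:
    freqs = stick_breaking_weights(rng, cfg.db_alpha)
    positions = _range_positions(cfg.mt_ranges)
    atoms = [_random_mt_atom(rng, positions, cfg.mt_ranges) for _ in freqs]
    return MtPool(atoms, freqs)


def make_y_pool(cfg: SimulationConfig, rng: np.random.Generator) -> YPool:
    freqs = stick_breaking_weights(rng, cfg.db_alpha)
    atoms = [_random_y_atom(rng, cfg.panel) for _ in freqs]
    return YPool(atoms, freqs)


# -- pedigree simulation ----------------------------------------------------------


@dataclass
class PedigreeSim:
    """A simulated pedigree plus the generator's own record of the tracked lines."""

    pedigree: Pedigree
    matriline_ids: list[str]  # descendant-first, ending at the founder ancestress
    patriline_ids: list[str]  # descendant-first, ending at the founder patriarch
    founder_mother: str
    founder_father: str


def simulate_pedigree(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> PedigreeSim:
    """Grow a pedigree with one tracked matriline and one tracked patriline.

    ``cfg.generations`` counts parent-child transmissions along each tracked
    line: 0 gives the founder couple only; g gives tracked lines of g + 1
    individuals.  Each tracked parent also has a Poisson(mean_offspring)
    number of additional (leaf) children, and marries an unrelated founder
    spouse, so the pedigree contains branching matrilineal networks.
    """
    if rng is None:
        rng = cfg.rng()
    inds: list[Individual] = []
    father0 = Individual(id="P0", sex=MALE, label="founder patriarch")
    mother0 = Individual(id="M0", sex=FEMALE, label="founder ancestress")
    inds += [father0, mother0]
    matriline = [mother0.id]
    patriline = [father0.id]
    spouse_count = 0

    def new_spouse(sex: str) -> Individual:
        nonlocal spouse_count
        spouse_count += 1
        return Individual(id=f"S{spouse_count}", sex=sex)

    mat_parents = (father0.id, mother0.id)
    pat_parents = (father0.id, mother0.id)
    for g in range(1, cfg.generations + 1):
        # tracked daughter continues the matriline
        daughter = Individual(
            id=f"D{g}", sex=FEMALE, father_id=mat_parents[0], mother_id=mat_parents[1]
        )
        husband = new_spouse(MALE)
        # tracked son continues the patriline
        son = Individual(
            id=f"B{g}", sex=MALE, father_id=pat_parents[0], mother_id=pat_parents[1]
        )
        wife = new_spouse(FEMALE)
        inds += [daughter, husband, son, wife]
        matriline.append(daughter.id)
        patriline.append(son.id)
        # extra leaf children of each tracked couple
        for tag, parents in (("d", (husband.id, daughter.id)), ("b", (son.id, wife.id))):
            for k in range(int(rng.poisson(cfg.mean_offspring))):
                sex = MALE if rng.random() < 0.5 else FEMALE
                inds.append(
                    Individual(
                        id=f"X{tag}{g}_{k}", sex=sex,
                        father_id=parents[0], mother_id=parents[1],
                    )
                )
        mat_parents = (husband.id, daughter.id)
        pat_parents = (son.id, wife.id)

    return PedigreeSim(
        pedigree=Pedigree(inds),
        matriline_ids=list(reversed(matriline)),
        patriline_ids=list(reversed(patriline)),
        founder_mother=mother0.id,
        founder_father=father0.id,
    )


# -- marker transmission -----------------------------------------------------------


@dataclass
class TruthRecord:
    """Everything needed to score a pipeline decision against the generator."""

    seed: int
    under_h1: Optional[bool] = None
    fp_links: list[tuple[str, str]] = field(default_factory=list)  # (recorded father, child)
    mt_mutations: list[tuple[str, str, int]] = field(default_factory=list)  # (parent, child, position)
    str_mutations: list[tuple[str, str, str]] = field(default_factory=list)  # (parent, child, locus)
    founder_mt_atoms: dict = field(default_factory=dict)
    founder_y_atoms: dict = field(default_factory=dict)

    def to_json(self) -> str:
        data = asdict(self)
        return json.dumps(data, indent=2, default=str) + "\n"


def _mt_states(hap: MtHaplotype) -> dict[int, str]:
    from .mtdna import _SUBSTITUTION  # state model covers substitutions only

    states = {}
    for token in hap.variants:
        if m := _SUBSTITUTION.match(token):
            states[int(m.group(1))] = m.group(2)
    return states


def _states_to_hap(states: dict[int, str], template: MtHaplotype) -> MtHaplotype:
    # indel tokens are inherited untouched by the substitution state model
    template_subs = {f"{p}{b}" for p, b in _mt_states(template).items()}
    inherited_indels = {t for t in template.variants if t not in template_subs}
    sub_tokens = {f"{p}{b}" for p, b in states.items()}
    return MtHaplotype(
        variants=frozenset(sub_tokens | inherited_indels), ranges=template.ranges
    )


def mutate_mt_once(
    hap: MtHaplotype, rng: np.random.Generator, positions: np.ndarray
) -> tuple[MtHaplotype, int]:
    """Apply one mutation event: a uniform in-range position moves to a state
    uniform over the four alternatives of {reference, A, C, G, T}."""
    states = _mt_states(hap)
    pos = int(positions[int(rng.integers(len(positions)))])
    current = states.get(pos, _REF_STATE)
    options = [s for s in (_REF_STATE, *_BASES) if s != current]
    new = options[int(rng.integers(len(options)))]
    if new == _REF_STATE:
        states.pop(pos, None)
    else:
        states[pos] = new
    return _states_to_hap(states, hap), pos


def transmit_mt(
    hap: MtHaplotype, mu: float, rng: np.random.Generator, positions: np.ndarray
) -> tuple[MtHaplotype, Optional[int]]:
    """One meiosis of mtDNA transmission: Bernoulli(mu) single-position mutation."""
    if rng.random() < mu:
        new, pos = mutate_mt_once(hap, rng, positions)
        return new, pos
    return hap, None


def mutate_y(
    hap: YstrHaplotype, str_rate: float, rng: np.random.Generator
) -> tuple[YstrHaplotype, list[str]]:
    """One meiosis of stepwise STR mutation: each locus +-1 w.p. str_rate."""
    alleles = dict(hap.alleles)
    mutated: list[str] = []
    for locus in hap.panel.loci:
        if locus not in alleles or rng.random() >= str_rate:
            continue
        step = 1.0 if rng.random() < 0.5 else -1.0
        value = alleles[locus]
        if isinstance(value, tuple):
            copy = int(rng.integers(len(value)))
            new = list(value)
            new[copy] = max(1.0, new[copy] + step)
            alleles[locus] = tuple(sorted(new))
        else:
            alleles[locus] = max(1.0, value + step)
        mutated.append(locus)
    if not mutated:
        return hap, mutated
    return (
        YstrHaplotype(
            panel=hap.panel, alleles=alleles,
            haplogroup_label=hap.haplogroup_label, id=hap.id,
        ),
        mutated,
    )


@dataclass
class MarkerSim:
    """Per-individual marker profiles plus the transmission truth record."""

    mt: dict[str, MtHaplotype]
    y: dict[str, YstrHaplotype]
    truth: TruthRecord
    mt_pool: MtPool
    y_pool: YPool


def transmit_markers(
    p: Pedigree,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    mt_pool: Optional[MtPool] = None,
    y_pool: Optional[YPool] = None,
) -> MarkerSim:
    """Assign founder haplotypes from the population pools and transmit them.

    mtDNA follows recorded mothers (with per-meiosis mutation); the Y follows
    the recorded father with probability 1 - fp_rate, otherwise a random male
    drawn from the population pool (a false-paternity event, logged in the
    truth record), with stepwise STR mutation applied per link either way.
    """
    if rng is None:
        rng = cfg.rng()
    if mt_pool is None:
        mt_pool = make_mt_pool(cfg, rng)
    if y_pool is None:
        y_pool = make_y_pool(cfg, rng)
    positions = _range_positions(cfg.mt_ranges)
    truth = TruthRecord(seed=cfg.seed)

    # process in generation order so parents are assigned before children
    depth: dict[str, int] = {}

    def _depth(ind_id: str) -> int:
        if ind_id not in depth:
            ind0 = p[ind_id]
            parents = [q for q in (ind0.father_id, ind0.mother_id) if q is not None]
            depth[ind_id] = 1 + max((_depth(q) for q in parents), default=-1)
        return depth[ind_id]

    order = sorted(p, key=lambda ind: _depth(ind.id))
    mt: dict[str, MtHaplotype] = {}
    y: dict[str, YstrHaplotype] = {}
    for ind in order:
        # mtDNA: everyone carries it
        if ind.mother_id is None:
            atom_i, hap = mt_pool.draw(rng)
            truth.founder_mt_atoms[ind.id] = atom_i
            mt[ind.id] = hap
        else:
            hap, pos = transmit_mt(mt[ind.mother_id], cfg.mt_mu, rng, positions)
            if pos is not None:
                truth.mt_mutations.append((ind.mother_id, ind.id, pos))
            mt[ind.id] = hap
        # Y: males only
        if ind.sex != MALE:
            continue
        if ind.father_id is None:
            atom_i, yhap = y_pool.draw(rng)
            truth.founder_y_atoms[ind.id] = atom_i
        else:
            if rng.random() < cfg.fp_rate:
                truth.fp_links.append((ind.father_id, ind.id))
                _, yhap = y_pool.draw(rng)
            else:
                yhap = y[ind.father_id]
            yhap, mutated = mutate_y(yhap, cfg.str_rate, rng)
            for locus in mutated:
                truth.str_mutations.append((ind.father_id, ind.id, locus))
        y[ind.id] = YstrHaplotype(
            panel=yhap.panel, alleles=yhap.alleles,
            haplogroup_label=yhap.haplogroup_label, id=ind.id,
        )
    return MarkerSim(mt=mt, y=y, truth=truth, mt_pool=mt_pool, y_pool=y_pool)


# -- database sampling ---------------------------------------------------------------


@dataclass
class DatabaseSim:
    """A sampled reference database plus the spectrum it was drawn from."""

    db: HaplotypeDatabase
    pool: MtPool
    atom_counts: np.ndarray


def sample_database(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    pool: Optional[MtPool] = None,
) -> DatabaseSim:
    """Draw ``cfg.db_size`` database records from the haplotype spectrum."""
    if rng is None:
        rng = cfg.rng()
    if pool is None:
        pool = make_mt_pool(cfg, rng)
    counts = np.zeros(len(pool.atoms), dtype=int)
    records = []
    if cfg.db_size > 0:
        draws = rng.choice(len(pool.atoms), size=cfg.db_size, p=pool.freqs)
        for j, i in enumerate(draws):
            counts[i] += 1
            records.append((f"DB{j + 1:05d}", pool.atoms[int(i)]))
    return DatabaseSim(db=HaplotypeDatabase(records), pool=pool, atom_counts=counts)


# -- complete cases --------------------------------------------------------------------


@dataclass
class CaseBundle:
    """A complete synthetic identification case with ground truth."""

    cfg: SimulationConfig
    under_h1: bool
    pedigree: Pedigree
    target_id: str
    mt_relative_id: str
    y_relative_id: str
    m_mt: int          # meioses between target and matrilineal relative
    m_y_links: int     # father-son links between target and patrilineal relative
    skeleton_mt: MtHaplotype
    skeleton_y: YstrHaplotype
    relative_mt: MtHaplotype
    relative_y: YstrHaplotype
    database: HaplotypeDatabase
    markers: MarkerSim
    truth: TruthRecord

    def evidence_config(self) -> ev.EvidenceConfig:
        """Genetic evidence items with generatively correct likelihood pairs.

        The mtDNA item conditions on whether the remains match the matrilineal
        relative over the declared ranges; the Y item on whether the remains'
        haplotype equals the patrilineal relative's.  H2 likelihoods are the
        true population frequencies from the generating spectrum (floored at
        1e-12 so the items remain valid probabilities).
        """
        floor = 1e-12
        mt_match = not diff(self.skeleton_mt, self.relative_mt)
        p_h1 = (1.0 - self.cfg.mt_mu) ** self.m_mt
        p_h2 = self.markers.mt_pool.true_frequency(self.relative_mt, self.cfg.mt_ranges)
        mt_item = ev.EvidenceItem.from_likelihoods(
            "mtdna",
            p_h1 if mt_match else 1.0 - p_h1,
            max(p_h2 if mt_match else 1.0 - p_h2, floor),
            notes="match status of remains vs matrilineal relative",
        )
        y_match = (
            compare(self.skeleton_y, self.relative_y).mismatch_count == 0
            and self.skeleton_y.clade() == self.relative_y.clade()
        )
        per_link = (1.0 - self.cfg.fp_rate) * (1.0 - self.cfg.str_rate) ** len(
            self.cfg.panel.loci
        )
        p_h1_y = per_link ** self.m_y_links
        p_h2_y = self.markers.y_pool.true_frequency(self.relative_y)
        y_item = ev.EvidenceItem.from_likelihoods(
            "y_str",
            p_h1_y if y_match else 1.0 - p_h1_y,
            max(p_h2_y if y_match else 1.0 - p_h2_y, floor),
            notes="match status of remains vs patrilineal relative",
        )
        return ev.EvidenceConfig(
            items=[mt_item, y_item],
            priors=[ev.Prior(0.025), ev.Prior(0.5)],
            subsets={"all": ["mtdna", "y_str"], "mtdna": ["mtdna"], "y": ["y_str"]},
        )

    def posterior(self, prior: float = 0.5) -> float:
        cfg = self.evidence_config()
        return ev.posterior(ev.Prior(prior), ev.combine(cfg.items))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle in the package's own text formats; all re-parseable."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": out / "pedigree.tsv",
            "profiles": out / "mt_profiles.tsv",
            "database": out / "mt_database.tsv",
            "ystr": out / "y_haplotypes.tsv",
            "evidence": out / "evidence.json",
            "truth": out / "truth.json",
        }
        paths["pedigree"].write_text(to_ped_text(self.pedigree))
        profile_db = HaplotypeDatabase(
            [
                ("skeleton", self.skeleton_mt),
                (self.mt_relative_id, self.relative_mt),
            ]
        )
        paths["profiles"].write_text(profiles_to_text(profile_db))
        paths["database"].write_text(profiles_to_text(self.database))
        skel_y = YstrHaplotype(
            panel=self.skeleton_y.panel, alleles=self.skeleton_y.alleles,
            haplogroup_label=self.skeleton_y.haplogroup_label, id="skeleton",
        )
        paths["ystr"].write_text(ystr_table_to_text([skel_y, self.relative_y]))
        self.evidence_config().save(paths["evidence"])
        truth_data = asdict(self.truth)
        truth_data.update(
            under_h1=self.under_h1,
            target_id=self.target_id,
            mt_relative_id=self.mt_relative_id,
            y_relative_id=self.y_relative_id,
            m_mt=self.m_mt,
            m_y_links=self.m_y_links,
        )
        paths["truth"].write_text(json.dumps(truth_data, indent=2, default=str) + "\n")
        return paths


def make_case(cfg: SimulationConfig, under_h1: bool = True) -> CaseBundle:
    """Generate one complete identification case.

    The target is the founder couple's son; the matrilineal relative is the
    tracked matriline's final descendant (sharing the founder ancestress),
    the patrilineal relative the tracked patriline's final descendant.  Under
    H1 the remains carry the target's own markers; under H2 they are drawn
    from the unrelated population spectrum.
    """
    if cfg.generations < 1:
        raise ValidationError("a case needs at least one offspring generation")
    rng = cfg.rng()
    sim = simulate_pedigree(cfg, rng)
    markers = transmit_markers(sim.pedigree, cfg, rng)
    ped = sim.pedigree

    target = "B1"  # founder couple's tracked son: has both a matriline and a patriline
    mt_relative = sim.matriline_ids[0]
    y_relative = sim.patriline_ids[0]
    m_mt = ped.meioses_between(target, mt_relative, "matrilineal")
    m_y = ped.meioses_between(target, y_relative, "patrilineal")
    assert m_mt is not None and m_y is not None

    if under_h1:
        skeleton_mt = markers.mt[target]
        skeleton_y = markers.y[target]
    else:
        _, skeleton_mt = markers.mt_pool.draw(rng)
        _, skeleton_y = markers.y_pool.draw(rng)
    db = sample_database(cfg, rng, pool=markers.mt_pool)
    truth = markers.truth
    truth.under_h1 = under_h1

    return CaseBundle(
        cfg=cfg,
        under_h1=under_h1,
        pedigree=ped,
        target_id=target,
        mt_relative_id=mt_relative,
        y_relative_id=y_relative,
        m_mt=m_mt,
        m_y_links=m_y,
        skeleton_mt=skeleton_mt,
        skeleton_y=YstrHaplotype(
            panel=skeleton_y.panel, alleles=skeleton_y.alleles,
            haplogroup_label=skeleton_y.haplogroup_label, id="skeleton",
        ),
        relative_mt=markers.mt[mt_relative],
        relative_y=markers.y[y_relative],
        database=db.db,
        markers=markers,
        truth=truth,
    )


# -- fast replicators (Monte-Carlo checks of the closed forms) -----------------------


def patriline_fp_fraction(
    r: float, m: int, n_rep: int, rng: np.random.Generator
) -> float:
    """Fraction of simulated m-link patrilines with >= 1 false-paternity event.

    Same per-link Bernoulli model as :func:`transmit_markers`, vectorised.
    Compare with the closed form 1 - (1-r)**m.
    """
    events = rng.random((n_rep, m)) < r
    return float(events.any(axis=1).mean())


def matriline_match_fraction(
    mu: float,
    m: int,
    n_rep: int,
    rng: np.random.Generator,
    ranges: Sequence[PositionRange] | None = None,
) -> float:
    """Fraction of simulated m-meiosis matrilines whose end haplotype equals the
    founder's.

    Mutation events are Bernoulli(mu) per meiosis; each event applies the
    single-position state-change model, so rare back-mutations can restore a
    match.  Compare with (1-mu)**m.
    """
    if ranges is None:
        ranges = parse_ranges(DEFAULT_CONTROL_RANGES_TEXT)
    positions = _range_positions(ranges)
    event_counts = rng.binomial(m, mu, size=n_rep)
    matches = int((event_counts == 0).sum())
    for count in event_counts[event_counts > 0]:
        states: dict[int, str] = {}
        for _ in range(int(count)):
            pos = int(positions[int(rng.integers(len(positions)))])
            current = states.get(pos, _REF_STATE)
            options = [s for s in (_REF_STATE, *_BASES) if s != current]
            new = options[int(rng.integers(len(options)))]
            if new == _REF_STATE:
                states.pop(pos, None)
            else:
                states[pos] = new
        if not states:
            matches += 1
    return matches / n_rep


def estimate_fp_rate(fraction_with_event: float, m: int) -> float:
    """Maximum-likelihood per-link rate from the fraction of lines with >= 1 event.

    Inverts 1 - (1-r)**m: r_hat = 1 - (1 - fraction)**(1/m).
    """
    if not 0 <= fraction_with_event < 1:
        raise ValidationError("fraction must lie in [0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return 1.0 - (1.0 - fraction_with_event) ** (1.0 / m)
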