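# Methods

## Hypotheses and evidence combination

Every item of evidence is scored by its likelihood under H1 (the remains are
the target individual) and under H2 (they are not). Items are assumed
mutually independent, so the joint LR is the product of item LRs; the engine
accumulates the product as a sum of logarithms to avoid under/overflow and
exposes it at full double precision. An item whose internal derivation is
out of scope (radiocarbon calibration, the age/sex and wound reference data)
enters as a `fixed_lr` item; everything else as a `likelihood_pair`. An
empty evidence set combines to LR = 1, returning the prior unchanged.

Posterior conversion follows Bayes' rule in odds form,
`posterior odds = LR × prior odds`. The complement (the probability the
remains are *not* the target) is computed directly as
`(1−p)/(LR·p + 1−p)` rather than by subtracting the posterior from 1;
subtraction loses all significant digits once the posterior approaches 1,
which is precisely the regime these analyses end in. `posterior` maps
LR = +∞ to 1 exactly (an observation impossible under H2).

Each item carries an optional `conservative` annotation recording which
direction its assumptions bias the LR. An assumption is conservative if it
reduces the LR; the annotation is documentation only and never enters the
computation.

## mtDNA evidence

Haplotypes are sets of differences from the rCRS over declared 1-based
inclusive position ranges, in EMPOP-style notation. Substitutions are
validated against the declared ranges; insertions (`315.1C`) and deletions
(`249DEL`) are opaque tokens compared by string equality — equality is
well-defined in this notation and the framework never needs to arbitrate
indel alignment. Ambiguity codes other than N are rejected rather than
silently interpreted; positions where either sequence has N are excluded
from profiling. Comparison restricts both haplotypes to the intersection of
their declared ranges; disjoint ranges are a distinct "no comparable
positions" outcome. The control region is expressed as two separate ranges
(16093–16320 and 73–188 by default) rather than a wrap-around object.

The H1 likelihood of an observed match over m meioses is `(1−μ)^m`. The
default μ = 10/327 is the genealogical control-region estimate
(10 observed mutations in 327 transmissions) — deliberately on the high
side, which is conservative here because a higher rate lowers the H1
likelihood. Note that `(1−10/327)^19 = 0.554`, whereas the published
analysis of the worked case used 0.52 for 19 meioses (0.52 equals the
closed form at m = 21); the package implements the closed form and treats
0.52 as an externally supplied constant (`p_no_mutation`) when reproducing
the published LR chain of that case.

The H2 likelihood is the population match probability, estimated from k
matches among n database records as

```
p_match = (k + relative + pseudocount) / (n + relative)
```

with `relative = 1` (the matching relative's own observation, added to both
counts) and `pseudocount = 1` by default. Both additions are exposed as
parameters so other conventions are selectable. The defaults reproduce the
worked case's 2/1,832 from a zero-match database of 1,831. The database
size in that case is reported inconsistently in the source material (1,832
records vs "0 among 1823"); the package follows the printed fraction
2/1,832, i.e. n = 1,831 plus the relative.

Conservatism of the pseudocount rule, precisely stated: the estimator always
strictly exceeds the plain frequency k/n, and its expectation exceeds the
true frequency f for every haplotype (the bias is `(2−f)/(n+1) > 0`), so the
mtDNA LR is biased toward 1. The stronger claim that the *realised* estimate
exceeds f in ≥95% of replicates holds only in the rare-haplotype regime
(nf ≲ 1, the regime identification cases occupy — the worked case observed
k = 0): for common haplotypes, binomial sampling noise `√(nf(1−f))`
dominates the fixed +2 bonus. The test suite asserts exactly these three
properties.

A second matrilineal relative whose haplotype differs from the shared
sequence at a single site contributes LR = 1: conditional on the sequence
already observed in the first relative, the second observation is equally
likely under both hypotheses and cancels (`second_relative_lr`).

## Y-chromosome evidence

Haplotypes are locus→allele maps over a configurable STR panel; the shipped
default is the 23-locus PowerPlex Y23 panel with DYS385 as a two-copy locus
whose value is a sorted multiset. Comparison counts mismatching loci among
those typed in both haplotypes.

Patriline partitioning excludes an individual if its haplogroup clade
(the label's top-level token before any hyphenated refinement: "R1b-U152" →
"R1b") differs from the modal clade — haplogroup discordance cannot arise by
stepwise mutation, so it settles the question alone — or, failing labels, if
its minimum pairwise mismatch distance to modal-clade members exceeds a cap
(default: 10% of compared loci, rounded up; an explicit heuristic).

The evidence LR of an observed non-match between the remains and a
consistent patriline is the false-paternity exposure `1 − (1−r)^m` over the
m recorded father–son links: under H1 at least one false paternity must have
occurred, and the haplotype's population frequency cancels between the two
hypotheses. The default per-link rate r = 0.009 is a conservative
genealogically derived value (the general literature suggests ~1–2%); it is
a required, documented parameter rather than a constant, since published
analyses do not always print it. With m = 19 it yields the worked case's
0.16. Whether the additional recorded link below the most recent common
patrilineal ancestor is folded into m is left to the caller; m is an
explicit parameter.

## Pedigrees

Genealogies are validated at construction: unique ids, resolvable parent
references, global acyclicity (iterative three-colour DFS), and
sex-consistent parent roles. An unknown-sex individual appearing as a parent
logs a warning rather than failing — historical genealogies are incomplete.
Meiosis counts between two individuals follow the most recent common
ancestor on the chosen uniparental line (minimal total meioses when several
exist, matching cousin-naming convention); two individuals without a common
recorded ancestor on that line yield `None` ("unrelated on this lineage"),
a result distinct from any exception. Cousin terminology satisfies
`meioses = 2·(degree+1) + removed` and round-trips back to the generation
counts. The PED-like dialect is tab-separated with a header row and "0" for
unknown parents; serialisation is byte-stable under a parse/write cycle.

## Synthetic data

The generator's defaults are the study conditions of the worked case:
r = 0.009 per link, μ = 10/327 per meiosis, a 1,831-record database over the
two control-region ranges, the PowerPlex Y23 panel, and a per-locus
stepwise-mutation rate of 2×10⁻³ per meiosis (a typical Y-STR average).

* **Pedigrees.** `generations` counts parent–child transmissions along the
  tracked lines (0 = founder couple only), so a 20-generation run yields a
  21-individual matriline. Each generation, a tracked daughter continues the
  matriline and a tracked son the patriline; spouses marry in as unrelated
  founders and each couple adds Poisson-distributed leaf children, giving
  branching matrilineal networks.
* **mtDNA transmission.** At each meiosis one mutation occurs with
  probability μ (Bernoulli — at most one per meiosis, matching the closed
  form `(1−μ)^m` the tests verify); the event moves a uniformly chosen
  in-range position to a state uniform over the four alternatives of
  {reference, A, C, G, T}. Rare back-mutation chains can restore a match;
  at study rates the effect is orders of magnitude below Monte-Carlo
  resolution.
* **Y transmission.** Each recorded father–son link fails with probability
  r, in which case the biological father is a fresh draw from the population
  pool — usually changing the haplogroup label, mirroring how real false
  paternities reveal themselves. Stepwise mutation then perturbs each locus
  ±1 repeat with probability 2×10⁻³, direction equiprobable.
* **Databases.** Haplotype spectra use GEM stick-breaking with concentration
  `db_alpha` (default 10), truncated at 10⁻⁶ residual mass and renormalised;
  records are i.i.d. draws and the truth record retains every atom's true
  frequency.
* **Cases.** Under H1 the remains carry the target's own markers; under H2
  a random population draw. The bundle's evidence items use generatively
  correct likelihood pairs (true pool frequencies under H2, floored at
  10⁻¹² to remain valid probabilities), so batch posteriors are calibrated;
  the suite checks discrimination and bin-wise calibration on 200 simulated
  cases.

All randomness flows from one seeded `numpy` generator per bundle; bundles
are byte-identical under a fixed seed. What the generator does *not*
emulate: sequencing error and DNA damage, heteroplasmy, population
structure or database ascertainment bias, and non-paternity correlations
between links. Passing tests therefore validate the statistical machinery
under the stated transmission models, not the upstream data-generation
realities of ancient-DNA work.

## Numerical and reporting choices

Problem sizes in the test suite: closed-form recoveries use 10,000
Monte-Carlo replicates (3 standard-error acceptance bands); database
recovery uses n = 5,000; the calibration batch uses 200 cases at
4 generations and 200-record databases. Log-space products, the stable
posterior complement, and the `format_lr`/`format_posterior` policies (LRs
≥ 100 to three significant figures; posteriors to just enough decimals to
separate them from 1) are the only places floating-point presentation is
touched; TSV outputs always carry full precision.

Known limitations: no dependence modelling between evidence items
(independence is assumed, as in the underlying framework); no
kinship-coefficient or autosomal IBD computation (uniparental queries
only); no haplogroup prediction from STR profiles; indel tokens are never
realigned. The recomputed combined LR of the worked case is 6.47 million
rather than the published rounded headline of 6.7 million because the
publication multiplies intermediates that were themselves rounded (0.16,
478, 212, …); all subset LRs agree with the published values within the
slack those roundings imply.
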