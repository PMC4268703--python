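"""The worked case: the 2012 Grey Friars (Leicester) skeleton.

Builds the evidence configuration for the identification of the skeleton
excavated at the Grey Friars friary as Richard III, from published inputs:

* four non-genetic items consumed as externally computed fixed LRs —
  radiocarbon dating (1.84), age and sex at death (5.25), scoliosis (212),
  perimortem wounds (42);
* the Y-chromosome item: the remains' Y haplotype does not match the
  patrilineal relatives', explained under H1 by at least one false paternity
  across the 19 recorded father-son links at a conservative per-link rate of
  0.009 (LR = 1 - 0.991**19 ~ 0.16);
* the mtDNA item: a control-region match with a matrilineal relative 19
  meioses away, with a no-mutation probability of 0.52 (a published
  genealogical derivation, consumed as an input constant) against a very
  conservative match probability of 2/1,832 from a zero-match British Isles
  database of 1,831 records (LR ~ 476).

Priors span a sceptical 1/40 and an even 1/2.
"""

from __future__ import annotations

from .evidence import EvidenceConfig, EvidenceItem, Prior, canonical_subsets
from .mtdna import MtEvidenceParams, match_probability, mtdna_lr
from .ystr import FalsePaternityParams, y_lr

#: Conservative per-link false-paternity probability (genealogically derived).
FP_RATE = 0.009
#: Recorded father-son links between the target and the patrilineal relatives.
FP_LINKS = 19
#: Meioses between the target and the matrilineal relative.
MT_MEIOSES = 19
#: Published per-meiosis control-region mutation probability (10 events / 327 meioses).
MT_MU = 10 / 327
#: Published no-mutation probability over the 19 meioses, consumed as an input.
MT_NO_MUTATION = 0.52
#: Zero-match British Isles control-region database size.
BRITISH_DB_N = 1831
#: Zero-match European control-region database size.
EUROPEAN_DB_N = 26127

SCEPTICAL_PRIOR = 1 / 40
EVEN_PRIOR = 1 / 2

NONGENETIC_ITEMS = ("radiocarbon", "age_sex", "scoliosis", "wounds")
GENETIC_ITEMS = ("y_chromosome", "mtdna")


def british_match_probability() -> float:
    """Conservative match probability from the zero-match British database: 2/1,832."""
    return match_probability(k=0, n=BRITISH_DB_N, add_relative=True, pseudocount=1)


def european_match_probability() -> float:
    """Same rule applied to the zero-match European database: 2/26,128."""
    return match_probability(k=0, n=EUROPEAN_DB_N, add_relative=True, pseudocount=1)


def y_item() -> EvidenceItem:
    lr = y_lr(FalsePaternityParams(r=FP_RATE, m=FP_LINKS))
    return EvidenceItem.fixed(
        "y_chromosome", lr,
        notes="Y non-match vs patriline; LR = P(>=1 false paternity in 19 links)",
        conservative="low per-link rate reduces the combined LR",
    )


def mt_item(p_match: float | None = None) -> EvidenceItem:
    lr = mtdna_lr(
        MtEvidenceParams(
            mu=MT_MU, m=MT_MEIOSES,
            p_match=p_match if p_match is not None else british_match_probability(),
            p_no_mutation=MT_NO_MUTATION,
        )
    )
    return EvidenceItem.fixed(
        "mtdna", lr,
        notes="control-region match with the 19-meiosis matrilineal relative",
        conservative="small low-resolution database inflates the match probability",
    )


def grey_friars_config() -> EvidenceConfig:
    """Full evidence configuration of the worked case."""
    items = [
        EvidenceItem.fixed("radiocarbon", 1.84, notes="externally calibrated date model"),
        EvidenceItem.fixed("age_sex", 5.25, notes="male, age 30-34 at death"),
        EvidenceItem.fixed(
            "scoliosis", 212.0,
            notes="0.90 condition share x 0.95 record correctness vs population rate",
        ),
        EvidenceItem.fixed("wounds", 42.0, notes="perimortem battle injuries"),
        y_item(),
        mt_item(),
    ]
    return EvidenceConfig(
        items=items,
        priors=[Prior(SCEPTICAL_PRIOR), Prior(EVEN_PRIOR)],
        subsets=canonical_subsets(
            genetic=list(GENETIC_ITEMS),
            nongenetic=list(NONGENETIC_ITEMS),
            y_item="y_chromosome",
        ),
    )
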