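"""Likelihood-ratio evidence combination and prior-to-posterior conversion.

Each item of evidence — genetic or not — carries likelihoods of the observed
data under two hypotheses: H1, the remains are the target individual, and
H2, they are not.  Items are assumed independent, so the combined LR is the
product of item LRs (accumulated in log space), and Bayes' rule converts a
prior probability into a posterior:

    posterior odds = LR x prior odds.

An item may instead carry a fixed LR computed elsewhere (e.g. a radiocarbon
calibration); the engine treats both forms uniformly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import EvidenceConfigError, ValidationError

LIKELIHOOD_PAIR = "likelihood_pair"
FIXED_LR = "fixed_lr"


@dataclass(frozen=True)
class EvidenceItem:
    """One line of evidence with its likelihoods under H1 and H2.

    ``conservative`` is a documentation field recording which direction the
    item's assumptions bias the LR (an assumption is conservative if it
    reduces the LR); it never enters the computation.
    """

    name: str
    form: str
    lik_h1: Optional[float] = None
    lik_h2: Optional[float] = None
    lr_value: Optional[float] = None
    notes: str = ""
    conservative: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form == LIKELIHOOD_PAIR:
            if self.lik_h1 is None or self.lik_h2 is None:
                raise ValidationError(f"{self.name}: likelihood_pair needs lik_h1 and lik_h2")
            if not 0 <= self.lik_h1 <= 1 or not 0 < self.lik_h2 <= 1:
                raise ValidationError(
                    f"{self.name}: likelihoods must be probabilities with lik_h2 > 0"
                )
        elif self.form == FIXED_LR:
            if self.lr_value is None or self.lr_value <= 0:
                raise ValidationError(f"{self.name}: fixed_lr needs lr > 0")
        else:
            raise ValidationError(f"{self.name}: unknown evidence form {self.form!r}")

    def lr(self) -> float:
        """Likelihood ratio of this item: lik_h1/lik_h2 or the stored fixed LR."""
        if self.form == FIXED_LR:
            return float(self.lr_value)
        return self.lik_h1 / self.lik_h2

    @classmethod
    def fixed(cls, name: str, lr: float, notes: str = "", conservative: str | None = None):
        return cls(name=name, form=FIXED_LR, lr_value=lr, notes=notes, conservative=conservative)

    @classmethod
    def from_likelihoods(
        cls, name: str, lik_h1: float, lik_h2: float, notes: str = "",
        conservative: str | None = None,
    ):
        return cls(
            name=name, form=LIKELIHOOD_PAIR, lik_h1=lik_h1, lik_h2=lik_h2,
            notes=notes, conservative=conservative,
        )


def combine(items: Sequence[EvidenceItem]) -> float:
    """Combined LR of independent evidence items: the product of item LRs.

    Accumulated as a sum of logs to avoid under/overflow; order-invariant.
    An empty collection is the neutral combination, LR = 1.
    """
    log_total = 0.0
    for item in items:
        lr = item.lr()
        if lr == 0.0:
            return 0.0
        log_total += math.log(lr)
    return math.exp(log_total)


@dataclass(frozen=True)
class Prior:
    """Prior probability that H1 is true, before any of the itemised evidence."""

    p: float

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValidationError("prior probability must lie strictly in (0, 1)")

    @property
    def odds(self) -> float:
        return self.p / (1.0 - self.p)


def posterior(prior: Prior, lr: float) -> float:
    """Posterior probability of H1: lr*p / (lr*p + (1-p)).

    Equivalent to posterior odds = lr x prior odds.  lr = +inf (an observation
    impossible under H2) gives posterior 1.
    """
    if lr < 0:
        raise ValidationError("likelihood ratio must be >= 0")
    if math.isinf(lr):
        return 1.0
    num = lr * prior.p
    return num / (num + (1.0 - prior.p))


def not_h1_probability(prior: Prior, lr: float) -> float:
    """Posterior probability that the remains are NOT the target: 1 - posterior."""
    if math.isinf(lr):
        return 0.0
    # computed directly to keep precision when posterior ~ 1
    return (1.0 - prior.p) / (lr * prior.p + (1.0 - prior.p))


# -- scoliosis likelihood construction -------------------------------------------

@dataclass(frozen=True)
class ScoliosisParams:
    """Inputs of the skeletal-deformity likelihood.

    A historical description of one shoulder higher than the other could be
    explained by scoliosis, Erb's palsy or Sprengel's deformity; under H1 the
    probability of observing scoliosis is the scoliosis rate divided by the
    sum of the three rates, discounted by the probability ``p_record`` that
    the recorded description was correct.  ``p_pop`` is the probability of
    the skeletal finding in an unrelated individual (H2).
    """

    rate_s: float
    rate_e: float
    rate_sp: float
    p_record: float
    p_pop: float

    def __post_init__(self) -> None:
        for name in ("rate_s", "rate_e", "rate_sp", "p_record", "p_pop"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")


def scoliosis_share(params: ScoliosisParams) -> float:
    """P(scoliosis | the description): rate_s / (rate_s + rate_e + rate_sp)."""
    total = params.rate_s + params.rate_e + params.rate_sp
    return params.rate_s / total


def scoliosis_lr(params: ScoliosisParams) -> float:
    """LR of the scoliosis finding: (share x p_record) / p_pop."""
    return scoliosis_share(params) * params.p_record / params.p_pop


# -- combination tables -----------------------------------------------------------

def lr_table(
    items: Sequence[EvidenceItem],
    subsets: Mapping[str, Iterable[str]],
    priors: Sequence[Prior],
) -> pd.DataFrame:
    """Combined LR and posteriors for named subsets of the evidence.

    One row per subset; an empty subset is neutral (LR 1, posterior = prior).
    Raises on subset names that do not resolve to items.
    """
    by_name = {item.name: item for item in items}
    rows = []
    for subset_name, member_names in subsets.items():
        members = []
        for name in member_names:
            if name not in by_name:
                raise EvidenceConfigError(f"unknown evidence item {name!r} in subset {subset_name!r}")
            members.append(by_name[name])
        lr = combine(members)
        row: dict = {"subset": subset_name, "items": ",".join(m.name for m in members), "lr": lr}
        for prior in priors:
            row[f"posterior@{prior.p:g}"] = posterior(prior, lr)
        rows.append(row)
    return pd.DataFrame(rows)


def canonical_subsets(
    genetic: Sequence[str], nongenetic: Sequence[str], y_item: Optional[str] = None
) -> dict[str, list[str]]:
    """The four canonical evidence subsets: everything, non-genetic only,
    genetic only, and genetic with the false-paternity-prone Y item dropped."""
    subsets = {
        "all": list(nongenetic) + list(genetic),
        "nongenetic": list(nongenetic),
        "genetic": list(genetic),
    }
    if y_item is not None:
        subsets["genetic_no_y"] = [g for g in genetic if g != y_item]
    return subsets


# -- JSON config ------------------------------------------------------------------

CONFIG_VERSION = 1


def _item_from_dict(entry: Mapping) -> EvidenceItem:
    try:
        name = entry["name"]
        form = entry["form"]
    except KeyError as exc:
        raise EvidenceConfigError(f"evidence item missing key {exc}") from None
    try:
        if form == FIXED_LR:
            return EvidenceItem.fixed(
                name, float(entry["lr"]),
                notes=entry.get("notes", ""), conservative=entry.get("conservative"),
            )
        if form == LIKELIHOOD_PAIR:
            return EvidenceItem.from_likelihoods(
                name, float(entry["lik_h1"]), float(entry["lik_h2"]),
                notes=entry.get("notes", ""), conservative=entry.get("conservative"),
            )
    except KeyError as exc:
        raise EvidenceConfigError(f"item {name!r} missing key {exc}") from None
    raise EvidenceConfigError(f"item {name!r}: unknown form {form!r}")


def _item_to_dict(item: EvidenceItem) -> dict:
    entry: dict = {"name": item.name, "form": item.form}
    if item.form == FIXED_LR:
        entry["lr"] = item.lr_value
    else:
        entry["lik_h1"] = item.lik_h1
        entry["lik_h2"] = item.lik_h2
    if item.notes:
        entry["notes"] = item.notes
    if item.conservative:
        entry["conservative"] = item.conservative
    return entry


@dataclass
class EvidenceConfig:
    """A full evidence specification: items, priors and named subsets."""

    items: list[EvidenceItem]
    priors: list[Prior]
    subsets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [i.name for i in self.items]
        if len(names) != len(set(names)):
            raise EvidenceConfigError("duplicate evidence item names")
        if not self.subsets:
            self.subsets = {"all": names}

    @classmethod
    def from_dict(cls, data: Mapping) -> "EvidenceConfig":
        version = data.get("version", CONFIG_VERSION)
        if version != CONFIG_VERSION:
            raise EvidenceConfigError(f"unsupported config version {version}")
        if "items" not in data or "priors" not in data:
            raise EvidenceConfigError("config needs 'items' and 'priors'")
        return cls(
            items=[_item_from_dict(e) for e in data["items"]],
            priors=[Prior(float(p)) for p in data["priors"]],
            subsets={k: list(v) for k, v in data.get("subsets", {}).items()},
        )

    def to_dict(self) -> dict:
        return {
            "version": CONFIG_VERSION,
            "items": [_item_to_dict(i) for i in self.items],
            "priors": [p.p for p in self.priors],
            "subsets": self.subsets,
        }

    @classmethod
    def load(cls, path: str | Path) -> "EvidenceConfig":
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise EvidenceConfigError(f"malformed JSON in {path}: {exc}") from None
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
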