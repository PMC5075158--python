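"""Item-level missingness induction.

Missing items cluster by subject: a fraction p_sub of subjects become
*candidates* for item deletion, then each in-scope item of a candidate is
deleted independently with probability p_item, so the overall in-scope
missing-cell rate is p_sub * p_item. Three candidate-selection mechanisms
are supported:

* ``random`` — each subject is a candidate independently with probability
  p_sub (MCAR; the candidate count is binomial);
* ``demographic`` — subjects are ranked by a logistic-model linear
  predictor in age, sex, treatment and immigrant status and the top
  round(p_sub * n) become candidates (MAR given covariates);
* ``subscale`` — subjects are ranked by their *true* score on the target
  scale; the top round(p_sub * n) become candidates (MNAR: worse scores
  are more likely to lose items).

Deletion scope is the target scale's items: the 7 items of a subscale, or
all 14 when the target is distress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .scales import SCALES, scale_columns

__all__ = [
    "MECHANISMS",
    "DemographicCoefficients",
    "MissingnessSpec",
    "MaskedItems",
    "select_candidates",
    "delete_items",
    "induce_missingness",
    "overall_missing_rate",
]

MECHANISMS = ("random", "demographic", "subscale")


@dataclass(frozen=True)
class DemographicCoefficients:
    """Log-odds weights of the candidate-selection logistic model.

    Age enters standardized (per SD). Because candidates are chosen by
    *rank* of the linear predictor, only the ordering these weights induce
    matters, not their absolute size; the defaults weight each predictor
    equally in the direction of more missingness for older, male,
    on-treatment, immigrant subjects.
    """

    age: float = 1.0
    male: float = 1.0
    on_treatment: float = 1.0
    immigrant: float = 1.0


@dataclass(frozen=True)
class MissingnessSpec:
    mechanism: str
    p_sub: float
    p_item: float
    target_scale: str = "depression"
    demo_coefficients: DemographicCoefficients = field(default_factory=DemographicCoefficients)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; expected one of {MECHANISMS}")
        if not 0.0 <= self.p_sub <= 1.0:
            raise ValueError("p_sub must lie in [0, 1]")
        if not 0.0 <= self.p_item <= 1.0:
            raise ValueError("p_item must lie in [0, 1]")
        if self.target_scale not in SCALES:
            raise ValueError(f"unknown target scale {self.target_scale!r}")


@dataclass
class MaskedItems:
    """An item matrix with induced missingness (NaN) plus candidate flags."""

    items: np.ndarray  # float n x 14, NaN = missing
    candidate_flags: np.ndarray  # bool n

    @property
    def n(self) -> int:
        return self.items.shape[0]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.items)


def _top_fraction(scores: np.ndarray, p_sub: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of the round(p_sub * n) highest scores, ties broken at random."""
    n = scores.shape[0]
    k = int(np.floor(p_sub * n + 0.5))
    if k == 0:
        return np.empty(0, dtype=int)
    perm = rng.permutation(n)  # random tie-break under a stable sort
    order = perm[np.argsort(scores[perm], kind="stable")]
    return order[n - k:]


def select_candidates(
    cohort: Cohort, spec: MissingnessSpec, rng: np.random.Generator
) -> np.ndarray:
    """Subject indices selected as deletion candidates."""
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    if spec.mechanism == "random":
        return np.flatnonzero(rng.uniform(size=cohort.n) < spec.p_sub)
    if spec.mechanism == "subscale":
        truth = cohort.true_scores().scores(spec.target_scale)
        return _top_fraction(truth, spec.p_sub, rng)
    # demographic: rank by logistic linear predictor
    c = spec.demo_coefficients
    age_sd = cohort.age.std(ddof=1)
    age_z = (cohort.age - cohort.age.mean()) / age_sd if age_sd > 0 else np.zeros(cohort.n)
    lp = (
        c.age * age_z
        + c.male * cohort.male
        + c.on_treatment * cohort.on_treatment
        + c.immigrant * cohort.immigrant
    )
    return _top_fraction(lp, spec.p_sub, rng)


def delete_items(
    cohort: Cohort,
    candidates: np.ndarray,
    spec: MissingnessSpec,
    rng: np.random.Generator,
) -> MaskedItems:
    """Delete each in-scope item of each candidate with probability p_item
    (uniform draw < p_item rule). Non-candidates are untouched."""
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size and (candidates.min() < 0 or candidates.max() >= cohort.n):
        raise ValueError("candidate indices out of range")
    items = cohort.items.astype(float).copy()
    scope = scale_columns(spec.target_scale)
    if candidates.size:
        u = rng.uniform(size=(candidates.size, scope.size))
        hit = (u < spec.p_item).ravel()
        rows = np.repeat(candidates, scope.size)[hit]
        cols = np.tile(scope, candidates.size)[hit]
        items[rows, cols] = np.nan
    flags = np.zeros(cohort.n, dtype=bool)
    flags[candidates] = True
    return MaskedItems(items=items, candidate_flags=flags)


def induce_missingness(
    cohort: Cohort, spec: MissingnessSpec, rng: np.random.Generator
) -> MaskedItems:
    """Candidate selection followed by in-scope item deletion."""
    return delete_items(cohort, select_candidates(cohort, spec, rng), spec, rng)


def overall_missing_rate(p_sub: float, p_item: float) -> float:
    """Expected percentage of in-scope cells deleted: 100 * p_sub * p_item."""
    if not (0.0 <= p_sub <= 1.0 and 0.0 <= p_item <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return 100.0 * p_sub * p_item
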