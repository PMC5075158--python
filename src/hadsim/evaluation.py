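"""Bias, imprecision and QoL-correlation metrics.

Each handling method is judged against the complete-data truth of the
same simulated sample, at two levels:

* individual — mean (and mean squared) difference between a subject's
  method score and their complete score, averaged over the subjects the
  method actually scored;
* population — difference between the method's mean score (over scored
  subjects) and the complete-data mean over *all* subjects of the sample;
  per-replicate imprecision is that difference squared.

Per-cell results average these over replicates. An important level of
bias is 10% of the subscale range (2.1 points), a common minimum
important difference (MID).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scales import ScoreSet

__all__ = [
    "MID_POINTS",
    "ReplicateMetrics",
    "CellResult",
    "individual_metrics",
    "population_metrics",
    "qol_correlation",
    "flag_important_bias",
    "aggregate_cell",
]

#: Minimum important difference: 10% of the 0-21 subscale range.
MID_POINTS = 2.1


def individual_metrics(
    imputed: ScoreSet, truth: ScoreSet, scale: str
) -> tuple[float, float]:
    """(bias, imprecision) of individual scores.

    Averages imputed - truth and (imputed - truth)^2 over subjects whose
    method score is non-missing. Returns (nan, nan) when no subject is
    scored — undefined, never coerced to zero.
    """
    t = truth.scores(scale)
    if np.isnan(t).any():
        raise ValueError("truth scores must be complete")
    diff = imputed.scores(scale) - t
    scored = ~np.isnan(diff)
    if not scored.any():
        return (float("nan"), float("nan"))
    d = diff[scored]
    return (float(d.mean()), float((d**2).mean()))


def population_metrics(
    imputed: ScoreSet, truth: ScoreSet, scale: str
) -> tuple[float, float]:
    """(bias, imprecision) of the sample mean for one replicate.

    bias = mean(method score over scored subjects) - mean(truth over all
    subjects); imprecision = bias^2. Undefined (nan, nan) when no subject
    is scored.
    """
    t = truth.scores(scale)
    if np.isnan(t).any():
        raise ValueError("truth scores must be complete")
    s = imputed.scores(scale)
    scored = ~np.isnan(s)
    if not scored.any():
        return (float("nan"), float("nan"))
    bias = float(s[scored].mean() - t.mean())
    return (bias, bias * bias)


def qol_correlation(scores: ScoreSet, qol: np.ndarray, scale: str) -> float:
    """Pearson correlation of the method's scores with QoL over scored
    subjects; nan when fewer than 3 subjects are scored or either side is
    constant."""
    s = scores.scores(scale)
    qol = np.asarray(qol, dtype=float)
    keep = ~np.isnan(s) & ~np.isnan(qol)
    if keep.sum() < 3:
        return float("nan")
    a, b = s[keep], qol[keep]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def flag_important_bias(bias: float, mid: float = MID_POINTS) -> bool:
    """Is |bias| at or beyond the minimum important difference?"""
    return bool(abs(bias) >= mid)


@dataclass(frozen=True)
class ReplicateMetrics:
    """Metrics of one method on one simulated dataset."""

    individual_bias: float
    individual_imprecision: float
    population_bias: float
    population_imprecision: float
    n_scored: int
    qol_corr: float


@dataclass
class CellResult:
    """Aggregated metrics for one (method x mechanism x p_sub x p_item x n
    x scale) cell."""

    method: str
    mechanism: str
    p_sub: float
    p_item: float
    n: int
    scale: str
    replicates: int
    individual_bias: float
    individual_imprecision: float
    population_bias: float
    population_imprecision: float
    mean_n_scored: float
    qol_correlation: float
    n_undefined: int = 0
    valid: bool = True

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "mechanism": self.mechanism,
            "p_sub": self.p_sub,
            "p_item": self.p_item,
            "n": self.n,
            "scale": self.scale,
            "replicates": self.replicates,
            "individual_bias": self.individual_bias,
            "individual_imprecision": self.individual_imprecision,
            "population_bias": self.population_bias,
            "population_imprecision": self.population_imprecision,
            "mean_n_scored": self.mean_n_scored,
            "qol_correlation": self.qol_correlation,
            "n_undefined": self.n_undefined,
            "valid": self.valid,
        }


def _nanmean(values) -> float:
    arr = np.asarray(values, dtype=float)
    if np.isnan(arr).all():
        return float("nan")
    return float(np.nanmean(arr))


def aggregate_cell(
    metrics: list[ReplicateMetrics],
    *,
    method: str,
    mechanism: str,
    p_sub: float,
    p_item: float,
    n: int,
    scale: str,
) -> CellResult:
    """Arithmetic means of each metric over replicates.

    Replicates with undefined (nan) population bias are counted in
    ``n_undefined`` and excluded from the averages; if every replicate is
    undefined the cell is flagged invalid.
    """
    if not metrics:
        raise ValueError("aggregate_cell needs at least one replicate")
    pop_bias = [m.population_bias for m in metrics]
    n_undef = int(np.isnan(pop_bias).sum())
    valid = n_undef < len(metrics)
    return CellResult(
        method=method,
        mechanism=mechanism,
        p_sub=p_sub,
        p_item=p_item,
        n=n,
        scale=scale,
        replicates=len(metrics),
        individual_bias=_nanmean([m.individual_bias for m in metrics]),
        individual_imprecision=_nanmean([m.individual_imprecision for m in metrics]),
        population_bias=_nanmean(pop_bias),
        population_imprecision=_nanmean([m.population_imprecision for m in metrics]),
        mean_n_scored=_nanmean([m.n_scored for m in metrics]),
        qol_correlation=_nanmean([m.qol_corr for m in metrics]),
        n_undefined=n_undef,
        valid=valid,
    )
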