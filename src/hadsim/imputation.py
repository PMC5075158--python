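"""The seven missing-item handling methods.

Six imputation strategies plus complete-case scoring:

1. ``subject_mean`` — a missing item gets the mean of the subject's
   observed items across the whole 14-item form;
2. ``subscale_mean`` — the mean of the subject's observed items in the
   missing item's own subscale (so a subscale score equals 7 x the mean
   observed subscale item);
3. ``subscale_half_mean`` — the half-rule: subscale-mean imputation, but
   a subscale is scored only if at least half (>= 4 of 7) of its items
   are answered;
4. ``item_mean`` — the mean of the item over the other subjects of the
   current sample;
5. ``mi`` — multiple imputation by chained equations on all 14 items, 10
   completed sets averaged item-wise into one completed matrix;
6. ``mi_half`` — MI scores retained only where the half-rule is met;
7. ``complete_case`` — a scale is scored only for subjects with every one
   of that scale's items observed (exclusion is per analyzed scale).

Imputed values are real-valued and never rounded; every method leaves
observed cells untouched and every imputed cell lies in [0, 3].
"""

from __future__ import annotations

import logging

import numpy as np

from .missingness import MaskedItems
from .scales import (
    N_ITEMS,
    SUBSCALES,
    ScoreSet,
    scale_columns,
    score_allow_missing,
)

__all__ = [
    "METHODS",
    "IMPUTATION_METHODS",
    "impute_subject_mean",
    "impute_subscale_mean",
    "impute_item_mean",
    "mice_impute",
    "half_rule_scored",
    "apply_half_rule",
    "complete_case_scores",
    "score_with_method",
]

logger = logging.getLogger(__name__)

METHODS = (
    "subject_mean",
    "subscale_mean",
    "subscale_half_mean",
    "item_mean",
    "mi",
    "mi_half",
    "complete_case",
)
#: The six methods that fill in items (complete case excluded).
IMPUTATION_METHODS = METHODS[:-1]

#: Minimum answered items per subscale under the half-rule: "at least
#: half" of 7 items, i.e. >= 4 (3.5 is not attainable).
HALF_RULE_MIN_OBSERVED = 4


def _as_items(masked: MaskedItems | np.ndarray) -> np.ndarray:
    items = masked.items if isinstance(masked, MaskedItems) else masked
    return np.asarray(items, dtype=float)


def impute_subject_mean(masked: MaskedItems | np.ndarray) -> np.ndarray:
    """Missing cells <- mean of the subject's observed items across all 14.

    A subject with all 14 items missing keeps NaN everywhere (their scores
    stay missing); this is logged.
    """
    items = _as_items(masked).copy()
    miss = np.isnan(items)
    if not miss.any():
        return items
    all_missing = miss.all(axis=1)
    if all_missing.any():
        logger.info(
            "subject_mean: %d subject(s) with all 14 items missing left unscored",
            int(all_missing.sum()),
        )
    with np.errstate(invalid="ignore"):
        row_means = np.nanmean(np.where(all_missing[:, None], 0.0, items), axis=1)
    fill = np.broadcast_to(row_means[:, None], items.shape)
    items[miss & ~all_missing[:, None]] = fill[miss & ~all_missing[:, None]]
    return items


def impute_subscale_mean(masked: MaskedItems | np.ndarray) -> np.ndarray:
    """Missing cells <- mean of the subject's observed items in the cell's
    own subscale. A subject missing all 7 items of a subscale keeps that
    subscale missing (logged)."""
    items = _as_items(masked).copy()
    for subscale in SUBSCALES:
        cols = scale_columns(subscale)
        block = items[:, cols]
        miss = np.isnan(block)
        if not miss.any():
            continue
        empty = miss.all(axis=1)
        if empty.any():
            logger.info(
                "subscale_mean: %d subject(s) missing all %s items left unscored",
                int(empty.sum()), subscale,
            )
        with np.errstate(invalid="ignore"):
            means = np.nanmean(np.where(empty[:, None], 0.0, block), axis=1)
        fill = np.broadcast_to(means[:, None], block.shape)
        sel = miss & ~empty[:, None]
        block[sel] = fill[sel]
        items[:, cols] = block
    return items


def impute_item_mean(masked: MaskedItems | np.ndarray) -> np.ndarray:
    """Missing cells <- mean of the item's observed values across the
    current sample's subjects."""
    items = _as_items(masked).copy()
    miss = np.isnan(items)
    if not miss.any():
        return items
    empty_cols = miss.all(axis=0)
    if empty_cols[miss.any(axis=0)].any():
        bad = np.flatnonzero(empty_cols) + 1
        raise ValueError(f"item(s) {bad.tolist()} missing for every subject; item mean undefined")
    col_means = np.nanmean(items, axis=0)
    fill = np.broadcast_to(col_means, items.shape)
    items[miss] = fill[miss]
    return items


def mice_impute(
    masked: MaskedItems | np.ndarray,
    m: int = 10,
    rng: np.random.Generator | int | None = None,
    n_sweeps: int = 10,
) -> np.ndarray:
    """Multiple imputation by chained equations, averaged item-wise.

    Each chain initializes missing cells at the item mean, then for
    `n_sweeps` burn-in sweeps visits items 1..14 in order, regressing each
    incomplete item on the other 13 (ordinary least squares over the rows
    where the item was observed) and redrawing its missing cells as the
    prediction plus Gaussian residual noise, truncated to [0, 3]. The `m`
    completed matrices are averaged cell-wise, the point-estimate
    equivalent of scoring each set and pooling the estimates.

    A degenerate regression (no usable rows, or a numerically singular
    system) falls back to the item mean for that item in that sweep and
    is logged.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    items = _as_items(masked)
    miss = np.isnan(items)
    if not miss.any():
        return items.copy()
    if miss.all(axis=0).any():
        bad = np.flatnonzero(miss.all(axis=0)) + 1
        raise ValueError(f"item(s) {bad.tolist()} missing for every subject; cannot impute")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    col_means = np.nanmean(items, axis=0)
    incomplete = np.flatnonzero(miss.any(axis=0))

    total = np.zeros_like(items)
    for _chain in range(m):
        X = items.copy()
        X[miss] = np.broadcast_to(col_means, X.shape)[miss]
        for _sweep in range(n_sweeps):
            for j in incomplete:
                mj = miss[:, j]
                obs = ~mj
                others = np.delete(np.arange(N_ITEMS), j)
                n_obs = int(obs.sum())
                if n_obs < 2:
                    logger.warning("mice: item %d has <2 observed rows; item-mean fallback", j + 1)
                    X[mj, j] = np.clip(col_means[j] + rng.standard_normal(mj.sum()), 0.0, 3.0)
                    continue
                A = np.column_stack([np.ones(n_obs), X[obs][:, others]])
                y = X[obs, j]
                try:
                    beta, rss, rank, _ = np.linalg.lstsq(A, y, rcond=None)
                except np.linalg.LinAlgError:
                    logger.warning("mice: singular system for item %d; item-mean fallback", j + 1)
                    X[mj, j] = np.clip(col_means[j] + rng.standard_normal(mj.sum()), 0.0, 3.0)
                    continue
                dof = max(n_obs - A.shape[1], 1)
                resid = y - A @ beta
                sd = float(np.sqrt(max(resid @ resid / dof, 1e-12)))
                pred = np.column_stack([np.ones(mj.sum()), X[mj][:, others]]) @ beta
                X[mj, j] = np.clip(pred + sd * rng.standard_normal(mj.sum()), 0.0, 3.0)
        total += X
    return total / m


def half_rule_scored(masked: MaskedItems | np.ndarray) -> dict[str, np.ndarray]:
    """Per-subscale boolean arrays: does the subject pass the half-rule
    (>= 4 of 7 items observed)?"""
    items = _as_items(masked)
    out = {}
    for subscale in SUBSCALES:
        observed = (~np.isnan(items[:, scale_columns(subscale)])).sum(axis=1)
        out[subscale] = observed >= HALF_RULE_MIN_OBSERVED
    return out


def _scores_from_completed(completed: np.ndarray) -> ScoreSet:
    return score_allow_missing(np.clip(completed, 0.0, 3.0))


def apply_half_rule(
    masked: MaskedItems | np.ndarray,
    inner_method: str = "subscale_mean",
    rng: np.random.Generator | int | None = None,
    mi_completed: np.ndarray | None = None,
    m: int = 10,
) -> ScoreSet:
    """Score each subscale via `inner_method` where the half-rule passes;
    otherwise the subscale score is missing. Distress is reported only
    when both subscales are scored.

    `mi_completed` lets the caller reuse an already-computed MI matrix
    when both ``mi`` and ``mi_half`` are evaluated on the same replicate.
    """
    if inner_method == "subscale_mean":
        completed = impute_subscale_mean(masked)
    elif inner_method == "mi":
        completed = mi_completed if mi_completed is not None else mice_impute(masked, m=m, rng=rng)
    else:
        raise ValueError(f"half-rule inner method must be subscale_mean or mi, got {inner_method!r}")
    scored = half_rule_scored(masked)
    scores = _scores_from_completed(completed)
    anx = np.where(scored["anxiety"], scores.anxiety, np.nan)
    dep = np.where(scored["depression"], scores.depression, np.nan)
    return ScoreSet(anxiety=anx, depression=dep)


def complete_case_scores(masked: MaskedItems | np.ndarray) -> ScoreSet:
    """Per-scale complete-case scoring: a subject contributes a scale's
    score only when all of that scale's items are observed. Sum with NaN
    propagation does exactly that."""
    items = _as_items(masked)
    scores = score_allow_missing(items)
    if all(scores.n_scored(s) == 0 for s in ("anxiety", "depression", "distress")):
        logger.warning("complete_case: no subject has a complete scale")
    return scores


def score_with_method(
    masked: MaskedItems | np.ndarray,
    method: str,
    rng: np.random.Generator | int | None = None,
    mi_completed: np.ndarray | None = None,
    m: int = 10,
) -> ScoreSet:
    """Dispatch a handling method and return the resulting scores."""
    if method == "subject_mean":
        return _scores_from_completed(impute_subject_mean(masked))
    if method == "subscale_mean":
        return _scores_from_completed(impute_subscale_mean(masked))
    if method == "subscale_half_mean":
        return apply_half_rule(masked, inner_method="subscale_mean")
    if method == "item_mean":
        return _scores_from_completed(impute_item_mean(masked))
    if method == "mi":
        completed = mi_completed if mi_completed is not None else mice_impute(masked, m=m, rng=rng)
        return _scores_from_completed(completed)
    if method == "mi_half":
        return apply_half_rule(masked, inner_method="mi", rng=rng, mi_completed=mi_completed, m=m)
    if method == "complete_case":
        return complete_case_scores(masked)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
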