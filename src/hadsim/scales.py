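"""HADS scale structure, orientation and scoring.

The Hospital Anxiety and Depression Scale (HADS) has 14 items rated 0-3.
Odd-numbered items form the anxiety subscale, even-numbered items the
depression subscale; each subscale score is the sum of its 7 items
(range 0-21) and "distress" is the total over all 14 items (range 0-42).
Several items are worded positively on the questionnaire and must be
reverse scored (x -> 3 - x) before summing; throughout this package item
matrices are stored in *scored orientation* (higher = worse) and
:func:`orient_raw_items` converts raw questionnaire coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SCALES",
    "SUBSCALES",
    "ANXIETY_ITEMS",
    "DEPRESSION_ITEMS",
    "REVERSE_SCORED_ITEMS",
    "SEVERITY_BANDS",
    "N_ITEMS",
    "ITEMS_PER_SUBSCALE",
    "scale_columns",
    "scale_range",
    "orient_raw_items",
    "ScoreSet",
    "score_complete",
    "score_allow_missing",
    "cronbach_alpha",
]

N_ITEMS = 14
ITEMS_PER_SUBSCALE = 7

#: 1-based item numbers per subscale (questionnaire numbering).
ANXIETY_ITEMS = (1, 3, 5, 7, 9, 11, 13)
DEPRESSION_ITEMS = (2, 4, 6, 8, 10, 12, 14)

#: Items whose raw questionnaire coding runs opposite to severity.
#: Anxiety: 1, 3, 5, 11, 13; depression: 6, 8, 10.
REVERSE_SCORED_ITEMS = frozenset({1, 3, 5, 11, 13, 6, 8, 10})

SUBSCALES = ("anxiety", "depression")
SCALES = ("anxiety", "depression", "distress")

#: Conventional severity bands for a subscale score:
#: normal, mild, moderate, severe.
SEVERITY_BANDS = ((0, 7), (8, 10), (11, 14), (15, 21))


def scale_columns(scale: str) -> np.ndarray:
    """0-based column indices of `scale`'s items in an n x 14 matrix."""
    if scale == "anxiety":
        items = ANXIETY_ITEMS
    elif scale == "depression":
        items = DEPRESSION_ITEMS
    elif scale == "distress":
        items = tuple(range(1, N_ITEMS + 1))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return np.asarray(items, dtype=int) - 1


def scale_range(scale: str) -> tuple[int, int]:
    """Possible (min, max) of a scale score."""
    return (0, 42) if scale == "distress" else (0, 21)


def _validate_items(items: np.ndarray, allow_missing: bool) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    if items.ndim != 2 or items.shape[1] != N_ITEMS:
        raise ValueError(f"expected an n x {N_ITEMS} item matrix, got shape {items.shape}")
    missing = np.isnan(items)
    if missing.any() and not allow_missing:
        subj, item = np.argwhere(missing)[0]
        raise ValueError(f"missing entry at subject {subj}, item {item + 1}")
    finite = items[~missing]
    bad = (finite < 0) | (finite > 3)
    if bad.any():
        # name the first offender for the error message
        ok = np.where(missing, True, (items >= 0) & (items <= 3))
        subj, item = np.argwhere(~ok)[0]
        raise ValueError(
            f"item value out of range [0, 3] at subject {subj}, item {item + 1}: "
            f"{items[subj, item]!r}"
        )
    return items


def orient_raw_items(raw_items: np.ndarray) -> np.ndarray:
    """Map raw questionnaire coding to scored orientation.

    Reverse-scored items are mapped x -> 3 - x; all other entries are
    unchanged. Missing entries (NaN) are preserved. The transform is an
    involution: applying it twice restores the input.
    """
    items = _validate_items(raw_items, allow_missing=True)
    out = items.copy()
    cols = np.asarray(sorted(REVERSE_SCORED_ITEMS)) - 1
    out[:, cols] = 3.0 - out[:, cols]
    return out


@dataclass
class ScoreSet:
    """Per-subject anxiety/depression/distress scores; NaN marks a score
    that a handling method could not (or chose not to) produce."""

    anxiety: np.ndarray
    depression: np.ndarray
    distress: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.anxiety = np.asarray(self.anxiety, dtype=float)
        self.depression = np.asarray(self.depression, dtype=float)
        if self.distress is None:
            self.distress = self.anxiety + self.depression
        else:
            self.distress = np.asarray(self.distress, dtype=float)

    @property
    def n(self) -> int:
        return self.anxiety.shape[0]

    def scores(self, scale: str) -> np.ndarray:
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r}")
        return getattr(self, scale)

    def n_scored(self, scale: str) -> int:
        """Number of subjects with a non-missing score (the tables' "n method")."""
        return int(np.sum(~np.isnan(self.scores(scale))))


def score_allow_missing(items: np.ndarray) -> ScoreSet:
    """Sum subscales, propagating NaN: a scale score is missing whenever
    any of its items is missing."""
    items = _validate_items(items, allow_missing=True)
    anx = items[:, scale_columns("anxiety")].sum(axis=1)
    dep = items[:, scale_columns("depression")].sum(axis=1)
    return ScoreSet(anxiety=anx, depression=dep)


def score_complete(items: np.ndarray) -> ScoreSet:
    """Standard HADS scoring of a complete item matrix in scored orientation.

    anxiety = sum of items 1,3,5,7,9,11,13; depression = sum of items
    2,4,6,8,10,12,14; distress = anxiety + depression.

    Raises
    ------
    ValueError
        If any entry is missing (apply a handling method first) or out of
        range.
    """
    items = _validate_items(items, allow_missing=False)
    return score_allow_missing(items)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum of item variances / variance of sum).

    Parameters
    ----------
    items : (n, k) array
        Complete item responses, n >= 2 subjects, k >= 2 items.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("alpha requires an n x k matrix with n >= 2, k >= 2")
    if np.isnan(X).any():
        raise ValueError("alpha requires complete data")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))
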