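"""Synthetic HADS cohorts from a Gaussian latent-trait model.

The generator emulates an oncology patient/survivor population: two
correlated standard-normal latent traits (anxiety, depression) drive the
14 ordinal items through a graded-response-style discretization, a
continuous quality-of-life score is a linear function of the latents plus
noise, and demographic covariates (age, sex, treatment status, immigrant
status) are drawn independently. Calibration of the model to published
descriptive statistics lives in :mod:`hadsim.calibration`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scales import (
    ANXIETY_ITEMS,
    DEPRESSION_ITEMS,
    N_ITEMS,
    SEVERITY_BANDS,
    SUBSCALES,
    cronbach_alpha,
    scale_columns,
    score_complete,
)

__all__ = [
    "ItemModel",
    "CovariateModel",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "summarize_cohort",
    "CohortSummary",
]


def subscale_of_item(item_index: int) -> str:
    if item_index in ANXIETY_ITEMS:
        return "anxiety"
    if item_index in DEPRESSION_ITEMS:
        return "depression"
    raise ValueError(f"item index must be 1..14, got {item_index}")


@dataclass(frozen=True)
class ItemModel:
    """Latent-response model for one item.

    The item's latent response is ``loading * trait + sqrt(1 - loading^2)
    * noise`` (a standard normal marginally); the observed category 0..3
    is the number of `thresholds` the latent response exceeds.
    """

    item_index: int
    subscale: str
    thresholds: tuple[float, float, float]
    loading: float

    def __post_init__(self) -> None:
        if subscale_of_item(self.item_index) != self.subscale:
            raise ValueError(
                f"item {self.item_index} belongs to the "
                f"{subscale_of_item(self.item_index)} subscale, not {self.subscale}"
            )
        t = self.thresholds
        if not (len(t) == 3 and t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be 3 strictly ascending cut-points")
        if not 0.0 <= self.loading < 1.0:
            raise ValueError("loading must lie in [0, 1)")


@dataclass(frozen=True)
class CovariateModel:
    """Marginal covariate distributions.

    Defaults reflect the population the generator emulates: age normal
    with mean 63 and SD 11.8 truncated to [19, 87]; 46% male; immigrant
    status matching an immigrant-enriched oncology sample. Covariates only
    matter through the ordering they induce in the demographic missingness
    mechanism, so their joint distribution with the HADS traits is not
    modelled.
    """

    age_mean: float = 63.0
    age_sd: float = 11.8
    age_bounds: tuple[float, float] = (19.0, 87.0)
    p_male: float = 0.46
    p_on_treatment: float = 0.5
    p_immigrant: float = 0.588


@dataclass(frozen=True)
class CohortSpec:
    """Complete recipe for generating a cohort."""

    n_subjects: int
    latent_corr: float
    item_models: tuple[ItemModel, ...]
    qol_weights: tuple[float, float]
    qol_noise_sd: float
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent_corr must lie in (-1, 1)")
        if len(self.item_models) != N_ITEMS:
            raise ValueError(f"need exactly {N_ITEMS} item models")
        indices = sorted(m.item_index for m in self.item_models)
        if indices != list(range(1, N_ITEMS + 1)):
            raise ValueError("item models must cover items 1..14 exactly once")
        if self.qol_noise_sd < 0:
            raise ValueError("qol_noise_sd must be non-negative")

    def ordered_items(self) -> tuple[ItemModel, ...]:
        return tuple(sorted(self.item_models, key=lambda m: m.item_index))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["item_models"] = [dataclasses.asdict(m) for m in self.ordered_items()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["item_models"] = tuple(
            ItemModel(
                item_index=int(m["item_index"]),
                subscale=m["subscale"],
                thresholds=tuple(float(t) for t in m["thresholds"]),
                loading=float(m["loading"]),
            )
            for m in d["item_models"]
        )
        d["qol_weights"] = tuple(float(w) for w in d["qol_weights"])
        cov = d.get("covariates")
        if isinstance(cov, dict):
            cov = dict(cov)
            cov["age_bounds"] = tuple(float(x) for x in cov["age_bounds"])
            d["covariates"] = CovariateModel(**cov)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        """Serialize as a declarative YAML config."""
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """A complete synthetic (or ingested) item-level dataset.

    `items` is n x 14 in scored orientation with entries in {0,1,2,3};
    there are no missing values — missingness is induced downstream.
    """

    items: np.ndarray
    age: np.ndarray
    male: np.ndarray
    on_treatment: np.ndarray
    immigrant: np.ndarray
    qol: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items)
        if self.items.ndim != 2 or self.items.shape[1] != N_ITEMS:
            raise ValueError(f"items must be n x {N_ITEMS}")
        if self.items.size and not np.isin(self.items, [0, 1, 2, 3]).all():
            raise ValueError("cohort items must all lie in {0, 1, 2, 3}")

    @property
    def n(self) -> int:
        return self.items.shape[0]

    def take(self, indices: np.ndarray) -> "Cohort":
        """Row-subset (or resample) every per-subject field."""
        idx = np.asarray(indices)
        return Cohort(
            items=self.items[idx],
            age=self.age[idx],
            male=self.male[idx],
            on_treatment=self.on_treatment[idx],
            immigrant=self.immigrant[idx],
            qol=self.qol[idx],
        )

    def true_scores(self):
        return score_complete(self.items)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.items.astype(int), columns=[f"hads{i}" for i in range(1, N_ITEMS + 1)]
        )
        df.insert(0, "subject_id", np.arange(1, self.n + 1))
        df["age"] = self.age
        df["sex"] = np.where(self.male, "male", "female")
        df["on_treatment"] = self.on_treatment.astype(int)
        df["immigrant"] = self.immigrant.astype(int)
        df["qol"] = self.qol
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        item_cols = [f"hads{i}" for i in range(1, N_ITEMS + 1)]
        missing_cols = [c for c in item_cols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort table lacks item columns: {missing_cols}")
        n = len(df)
        return cls(
            items=df[item_cols].to_numpy(dtype=int),
            age=df["age"].to_numpy(dtype=float) if "age" in df else np.full(n, np.nan),
            male=(
                df["sex"].astype(str).str.lower().eq("male").to_numpy()
                if "sex" in df
                else np.zeros(n, dtype=bool)
            ),
            on_treatment=(
                df["on_treatment"].astype(float).astype(bool).to_numpy()
                if "on_treatment" in df
                else np.zeros(n, dtype=bool)
            ),
            immigrant=(
                df["immigrant"].astype(float).astype(bool).to_numpy()
                if "immigrant" in df
                else np.zeros(n, dtype=bool)
            ),
            qol=df["qol"].to_numpy(dtype=float) if "qol" in df else np.full(n, np.nan),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))


def _truncated_normal(mean, sd, lo, hi, size, rng):
    from scipy import stats

    u = rng.uniform(size=size)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    lo_p, hi_p = stats.norm.cdf([a, b])
    return mean + sd * stats.norm.ppf(lo_p + u * (hi_p - lo_p))


def draw_items(
    spec: CohortSpec, traits: dict[str, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """Discretize latent responses into the n x 14 item matrix."""
    n = traits["anxiety"].shape[0]
    items = np.empty((n, N_ITEMS), dtype=np.int8)
    for model in spec.ordered_items():
        lam = model.loading
        latent = lam * traits[model.subscale] + np.sqrt(1.0 - lam**2) * rng.standard_normal(n)
        th = np.asarray(model.thresholds)
        items[:, model.item_index - 1] = (latent[:, None] > th[None, :]).sum(axis=1)
    return items


def generate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator | int | None = None,
    n: int | None = None,
) -> Cohort:
    """Draw a complete cohort from `spec`.

    Bit-reproducible: the same (spec, seed) always yields the same cohort.
    `n` overrides ``spec.n_subjects`` when given.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = spec.n_subjects if n is None else int(n)
    if n < 0:
        raise ValueError("n must be non-negative")

    rho = spec.latent_corr
    t_anx = rng.standard_normal(n)
    t_dep = rho * t_anx + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    traits = {"anxiety": t_anx, "depression": t_dep}

    items = draw_items(spec, traits, rng)

    w_a, w_d = spec.qol_weights
    qol = w_a * t_anx + w_d * t_dep + spec.qol_noise_sd * rng.standard_normal(n)

    cov = spec.covariates
    age = _truncated_normal(cov.age_mean, cov.age_sd, *cov.age_bounds, size=n, rng=rng)
    male = rng.uniform(size=n) < cov.p_male
    on_treatment = rng.uniform(size=n) < cov.p_on_treatment
    immigrant = rng.uniform(size=n) < cov.p_immigrant
    return Cohort(items=items, age=age, male=male, on_treatment=on_treatment,
                  immigrant=immigrant, qol=qol)


@dataclass
class CohortSummary:
    """Descriptives in the layout of a scale-validation table: item means,
    subscale mean/SD, severity-band proportions, alphas, QoL correlations."""

    n: int
    item_means: np.ndarray
    subscale_means: dict[str, float]
    subscale_sds: dict[str, float]
    band_proportions: dict[str, np.ndarray]
    alphas: dict[str, float]
    qol_correlations: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scale in ("anxiety", "depression", "distress"):
            rows.append(
                {
                    "scale": scale,
                    "mean": self.subscale_means[scale],
                    "sd": self.subscale_sds[scale],
                    "alpha": self.alphas[scale],
                    "qol_corr": self.qol_correlations[scale],
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        lines = [f"Cohort summary (n = {self.n})"]
        for i, m in enumerate(self.item_means, start=1):
            lines.append(f"  item {i:2d} mean = {m:.3f}")
        for scale in ("anxiety", "depression", "distress"):
            lines.append(
                f"  {scale:10s} mean = {self.subscale_means[scale]:6.3f}  "
                f"sd = {self.subscale_sds[scale]:6.3f}  "
                f"alpha = {self.alphas[scale]:.3f}  "
                f"r(QoL) = {self.qol_correlations[scale]:+.3f}"
            )
        for scale in SUBSCALES:
            bands = "  ".join(
                f"{lo}-{hi}: {100 * p:5.1f}%"
                for (lo, hi), p in zip(SEVERITY_BANDS, self.band_proportions[scale])
            )
            lines.append(f"  {scale} bands  {bands}")
        return "\n".join(lines)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Descriptive statistics of a complete cohort."""
    scores = cohort.true_scores()
    items = cohort.items.astype(float)
    means, sds, alphas, corrs, bands = {}, {}, {}, {}, {}
    for scale in ("anxiety", "depression", "distress"):
        s = scores.scores(scale)
        means[scale] = float(s.mean()) if cohort.n else float("nan")
        sds[scale] = float(s.std(ddof=1)) if cohort.n > 1 else float("nan")
        sub = items[:, scale_columns(scale)]
        try:
            alphas[scale] = cronbach_alpha(sub)
        except (ValueError, ZeroDivisionError):
            alphas[scale] = float("nan")
        if cohort.n > 2 and np.std(s) > 0 and np.std(cohort.qol) > 0:
            corrs[scale] = float(np.corrcoef(s, cohort.qol)[0, 1])
        else:
            corrs[scale] = float("nan")
    for scale in SUBSCALES:
        s = scores.scores(scale)
        props = np.array(
            [np.mean((s >= lo) & (s <= hi)) if cohort.n else np.nan for lo, hi in SEVERITY_BANDS]
        )
        bands[scale] = props
    return CohortSummary(
        n=cohort.n,
        item_means=items.mean(axis=0) if cohort.n else np.full(N_ITEMS, np.nan),
        subscale_means=means,
        subscale_sds=sds,
        band_proportions=bands,
        alphas=alphas,
        qol_correlations=corrs,
    )
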