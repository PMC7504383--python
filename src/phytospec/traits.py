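"""Spectra-trait model assessment: split ensembles, fit statistics, outlier
screening, external validation and batch trait prediction.

The modelling protocol mirrors common practice in leaf spectroscopy: a
~20% external hold-out is split off once; on the remaining samples the
model is assessed over 500 random 80:20 calibration/validation splits,
yielding distributions of fit statistics, standardized coefficients and
VIP profiles; coefficients averaged over the ensemble are then applied to
the external set.  Fit quality is summarised by R^2 (squared Pearson
correlation of observed and predicted), RMSE, bias (mean of predicted
minus observed) and %RMSE (RMSE as a percent of the observed range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls
from .spectra import SpectraSet, QCThresholds, qc_table, subset_range


class TraitModelError(ValueError):
    pass


#: Final spectral range (nm) and component count per trait.  These are the
#: published configuration choices for each parameter; they are taken as
#: defaults rather than re-derived.
DEFAULT_TRAIT_MODELS: dict[str, tuple[int, int, int]] = {
    "F0": (600, 900, 8),
    "Fm": (600, 900, 7),
    "FvFm": (600, 900, 8),
    "Fs": (400, 1200, 4),
    "Fm_prime": (400, 1200, 8),
    "F0_prime": (600, 900, 7),
    "PhiPSII": (600, 900, 10),
    "FvpFmp": (600, 900, 7),
    "ETR": (400, 2400, 12),
    "qP": (600, 900, 11),
    "qN": (600, 900, 7),
    "NPQ": (600, 900, 6),
    "qL": (600, 900, 8),
    "P": (400, 2400, 12),
    "D": (600, 900, 7),
}


@dataclass(frozen=True)
class FitStats:
    """R^2 / RMSE / bias / %RMSE of an observed-predicted comparison."""

    r2: float
    rmse: float
    bias: float
    pct_rmse: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse,
                "bias": self.bias, "pct_rmse": self.pct_rmse}


def fit_stats(observed: np.ndarray, predicted: np.ndarray) -> FitStats:
    """Compute fit statistics; R^2 is the squared Pearson correlation."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape != pred.shape or obs.size < 2:
        raise TraitModelError("observed/predicted must share length >= 2")
    rng_obs = obs.max() - obs.min()
    if rng_obs == 0:
        raise TraitModelError("constant observed values: range undefined")
    if np.std(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    return FitStats(
        r2=r2,
        rmse=rmse,
        bias=float(np.mean(pred - obs)),
        pct_rmse=100.0 * rmse / rng_obs,
    )


@dataclass
class EnsembleResult:
    """Per-iteration fit statistics and coefficient/VIP distributions."""

    trait: str
    n_components: int
    wavelengths: np.ndarray
    cal_stats: pd.DataFrame
    val_stats: pd.DataFrame
    coef_std: np.ndarray      # n_iter x p, autoscaled units
    coef_raw: np.ndarray      # n_iter x p, original units
    intercepts: np.ndarray    # n_iter
    vip: np.ndarray           # n_iter x p
    seed: int | None = None

    @property
    def n_iter(self) -> int:
        return len(self.cal_stats)

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD of each statistic for calibration and validation."""
        rows = []
        for split, df in (("cal", self.cal_stats), ("val", self.val_stats)):
            for stat in df.columns:
                rows.append({
                    "split": split, "statistic": stat,
                    "mean": df[stat].mean(), "sd": df[stat].std(ddof=1),
                })
        return pd.DataFrame(rows)

    def profile_summary(self) -> pd.DataFrame:
        """Mean and 5th/95th percentile coefficient and VIP profiles."""
        pct = lambda a, q: np.percentile(a, q, axis=0)
        return pd.DataFrame({
            "wavelength": self.wavelengths,
            "coef_mean": self.coef_std.mean(axis=0),
            "coef_p5": pct(self.coef_std, 5),
            "coef_p95": pct(self.coef_std, 95),
            "vip_mean": self.vip.mean(axis=0),
            "vip_p5": pct(self.vip, 5),
            "vip_p95": pct(self.vip, 95),
        })

    def mean_coefficients(self) -> tuple[np.ndarray, float]:
        """Ensemble-mean raw coefficient vector and intercept."""
        return self.coef_raw.mean(axis=0), float(self.intercepts.mean())


def permutation_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_iter: int = 500,
    cal_fraction: float = 0.8,
    seed: int | None = None,
    scale: bool = True,
    wavelengths: np.ndarray | None = None,
    trait: str = "",
) -> EnsembleResult:
    """Random-split validation ensemble.

    Each iteration draws a uniform (unstratified) calibration/validation
    split, fits the PLS model on the calibration part and evaluates fit
    statistics on both parts; standardized coefficients and VIP are stored
    per iteration.  Fully reproducible from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise TraitModelError("need at least 10 samples for the ensemble")
    if not 0.5 < cal_fraction < 0.95:
        raise TraitModelError("cal_fraction must lie in (0.5, 0.95)")
    n_cal = int(round(cal_fraction * n))
    if n_components >= n_cal:
        raise TraitModelError(
            f"n_components={n_components} >= calibration size {n_cal}"
        )
    if wavelengths is None:
        wavelengths = np.arange(p)
    rng = np.random.default_rng(seed)
    cal_rows, val_rows = [], []
    coef_std = np.zeros((n_iter, p))
    coef_raw = np.zeros((n_iter, p))
    intercepts = np.zeros(n_iter)
    vips = np.zeros((n_iter, p))
    for it in range(n_iter):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pls.fit_pls(X[cal], y[cal], n_components, scale=scale)
        cal_rows.append(fit_stats(y[cal], pls.predict(model, X[cal])).as_dict())
        val_rows.append(fit_stats(y[val], pls.predict(model, X[val])).as_dict())
        coef_std[it] = pls.standardized_coefficients(model)
        coef_raw[it] = model.coefficients_raw
        intercepts[it] = model.intercept
        vips[it] = pls.vip(model)
    return EnsembleResult(
        trait=trait,
        n_components=n_components,
        wavelengths=np.asarray(wavelengths),
        cal_stats=pd.DataFrame(cal_rows),
        val_stats=pd.DataFrame(val_rows),
        coef_std=coef_std,
        coef_raw=coef_raw,
        intercepts=intercepts,
        vip=vips,
        seed=seed,
    )


@dataclass(frozen=True)
class OutlierReport:
    sample_id: str
    reason: str  # RESIDUAL | QC_SPECTRAL | TRAIT_EXTREME
    value: float


def screen_outliers(
    sset: SpectraSet,
    y: np.ndarray | pd.Series,
    n_components: int,
    residual_k: float = 2.5,
    qc_thresholds: QCThresholds = QCThresholds(),
    scale: bool = True,
    model_range: tuple[int, int] | None = None,
) -> list[OutlierReport]:
    """Flag samples before final modelling.

    Three screens are combined: (i) leave-one-out prediction residuals
    beyond ``residual_k`` residual SDs, (ii) spectra failing quality
    control, and (iii) trait values beyond 3 interquartile ranges from the
    median.  The union is reported with reasons; callers drop flagged
    samples before fitting the final models.  ``sset`` must cover
    400-2400 nm for the QC screen; the residual model is fitted on
    ``model_range`` when given (e.g. the trait's published range).
    """
    ids = sset.sample_ids
    y = np.asarray(pd.Series(y).loc[ids] if isinstance(y, pd.Series) else y,
                   dtype=float)
    reports: list[OutlierReport] = []

    qc = qc_table(sset, qc_thresholds)
    for sid in ids:
        if not qc.loc[sid, "passed"]:
            reports.append(OutlierReport(str(sid), "QC_SPECTRAL", 1.0))

    fit_set = sset if model_range is None else subset_range(sset, *model_range)
    X = fit_set.data.to_numpy()
    curve_errors = np.zeros(len(ids))
    keep = np.ones(len(ids), dtype=bool)
    a = min(n_components, len(ids) - 2, X.shape[1])
    for i in range(len(ids)):
        keep[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pls.fit_pls(X[keep], y[keep], a, scale=scale)
        curve_errors[i] = y[i] - pls.predict(m, X[i:i + 1])[0]
        keep[i] = True
    sd = curve_errors.std(ddof=1)
    if sd > 0:
        z = np.abs(curve_errors) / sd
        for i, sid in enumerate(ids):
            if z[i] > residual_k:
                reports.append(OutlierReport(str(sid), "RESIDUAL", float(z[i])))

    q1, med, q3 = np.percentile(y, [25, 50, 75])
    iqr = q3 - q1
    if iqr > 0:
        dist = np.abs(y - med) / iqr
        for i, sid in enumerate(ids):
            if dist[i] > 3.0:
                reports.append(
                    OutlierReport(str(sid), "TRAIT_EXTREME", float(dist[i]))
                )
    return reports


def external_validate(
    ensemble: EnsembleResult,
    X_ext: np.ndarray,
    y_ext: np.ndarray,
    model_ids: list | None = None,
    ext_ids: list | None = None,
) -> FitStats:
    """Apply the ensemble-mean coefficient vector to an independent set.

    The external samples must be disjoint from the modelling samples (the
    ID check is enforced when both ID lists are given) and contain at
    least two observations.
    """
    if model_ids is not None and ext_ids is not None:
        overlap = set(map(str, model_ids)) & set(map(str, ext_ids))
        if overlap:
            raise TraitModelError(
                f"external samples overlap the modelling set: {sorted(overlap)[:5]}"
            )
    X_ext = np.atleast_2d(np.asarray(X_ext, dtype=float))
    y_ext = np.asarray(y_ext, dtype=float).ravel()
    if y_ext.size < 2:
        raise TraitModelError("external validation needs >= 2 samples")
    b, b0 = ensemble.mean_coefficients()
    return fit_stats(y_ext, b0 + X_ext @ b)


@dataclass
class TraitModel:
    """One trait's final model: ensemble plus external validation."""

    trait: str
    lo_nm: int
    hi_nm: int
    n_components: int
    ensemble: EnsembleResult
    external: FitStats | None = None


def predict_traits(
    bundle: dict[str, TraitModel],
    sset: SpectraSet,
    r2_threshold: float = 0.55,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Predict traits for new spectra from the best-performing models.

    Only traits whose external-validation R^2 reaches ``r2_threshold`` are
    produced; the second return value records the reason each remaining
    trait was omitted.
    """
    columns: dict[str, np.ndarray] = {}
    skipped: dict[str, str] = {}
    for trait, tm in bundle.items():
        try:
            sub = subset_range(sset, tm.lo_nm, tm.hi_nm)
        except Exception as exc:
            skipped[trait] = f"missing wavelength range: {exc}"
            continue
        if tm.external is None or not np.isfinite(tm.external.r2):
            skipped[trait] = "no external validation"
            continue
        if tm.external.r2 < r2_threshold:
            skipped[trait] = (
                f"external R2 {tm.external.r2:.2f} < {r2_threshold}"
            )
            continue
        b, b0 = tm.ensemble.mean_coefficients()
        columns[trait] = b0 + sub.data.to_numpy() @ b
    out = pd.DataFrame(columns, index=sset.data.index)
    return out, skipped


def ensemble_summary_table(bundle: dict[str, TraitModel]) -> pd.DataFrame:
    """One row per trait: range, components, cal/val mean +/- SD statistics."""
    rows = []
    for trait, tm in bundle.items():
        s = tm.ensemble.summary().set_index(["split", "statistic"])
        row = {
            "trait": trait,
            "range_nm": f"{tm.lo_nm}-{tm.hi_nm}",
            "n_components": tm.n_components,
        }
        for split in ("cal", "val"):
            for stat in ("r2", "rmse", "pct_rmse"):
                row[f"{split}_{stat}_mean"] = s.loc[(split, stat), "mean"]
                row[f"{split}_{stat}_sd"] = s.loc[(split, stat), "sd"]
        if tm.external is not None:
            row["ext_r2"] = tm.external.r2
            row["ext_rmse"] = tm.external.rmse
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
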