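"""Hyperspectral phenotyping of treatment groups.

Whole spectral signatures are compared across treatments with three
complementary tools:

* **PERMANOVA** on Euclidean distances — a permutational pseudo-F test of
  whether group centroids differ (10,000 label permutations by default,
  p-value with the +1 correction so it is never exactly zero);
* **PCoA** (classical metric multidimensional scaling) to visualise the
  spectral space; on Euclidean distances it reproduces PCA up to axis sign;
* **PLS-DA** — PLS2 regression on one-hot class labels decoded by argmax,
  evaluated over stratified random calibration/validation splits on a grid
  of split ratios and component counts, with Cohen's kappa as the selection
  criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import pls


class PhenotypingError(ValueError):
    pass


# --------------------------------------------------------------------- PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    ss_total: float
    ss_among: float
    ss_within: float
    n_permutations: int
    group_sizes: dict


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        m = labels == g
        ss += d2[np.ix_(m, m)].sum() / (2.0 * m.sum())
    return ss


def permanova(
    X: np.ndarray,
    groups,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA with Euclidean distances.

    ``SS_total = (1/n) sum_{i<j} d_ij^2``; ``SS_within`` sums the analogous
    quantity per group; ``pseudo-F = [SS_among/(g-1)] / [SS_within/(n-g)]``.
    The p-value counts permutations with F at least as large as observed,
    with the +1 correction.  On univariate data the pseudo-F equals the
    classical one-way ANOVA F.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(groups)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise PhenotypingError("group labels do not match sample count")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise PhenotypingError("need at least 2 groups")
    if counts.min() < 2:
        raise PhenotypingError("singleton group in PERMANOVA")
    g = uniq.size
    d2 = squareform(pdist(X, metric="euclidean")) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (g - 1)) / (ss_within / (n - g))

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        ssw = _ss_within(d2, perm, uniq)
        ssa = ss_total - ssw
        f_perm = (ssa / (g - 1)) / (ssw / (n - g))
        if f_perm >= f_obs:
            count_ge += 1
    p = (1.0 + count_ge) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs), p_value=float(p),
        ss_total=float(ss_total), ss_among=float(ss_among),
        ss_within=float(ss_within), n_permutations=n_permutations,
        group_sizes=dict(zip(uniq.tolist(), counts.tolist())),
    )


# ------------------------------------------------------------------------- PCoA

@dataclass
class PCoAResult:
    eigenvalues: np.ndarray
    scores: np.ndarray
    proportion_explained: np.ndarray


def pcoa(X: np.ndarray | None = None, D: np.ndarray | None = None) -> PCoAResult:
    """Principal coordinates analysis (Gower double-centering).

    Accepts either a data matrix ``X`` (Euclidean distances are computed)
    or a distance matrix ``D`` (symmetric, zero diagonal).  Scores are
    eigenvectors scaled by sqrt of the (non-negative) eigenvalues, ordered
    by decreasing eigenvalue; proportions are relative to the positive
    eigenvalue total.
    """
    if (X is None) == (D is None):
        raise PhenotypingError("give exactly one of X or D")
    if D is None:
        D = squareform(pdist(np.atleast_2d(np.asarray(X, dtype=float))))
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise PhenotypingError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise PhenotypingError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scores = evecs * np.sqrt(np.maximum(evals, 0.0))
    pos = np.maximum(evals, 0.0).sum()
    prop = np.maximum(evals, 0.0) / pos if pos > 0 else np.zeros(n)
    return PCoAResult(eigenvalues=evals, scores=scores,
                      proportion_explained=prop)


# ----------------------------------------------------------------------- PLS-DA

def plsda_fit_predict(
    X_cal: np.ndarray,
    labels_cal,
    X_val: np.ndarray,
    n_components: int,
    scale: bool = True,
) -> np.ndarray:
    """Fit one-hot PLS2 on the calibration set and decode by argmax.

    Ties go to the lexicographically first class; every calibration class
    must be present.
    """
    labels_cal = np.asarray(labels_cal)
    classes = np.unique(labels_cal)  # sorted, so argmax ties break lexically
    if classes.size < 2:
        raise PhenotypingError("need at least 2 classes in calibration")
    Y = (labels_cal[:, None] == classes[None, :]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = pls.fit_pls2(np.asarray(X_cal, dtype=float), Y,
                             n_components, scale=scale)
    scores = pls.predict_pls2(model, X_val)
    return classes[np.argmax(scores, axis=1)]


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement ``(p_o - p_e)/(1 - p_e)`` of a square
    confusion matrix (rows = observed, columns = predicted)."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise PhenotypingError("confusion matrix must be square")
    if np.any(cm < 0) or cm.sum() <= 0:
        raise PhenotypingError("confusion matrix must be nonnegative, total > 0")
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float(cm.sum(axis=1) @ cm.sum(axis=0)) / total ** 2
    if p_e >= 1.0:
        warnings.warn("degenerate confusion matrix (p_e = 1); kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class PLSDACell:
    cal_fraction: float
    n_components: int
    accuracy_mean: float
    accuracy_sd: float
    kappa_mean: float
    kappa_sd: float
    confusion: np.ndarray  # summed over iterations, validation split


@dataclass
class PLSDAResult:
    grid: pd.DataFrame              # one row per (ratio, ncomp) cell
    best: PLSDACell
    classes: np.ndarray
    n_iter: int


def _stratified_split(rng, labels: np.ndarray, cal_fraction: float):
    cal_idx = []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        n_cal = max(1, int(round(cal_fraction * idx.size)))
        n_cal = min(n_cal, idx.size - 1)  # keep >= 1 validation sample
        cal_idx.append(rng.permutation(idx)[:n_cal])
    cal = np.concatenate(cal_idx)
    mask = np.zeros(labels.size, dtype=bool)
    mask[cal] = True
    return np.nonzero(mask)[0], np.nonzero(~mask)[0]


def plsda_grid(
    X: np.ndarray,
    labels,
    ratios: tuple[float, ...] = (0.5, 0.7, 0.8),
    component_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 13),
    n_iter: int = 500,
    seed: int | None = None,
    scale: bool = True,
) -> PLSDAResult:
    """Grid search over split ratios and component counts.

    For each cell, ``n_iter`` stratified random splits are drawn (so every
    class appears in every calibration set) and validation accuracy and
    kappa recorded.  The best configuration has the highest mean validation
    kappa; ties prefer fewer components, then the larger calibration
    fraction.  Cells whose component count cannot be supported by the
    calibration size are skipped (capped at calibration size - 2) with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise PhenotypingError("every class needs >= 2 samples")
    k = classes.size
    rng = np.random.default_rng(seed)
    rows = []
    cells: list[PLSDACell] = []
    for frac in ratios:
        for ncomp in component_grid:
            n_cal_min = sum(
                min(max(1, int(round(frac * c))), c - 1) for c in counts
            )
            if ncomp > n_cal_min - 2:
                warnings.warn(
                    f"skipping cell (ratio={frac}, ncomp={ncomp}): "
                    f"calibration size {n_cal_min} too small"
                )
                continue
            acc = np.zeros(n_iter)
            kap = np.zeros(n_iter)
            confusion = np.zeros((k, k))
            for it in range(n_iter):
                cal, val = _stratified_split(rng, labels, frac)
                pred = plsda_fit_predict(X[cal], labels[cal], X[val],
                                         ncomp, scale=scale)
                cm = np.zeros((k, k))
                for obs_lab, pred_lab in zip(labels[val], pred):
                    cm[np.searchsorted(classes, obs_lab),
                       np.searchsorted(classes, pred_lab)] += 1
                confusion += cm
                acc[it] = np.trace(cm) / cm.sum()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kap[it] = cohen_kappa(cm)
            cell = PLSDACell(
                cal_fraction=frac, n_components=ncomp,
                accuracy_mean=float(acc.mean()), accuracy_sd=float(acc.std(ddof=1)),
                kappa_mean=float(kap.mean()), kappa_sd=float(kap.std(ddof=1)),
                confusion=confusion,
            )
            cells.append(cell)
            rows.append({
                "cal_fraction": frac, "n_components": ncomp,
                "acc_mean": cell.accuracy_mean, "acc_sd": cell.accuracy_sd,
                "kappa_mean": cell.kappa_mean, "kappa_sd": cell.kappa_sd,
            })
    if not cells:
        raise PhenotypingError("no feasible grid cell")
    best = max(
        cells,
        key=lambda c: (c.kappa_mean, -c.n_components, c.cal_fraction),
    )
    return PLSDAResult(
        grid=pd.DataFrame(rows), best=best, classes=classes, n_iter=n_iter
    )
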