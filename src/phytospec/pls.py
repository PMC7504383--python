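"""Partial least squares regression from scratch (NIPALS).

Hyperspectral reflectance gives hundreds of strongly collinear predictors;
PLS projects them onto a few latent components chosen to maximise covariance
with the response, avoiding the unstable coefficients of ordinary least
squares.  This module implements

* PLS1 (single response) via NIPALS with X-deflation,
* prediction in original units,
* leave-one-out PRESS and component selection,
* standardized (autoscaled-units) coefficients,
* variable importance in projection (VIP, Wold's definition), and
* a multi-response PLS2 used by the discriminant analysis in
  :mod:`phytospec.phenotyping`.

With ``A = min(n-1, p)`` components on full-rank data, PLS reproduces the
least-squares solution; the test suite holds the implementation to that
oracle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """A fitted PLS1 model.

    Arrays follow the usual chemometric notation: weights ``W`` (p x A),
    X-loadings ``P`` (p x A), y-loadings ``q`` (A), scores ``T`` (n x A).
    ``coefficients_std`` are the regression coefficients of autoscaled y on
    autoscaled X; ``coefficients_raw`` (plus ``intercept``) act on original
    units.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    coefficients_std: np.ndarray
    coefficients_raw: np.ndarray
    intercept: float
    scaled: bool = True
    wavelengths: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.x_mean.shape[0]

    def to_json(self) -> str:
        doc = {
            "n_components": int(self.n_components),
            "scaled": bool(self.scaled),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": float(self.y_mean),
            "y_scale": float(self.y_scale),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "scores": self.scores.tolist(),
            "coefficients_std": self.coefficients_std.tolist(),
            "coefficients_raw": self.coefficients_raw.tolist(),
            "intercept": float(self.intercept),
            "wavelengths": None if self.wavelengths is None
            else np.asarray(self.wavelengths).tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "PLSModel":
        d = json.loads(doc)
        wl = d.pop("wavelengths")
        arrays = {
            k: np.asarray(d[k], dtype=float)
            for k in ("x_mean", "x_scale", "weights", "x_loadings",
                      "y_loadings", "scores", "coefficients_std",
                      "coefficients_raw")
        }
        return cls(
            n_components=d["n_components"],
            y_mean=d["y_mean"], y_scale=d["y_scale"],
            intercept=d["intercept"], scaled=d["scaled"],
            wavelengths=None if wl is None else np.asarray(wl),
            **arrays,
        )


def _autoscale(X: np.ndarray, scale: bool):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = sd <= 0
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance predictor(s); their "
                "coefficients are set to 0", stacklevel=3
            )
            sd = np.where(zero, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = True,
    wavelengths: np.ndarray | None = None,
) -> PLSModel:
    """Fit a univariate-response PLS model by NIPALS with X-deflation.

    Predictors (and the response, when ``scale=True``) are centred and
    scaled to unit variance before extraction.  If a weight vector collapses
    to zero norm (rank exhausted) the component count is reduced with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSError("X and y sample counts differ")
    if n < 3:
        raise PLSError("need at least 3 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise PLSError("NaN or infinite values in X or y")
    max_a = min(n - 1, p)
    if n_components < 1 or n_components > max_a:
        raise PLSError(
            f"n_components must be in [1, {max_a}] for n={n}, p={p}"
        )

    Xs, x_mean, x_scale = _autoscale(X, scale)
    y_mean = y.mean()
    y_scale = y.std(ddof=1) if scale else 1.0
    if y_scale <= 0:
        raise PLSError("constant response")
    ys = (y - y_mean) / y_scale

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xd = Xs.copy()
    yd = ys.copy()
    a_used = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn(
                f"rank collapse at component {a + 1}; using {a} components",
                stacklevel=2,
            )
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            warnings.warn(
                f"degenerate score at component {a + 1}; using {a} components",
                stacklevel=2,
            )
            break
        pl = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd -= np.outer(t, pl)
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, qa, t
        a_used = a + 1
    if a_used == 0:
        raise PLSError("no PLS component could be extracted")
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]

    # b = W (P'W)^-1 q maps autoscaled X to autoscaled y.
    b_std = W @ np.linalg.solve(P.T @ W, q)
    b_raw = b_std * y_scale / x_scale
    intercept = y_mean - float(b_raw @ x_mean)

    return PLSModel(
        n_components=a_used,
        x_mean=x_mean, x_scale=x_scale,
        y_mean=float(y_mean), y_scale=float(y_scale),
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        coefficients_std=b_std, coefficients_raw=b_raw,
        intercept=intercept, scaled=scale,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths),
    )


def _check_grid(model: PLSModel, X_new: np.ndarray,
                wavelengths: np.ndarray | None) -> None:
    if X_new.shape[1] != model.n_features:
        raise PLSError(
            f"predictor count mismatch: model has {model.n_features}, "
            f"input has {X_new.shape[1]}"
        )
    if wavelengths is not None and model.wavelengths is not None:
        if not np.array_equal(np.asarray(wavelengths), model.wavelengths):
            raise PLSError("wavelength grid differs from the fitted model")


def predict(model: PLSModel, X_new: np.ndarray,
            wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Predict the response in original units."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _check_grid(model, X_new, wavelengths)
    return model.intercept + X_new @ model.coefficients_raw


def predict_components(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predictions using 1..A components (columns), original units."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _check_grid(model, X_new, None)
    Z = (X_new - model.x_mean) / model.x_scale
    A = model.n_components
    out = np.zeros((X_new.shape[0], A))
    acc = np.zeros(X_new.shape[0])
    Zd = Z.copy()
    for a in range(A):
        t = Zd @ model.weights[:, a]
        Zd -= np.outer(t, model.x_loadings[:, a])
        acc = acc + t * model.y_loadings[a]
        out[:, a] = model.y_mean + model.y_scale * acc
    return out


@dataclass
class PressCurve:
    """Leave-one-out PRESS for component counts 1..A."""

    components: np.ndarray
    press: np.ndarray


def loo_press(X: np.ndarray, y: np.ndarray, max_components: int,
              scale: bool = True) -> PressCurve:
    """Leave-one-out predicted residual sum of squares per component count.

    ``PRESS(A) = sum_i (y_i - yhat_{-i}(A))^2`` where each held-out
    prediction comes from a model fitted without sample ``i``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise PLSError("need at least 4 samples for leave-one-out")
    a_max = min(max_components, n - 2, p)
    if a_max < max_components:
        warnings.warn(
            f"max_components reduced to {a_max} for n={n}, p={p}",
            stacklevel=2,
        )
    errors = np.zeros((n, a_max))
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_pls(X[keep], y[keep], a_max, scale=scale)
        preds = predict_components(m, X[i:i + 1])[0]
        if m.n_components < a_max:  # rank collapsed in this fold
            preds = np.concatenate(
                [preds, np.full(a_max - m.n_components, preds[-1])]
            )
        errors[i] = y[i] - preds
        keep[i] = True
    return PressCurve(
        components=np.arange(1, a_max + 1),
        press=(errors ** 2).sum(axis=0),
    )


def select_ncomp(curve: PressCurve, rule: str = "onesigma",
                 tol: float = 0.05) -> int:
    """Pick the component count from a PRESS curve.

    ``"min"`` takes the argmin; ``"onesigma"`` (default) the smallest count
    whose PRESS is within ``tol`` (relative) of the minimum, guarding
    against overfitting.  Ties go to the smaller count.
    """
    press = np.asarray(curve.press, dtype=float)
    if press.size == 0:
        raise PLSError("empty PRESS curve")
    if rule == "min":
        return int(curve.components[int(np.argmin(press))])
    if rule == "onesigma":
        cutoff = press.min() * (1.0 + tol)
        ok = np.nonzero(press <= cutoff)[0]
        return int(curve.components[ok[0]])
    raise PLSError(f"unknown selection rule {rule!r}")


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection (Wold).

    ``VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a )`` with
    ``SSY_a = q_a^2 t_a' t_a`` the response variance captured by component
    ``a``.  The profile satisfies ``sum_j VIP_j^2 = p``.
    """
    W, q, T = model.weights, model.y_loadings, model.scores
    p = W.shape[0]
    ssy = q ** 2 * np.einsum("ia,ia->a", T, T)
    total = ssy.sum()
    if total <= 0:
        raise PLSError("degenerate model: no response variance captured")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2 @ ssy) / total)


def standardized_coefficients(model: PLSModel) -> np.ndarray:
    """Coefficients of the regression of autoscaled y on autoscaled X.

    Invariant under affine rescaling of the raw inputs (for models fitted
    with ``scale=True``, the default).
    """
    if model.scaled:
        return model.coefficients_std.copy()
    # unscaled fit: express the same linear map in autoscaled units
    return model.coefficients_std * model.x_scale / model.y_scale


# ---------------------------------------------------------------------------
# multi-response PLS2 (used for discriminant analysis)

@dataclass
class PLS2Model:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    coefficients: np.ndarray  # p x m, on scaled X, centred Y
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray


def fit_pls2(X: np.ndarray, Y: np.ndarray, n_components: int,
             scale: bool = True, max_iter: int = 500,
             tol: float = 1e-10) -> PLS2Model:
    """NIPALS PLS2 for a multi-column response (one-hot classes in PLS-DA)."""
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    m = Y.shape[1]
    max_a = min(n - 1, p)
    if n_components < 1 or n_components > max_a:
        raise PLSError(f"n_components must be in [1, {max_a}]")
    Xs, x_mean, x_scale = _autoscale(X, scale)
    y_mean = Y.mean(axis=0)
    Yd = Y - y_mean
    Xd = Xs.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((m, n_components))
    a_used = 0
    for a in range(n_components):
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        if np.linalg.norm(u) < 1e-12:
            break
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-12:
                break
            w /= nw
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        nw = np.linalg.norm(Xd.T @ u)
        if nw < 1e-12:
            break
        tt = t @ t
        if tt < 1e-24:
            break
        pl = Xd.T @ t / tt
        Xd -= np.outer(t, pl)
        Yd = Yd - np.outer(t, c)
        W[:, a], P[:, a], C[:, a] = w, pl, c
        a_used = a + 1
    if a_used == 0:
        raise PLSError("no PLS2 component could be extracted")
    W, P, C = W[:, :a_used], P[:, :a_used], C[:, :a_used]
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return PLS2Model(
        n_components=a_used, x_mean=x_mean, x_scale=x_scale,
        y_mean=y_mean, coefficients=B, weights=W, x_loadings=P, y_loadings=C,
    )


def predict_pls2(model: PLS2Model, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    Z = (X_new - model.x_mean) / model.x_scale
    return model.y_mean + Z @ model.coefficients
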