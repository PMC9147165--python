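"""NIPALS PLS1 regression with grouped leave-one-out factor selection.

The calibration model is partial least squares regression with a single
response (PLS1), fitted by the NIPALS algorithm on column-mean-centred
features and a centred response:

    for each latent factor a = 1..k:
        w_a = X'y / ||X'y||          (weight: covariance direction)
        t_a = X w_a                  (score)
        c_a = t_a'y / t_a't_a        (response loading)
        p_a = X't_a / t_a't_a        (feature loading)
        X <- X - t_a p_a',  y <- y - c_a t_a   (deflation)

with the regression vector composed as b = W (P'W)^-1 c, so that
predictions are yhat = (X - x_mean) b + y_mean.  Iteration stops early
when the residual covariance ||X'y|| falls below 1e-12.

The number of latent factors (1..20 by default) is chosen by
leave-one-out cross-validation on the calibration set.  When replicate
spectra of one sample are modelled as separate rows, the whole sample is
held out at once (grouped LOO) so replicates cannot leak between folds.
For speed the CV loop runs in the Gram (sample-space) formulation of
NIPALS, which is algebraically identical to the primal iteration and is
checked against it in the test suite; spectra are wide (q >> n), so
working with the n x n kernel K = Xc Xc' is much cheaper.

Model quality is summarised by the coefficient of determination
R^2 = 1 - SS_res/SS_tot (which can be negative on validation data) and
root-mean-square errors on the calibration set (RMSEC), under
cross-validation (RMSECV) and on the validation set (RMSEP/RMSEV).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateInputError, OilspecError

_EARLY_STOP_TOL = 1e-12


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise OilspecError("X must be 2-D")
    if y.shape[0] != X.shape[0]:
        raise OilspecError("X and y length mismatch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise OilspecError("non-finite values in X or y")
    return X, y


class PLS1Regression(RegressorMixin, BaseEstimator):
    """NIPALS PLS1 with mean centring.

    Parameters
    ----------
    n_components : requested number of latent factors (may be truncated
        if the residual covariance vanishes earlier).
    tol : early-stop tolerance on ||X'y|| during deflation.

    Attributes
    ----------
    x_mean_, y_mean_ : centring constants.
    x_weights_ (W), x_loadings_ (P) : (q, k) factor matrices.
    y_loadings_ (c) : (k,) response loadings.
    coef_ (b) : (q,) regression vector on centred data.
    n_components_ : number of factors actually extracted.
    """

    def __init__(self, n_components: int = 2, tol: float = _EARLY_STOP_TOL):
        self.n_components = n_components
        self.tol = tol

    def fit(self, X, y):
        X, y = _as_xy(X, y)
        n, q = X.shape
        if n < 2:
            raise OilspecError("need >= 2 calibration rows")
        k = int(self.n_components)
        if not 1 <= k <= min(n - 1, q):
            raise OilspecError(
                f"n_components={k} outside 1..min(n-1={n - 1}, q={q})"
            )
        if np.std(y) == 0.0:
            raise DegenerateInputError("uninformative response: zero-variance y")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        W = np.zeros((q, k))
        P = np.zeros((q, k))
        c = np.zeros(k)
        extracted = 0
        for a in range(k):
            w = Xc.T @ yc
            nw = float(np.linalg.norm(w))
            if nw < self.tol:
                break
            w /= nw
            t = Xc @ w
            tt = float(t @ t)
            c[a] = float(t @ yc) / tt
            p = (Xc.T @ t) / tt
            Xc -= np.outer(t, p)
            yc -= c[a] * t
            W[:, a], P[:, a] = w, p
            extracted += 1
        if extracted == 0:
            self.coef_ = np.zeros(q)
            self.x_weights_ = W[:, :0]
            self.x_loadings_ = P[:, :0]
            self.y_loadings_ = c[:0]
        else:
            W = W[:, :extracted]
            P = P[:, :extracted]
            c = c[:extracted]
            self.coef_ = W @ np.linalg.solve(P.T @ W, c)
            self.x_weights_ = W
            self.x_loadings_ = P
            self.y_loadings_ = c
        self.n_components_ = extracted
        self.n_features_in_ = q
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise OilspecError("column mismatch in predict")
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def r_squared(y, y_pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size < 2 or y.size != y_pred.size:
        raise OilspecError("r_squared needs two equal-length vectors, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("uninformative response: constant y")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss_tot


def rmse(y, y_pred) -> float:
    """Root-mean-square error."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.size == 0 or y.size != y_pred.size:
        raise OilspecError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


@dataclass
class CVResult:
    """Leave-one-out RMSECV profile over factor counts 1..k_max."""

    rmsecv_by_k: np.ndarray
    best_k: int


@dataclass
class ModelMetrics:
    """Quality summary of one fitted calibration model."""

    r2_c: float
    r2_v: float
    rmsec: float
    rmsecv: float
    rmsep: float
    calibration_range: tuple[float, float]


# ---------------------------------------------------------------------------
# grouped leave-one-out factor selection (Gram formulation)
# ---------------------------------------------------------------------------


def loocv_select(
    X_cal,
    y_cal,
    groups: Sequence | None = None,
    k_max: int = 20,
    tol: float = _EARLY_STOP_TOL,
) -> CVResult:
    """Choose the PLS factor count by grouped leave-one-out CV.

    Each unique value of ``groups`` (default: every row its own group) is
    held out in turn, all its rows together; a PLS1 model is refitted on
    the rest and the held-out rows are predicted for every factor count
    k = 1..min(k_max, n_groups - 2, q).  RMSECV(k) is the RMS of all
    held-out errors; ``best_k`` is the smallest minimiser.
    """
    X, y = _as_xy(X_cal, y_cal)
    n, q = X.shape
    garr = np.asarray(groups if groups is not None else np.arange(n))
    if garr.shape[0] != n:
        raise OilspecError("groups length mismatch")
    uniq = list(dict.fromkeys(garr.tolist()))
    n_g = len(uniq)
    if n_g < 3:
        raise OilspecError("grouped LOO needs >= 3 calibration samples")
    k_cap = int(min(k_max, n_g - 2, q))
    if k_cap < 1:
        raise OilspecError("no admissible factor count")
    if np.std(y) == 0.0:
        raise DegenerateInputError("uninformative response: zero-variance y")

    G = X @ X.T
    sq = np.zeros(k_cap)
    for g in uniq:
        T = np.flatnonzero(garr != g)
        O = np.flatnonzero(garr == g)
        Gtt = G[np.ix_(T, T)]
        gt = Gtt.mean(axis=1)
        mu = float(gt.mean())
        K = Gtt - gt[:, None] - gt[None, :] + mu
        Got = G[np.ix_(O, T)]
        M = Got - Got.mean(axis=1, keepdims=True) - gt[None, :] + mu
        ym = float(y[T].mean())
        r = y[T] - ym
        yo = y[O]
        yhat = np.full(O.size, ym)
        for a in range(k_cap):
            Kr = K @ r
            s2 = max(float(r @ Kr), 0.0)
            s = np.sqrt(s2)
            if s < tol:
                sq[a:] += float(np.sum((yo - yhat) ** 2))
                break
            t = Kr / s
            tt = float(t @ t)
            ca = float(t @ r) / tt
            t_o = (M @ r) / s
            yhat = yhat + ca * t_o
            sq[a] += float(np.sum((yo - yhat) ** 2))
            Kt = K @ t
            alpha = float(t @ Kt)
            K = (
                K
                - np.outer(t, Kt) / tt
                - np.outer(Kt, t) / tt
                + np.outer(t, t) * (alpha / tt**2)
            )
            M1 = M - np.outer(t_o, Kt) / tt
            M = M1 - np.outer(M1 @ t, t) / tt
            r = r - ca * t
    rmsecv = np.sqrt(sq / n)
    best_k = int(np.argmin(rmsecv)) + 1  # argmin returns the smallest tie
    return CVResult(rmsecv_by_k=rmsecv, best_k=best_k)


class PLS1RegressionCV(RegressorMixin, BaseEstimator):
    """PLS1 with the factor count chosen by grouped leave-one-out CV.

    ``fit(X, y, groups=...)`` runs :func:`loocv_select` and refits a
    :class:`PLS1Regression` with the winning factor count on all rows.

    Attributes
    ----------
    rmsecv_ : RMSECV profile over k = 1..k_cap.
    best_k_ : chosen factor count.
    model_ : the refitted :class:`PLS1Regression`.
    """

    def __init__(self, max_components: int = 20, tol: float = _EARLY_STOP_TOL):
        self.max_components = max_components
        self.tol = tol

    def fit(self, X, y, groups=None):
        cv = loocv_select(X, y, groups=groups, k_max=self.max_components, tol=self.tol)
        self.rmsecv_ = cv.rmsecv_by_k
        self.best_k_ = cv.best_k
        self.model_ = PLS1Regression(n_components=cv.best_k, tol=self.tol).fit(X, y)
        self.n_components_ = self.model_.n_components_
        self.n_features_in_ = self.model_.n_features_in_
        return self

    def predict(self, X):
        return self.model_.predict(X)


def fit_pls1(X, y, k: int) -> PLS1Regression:
    """Thin functional wrapper: NIPALS PLS1 with ``k`` latent factors."""
    return PLS1Regression(n_components=k).fit(X, y)


def predict(model: PLS1Regression, X) -> np.ndarray:
    """Thin functional wrapper around :meth:`PLS1Regression.predict`."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# flat text serialization (reproducibility snapshots)
# ---------------------------------------------------------------------------


def save_model(model: PLS1Regression, path: str | Path) -> None:
    """Write centring constants, regression vector and factor count."""
    lines = [
        f"n_components = {model.n_components_}",
        f"y_mean = {model.y_mean_!r}",
        "x_mean = " + " ".join(repr(float(v)) for v in model.x_mean_),
        "coef = " + " ".join(repr(float(v)) for v in model.coef_),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> PLS1Regression:
    """Rebuild a predictor from :func:`save_model` output."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition("=")
        fields[key.strip()] = val.strip()
    m = PLS1Regression(n_components=max(1, int(fields["n_components"])))
    m.n_components_ = int(fields["n_components"])
    m.y_mean_ = float(fields["y_mean"])
    m.x_mean_ = np.array([float(v) for v in fields["x_mean"].split()])
    m.coef_ = np.array([float(v) for v in fields["coef"].split()])
    m.n_features_in_ = m.coef_.size
    return m


__all__ = [
    "CVResult",
    "ModelMetrics",
    "PLS1Regression",
    "PLS1RegressionCV",
    "fit_pls1",
    "load_model",
    "predict",
    "loocv_select",
    "r_squared",
    "rmse",
    "save_model",
]
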