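"""Variable selection for multivariate calibration.

Three strategies reduce the feature set (to ~40% by default) before PLS:

* STD  - keep the columns with the largest across-sample standard deviation;
* CORR - keep the columns with the largest absolute Pearson correlation
         with the dependent variable;
* CHEM - keep the columns whose effective wavenumber falls inside closed
         windows around chemically informative absorption bands
         (default 600-1500, 1600-1800, 2850-3050 and 3400-3500 cm-1:
         fingerprint, C=O ester, C-H stretch and O-H stretch regions).

STD and CORR statistics are computed on calibration rows only by default
(``selection_scope='calibration'``), so no validation information leaks
into the selection.  Ties are broken toward the lower wavenumber index
and the retained count is round-half-away-from-zero of fraction*q,
with a floor of one column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    EmptySelectionError,
    OilspecError,
    UninformativeResponseError,
)
from .preprocess import FeatureMatrix

METHODS = ("STD", "CORR", "CHEM")

#: closed wavenumber windows of chemically informative absorption, cm-1
DEFAULT_CHEM_WINDOWS: tuple[tuple[float, float], ...] = (
    (600.0, 1500.0),
    (1600.0, 1800.0),
    (2850.0, 3050.0),
    (3400.0, 3500.0),
)


@dataclass(frozen=True)
class SelectionSpec:
    method: str = "STD"
    fraction: float = 0.4
    chem_windows: tuple[tuple[float, float], ...] = DEFAULT_CHEM_WINDOWS

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise OilspecError(f"unknown selection method {self.method!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise OilspecError("fraction must be in (0, 1]")
        object.__setattr__(
            self, "chem_windows", tuple((float(a), float(b)) for a, b in self.chem_windows)
        )
        prev_hi = -math.inf
        for lo, hi in self.chem_windows:
            if not lo <= hi or lo <= prev_hi:
                raise OilspecError("chem windows must be increasing and non-overlapping")
            prev_hi = hi


@dataclass
class SelectionResult:
    indices: np.ndarray
    spec: SelectionSpec = field(default_factory=SelectionSpec)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise EmptySelectionError("empty selection")
        if idx.size != np.unique(idx).size:
            raise OilspecError("selection indices must be unique")
        self.indices = np.sort(idx)


def _retain_count(fraction: float, q: int) -> int:
    # round half away from zero, floor of one
    return max(1, int(math.floor(fraction * q + 0.5)))


def _top_k(score: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lower index."""
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:k])


def select_by_std(F_cal: FeatureMatrix, fraction: float = 0.4) -> SelectionResult:
    """Keep the fraction of columns with the largest standard deviation."""
    X = F_cal.features
    if X.shape[0] < 2:
        raise OilspecError("STD selection needs >= 2 calibration rows")
    sd = X.std(axis=0, ddof=1)
    idx = _top_k(sd, _retain_count(fraction, X.shape[1]))
    return SelectionResult(idx, SelectionSpec("STD", fraction))


def select_by_corr(
    F_cal: FeatureMatrix, y_cal: np.ndarray, fraction: float = 0.4
) -> SelectionResult:
    """Keep the fraction of columns most correlated (|Pearson r|) with y."""
    X = F_cal.features
    y = np.asarray(y_cal, dtype=float)
    if X.shape[0] < 3:
        raise OilspecError("CORR selection needs >= 3 calibration rows")
    if y.shape[0] != X.shape[0]:
        raise OilspecError("y_cal length must match calibration rows")
    yc = y - y.mean()
    sy = np.sqrt(np.sum(yc**2))
    if sy == 0.0:
        raise UninformativeResponseError("uninformative response: constant y")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    r = np.zeros(X.shape[1])
    ok = sx > 0
    r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    idx = _top_k(np.abs(r), _retain_count(fraction, X.shape[1]))
    return SelectionResult(idx, SelectionSpec("CORR", fraction))


def select_by_chem(
    feature_axis: np.ndarray,
    windows: tuple[tuple[float, float], ...] = DEFAULT_CHEM_WINDOWS,
) -> SelectionResult:
    """Keep every feature whose wavenumber lies in a closed chem window."""
    axis = np.asarray(feature_axis, dtype=float)
    if axis.size == 0:
        raise OilspecError("empty feature axis")
    spec = SelectionSpec("CHEM", chem_windows=tuple(windows))
    keep = np.zeros(axis.size, dtype=bool)
    for lo, hi in spec.chem_windows:
        keep |= (axis >= lo) & (axis <= hi)
    if not keep.any():
        raise EmptySelectionError("empty selection: no feature inside any chem window")
    return SelectionResult(np.flatnonzero(keep), spec)


def apply_selection(F: FeatureMatrix, result: SelectionResult) -> FeatureMatrix:
    """Subset a feature matrix to the selected columns (ascending order)."""
    idx = result.indices
    if idx.min() < 0 or idx.max() >= F.n_features:
        raise OilspecError("selection index out of range for feature matrix")
    return FeatureMatrix(F.features[:, idx], F.feature_axis[idx], F.provenance)


class VariableSelector(TransformerMixin, BaseEstimator):
    """Scikit-learn style wrapper around the three selection strategies.

    Parameters
    ----------
    method : 'STD' | 'CORR' | 'CHEM'
    fraction : retained fraction of columns for STD/CORR (default 0.4).
    chem_windows : closed wavenumber intervals for CHEM.

    ``fit`` expects calibration rows only; pass ``feature_axis`` for CHEM
    and ``y`` for CORR.  After fitting, ``indices_`` and ``support_`` hold
    the retained columns.
    """

    def __init__(
        self,
        method: str = "STD",
        fraction: float = 0.4,
        chem_windows: tuple[tuple[float, float], ...] = DEFAULT_CHEM_WINDOWS,
    ):
        self.method = method
        self.fraction = fraction
        self.chem_windows = chem_windows

    def fit(self, X, y=None, feature_axis=None):
        X = np.asarray(X, dtype=float)
        fm = FeatureMatrix(
            X,
            np.arange(X.shape[1], dtype=float) if feature_axis is None else feature_axis,
        )
        if self.method == "STD":
            res = select_by_std(fm, self.fraction)
        elif self.method == "CORR":
            if y is None:
                raise OilspecError("CORR selection requires y")
            res = select_by_corr(fm, y, self.fraction)
        elif self.method == "CHEM":
            if feature_axis is None:
                raise OilspecError("CHEM selection requires feature_axis")
            res = select_by_chem(fm.feature_axis, self.chem_windows)
        else:
            raise OilspecError(f"unknown selection method {self.method!r}")
        self.indices_ = res.indices
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[res.indices] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise OilspecError("feature count mismatch in transform")
        return X[:, self.indices_]


__all__ = [
    "DEFAULT_CHEM_WINDOWS",
    "METHODS",
    "SelectionResult",
    "SelectionSpec",
    "VariableSelector",
    "apply_selection",
    "select_by_chem",
    "select_by_corr",
    "select_by_std",
]
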