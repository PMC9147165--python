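"""Spectral preprocessing: the 15 spectral variants plus a random-data control.

Each variant is a base transform (raw, vector normalisation, standard
normal variate, or one half of a single-level Haar wavelet transform)
optionally followed by a first or second finite-difference derivative.
The random-data control replaces the whole feature matrix with seeded
standard-normal noise of the same shape and is used as a null against
chance correlations.

The composition order is fixed: base transform first, then derivative
("first derivative of normalized spectral data").

Transformers follow the scikit-learn fit/transform protocol and are
stateless row-wise operations; axis-changing transforms additionally
expose ``transform_axis`` so the effective wavenumber of every feature is
tracked (needed by window-based variable selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateSpectrumError, IrregularGridError, OilspecError
from .spectra import SpectraMatrix, _check_axis

BASES = ("RAW", "NOR", "SNV", "WA", "WD", "RANDOM")


@dataclass(frozen=True)
class PreprocessSpec:
    """One preprocessing variant: a base transform plus a derivative order."""

    base: str = "RAW"
    derivative: int = 0

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise OilspecError(f"unknown base transform {self.base!r}")
        if self.derivative not in (0, 1, 2):
            raise OilspecError("derivative order must be 0, 1 or 2")
        if self.base == "RANDOM" and self.derivative != 0:
            raise OilspecError("RANDOM control admits no derivative")

    @property
    def code(self) -> str:
        """Reporting code: RAW, D1, D2, NOR, NOR+D1, ... SNV+D2, WA, ... RANDOM."""
        if self.derivative == 0:
            return self.base
        if self.base == "RAW":
            return f"D{self.derivative}"
        return f"{self.base}+D{self.derivative}"

    @classmethod
    def from_code(cls, code: str) -> "PreprocessSpec":
        if code in ("D1", "D2"):
            return cls(base="RAW", derivative=int(code[1]))
        base, _, dpart = code.partition("+")
        if dpart:
            if not dpart.startswith("D"):
                raise OilspecError(f"bad preprocess code {code!r}")
            return cls(base=base, derivative=int(dpart[1:]))
        return cls(base=base, derivative=0)


#: the 16 valid variants in reporting order (15 spectral + random control)
VARIANTS: tuple[PreprocessSpec, ...] = tuple(
    PreprocessSpec(b, d) for b in ("RAW", "NOR", "SNV", "WA", "WD") for d in (0, 1, 2)
) + (PreprocessSpec("RANDOM", 0),)

VARIANT_CODES: tuple[str, ...] = tuple(v.code for v in VARIANTS)


@dataclass
class FeatureMatrix:
    """Transformed spectra ready for selection and PLS.

    ``feature_axis`` carries the effective wavenumber of each column so
    chemically motivated window selection stays meaningful after
    derivatives or wavelet compression.
    """

    features: np.ndarray
    feature_axis: np.ndarray
    provenance: PreprocessSpec = field(default_factory=PreprocessSpec)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.feature_axis = np.asarray(self.feature_axis, dtype=float)
        if self.features.ndim != 2:
            raise OilspecError("features must be 2-D")
        if self.features.shape[1] != self.feature_axis.size:
            raise OilspecError("feature_axis length must equal feature count")
        if self.feature_axis.size >= 2 and np.any(np.diff(self.feature_axis) <= 0):
            raise OilspecError("feature_axis must be strictly increasing")
        if self.features.size and not np.all(np.isfinite(self.features)):
            raise OilspecError("non-finite features")

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


# ---------------------------------------------------------------------------
# row operations
# ---------------------------------------------------------------------------


def normalize_row(x: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm."""
    x = np.asarray(x, dtype=float)
    nrm = np.linalg.norm(x)
    if nrm == 0.0:
        raise DegenerateSpectrumError("degenerate spectrum: all-zero row")
    return x / nrm


def snv_row(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale to unit sd (n-1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSpectrumError("degenerate spectrum: need >= 2 points for SNV")
    sd = np.std(x, ddof=1)
    if sd == 0.0:
        raise DegenerateSpectrumError("degenerate spectrum: constant row")
    return (x - np.mean(x)) / sd


def derivative_row(
    x: np.ndarray, axis: np.ndarray, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """First differences on a uniform grid, applied ``order`` times.

    Returns the derivative and its effective axis (pairwise midpoints for
    order 1, the interior points for order 2).
    """
    x = np.asarray(x, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if order not in (1, 2):
        raise OilspecError("derivative order must be 1 or 2")
    if x.size < order + 1:
        raise OilspecError(f"need >= {order + 1} points for order-{order} derivative")
    h = _check_axis(axis)
    d = x
    a = axis
    for _ in range(order):
        d = np.diff(d) / h
        a = 0.5 * (a[:-1] + a[1:])
    return d, a


def haar_row(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-level Haar transform: (approximation, detail) coefficients.

    a_i = (x_{2i} + x_{2i+1}) / sqrt(2), d_i = (x_{2i} - x_{2i+1}) / sqrt(2);
    odd lengths are extended by repeating the last point.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise OilspecError("need >= 2 points for the Haar transform")
    approx, detail = pywt.dwt(x, "haar", mode="constant")
    return approx, detail


def haar_axis(axis: np.ndarray) -> np.ndarray:
    """Effective wavenumbers of single-level Haar coefficients.

    Pairwise midpoints; the padded pair of an odd-length axis is placed at
    ``axis[-1] + h/2`` so the result stays uniformly spaced (2h).
    """
    axis = np.asarray(axis, dtype=float)
    h = _check_axis(axis)
    n_out = (axis.size + 1) // 2
    return axis[0] + h / 2.0 + 2.0 * h * np.arange(n_out)


def random_features(n: int, q: int, seed: int) -> FeatureMatrix:
    """Seeded i.i.d. standard-normal feature matrix (the null control)."""
    if n < 1 or q < 1:
        raise OilspecError("random_features needs n, q >= 1")
    rng = np.random.default_rng(seed)
    return FeatureMatrix(
        features=rng.standard_normal((n, q)),
        feature_axis=np.arange(q, dtype=float),
        provenance=PreprocessSpec("RANDOM", 0),
    )


# ---------------------------------------------------------------------------
# scikit-learn style transformers (row-wise, stateless)
# ---------------------------------------------------------------------------


class _RowTransformer(TransformerMixin, BaseEstimator):
    def fit(self, X, y=None):  # noqa: D102 - stateless
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform_axis(self, axis: np.ndarray) -> np.ndarray:
        return np.asarray(axis, dtype=float)


class RowL2Normalizer(_RowTransformer):
    """Row-wise scaling to unit Euclidean norm ("NOR")."""

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        nrm = np.linalg.norm(X, axis=1)
        if np.any(nrm == 0.0):
            raise DegenerateSpectrumError("degenerate spectrum: all-zero row")
        return X / nrm[:, None]


class StandardNormalVariate(_RowTransformer):
    """Row-wise centring and unit-sd scaling ("SNV", n-1 denominator)."""

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=1, ddof=1)
        if np.any(sd == 0.0):
            raise DegenerateSpectrumError("degenerate spectrum: constant row")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


class FiniteDifference(_RowTransformer):
    """Row-wise finite-difference derivative on a uniform wavenumber grid."""

    def __init__(self, order: int = 1, spacing: float = 1.0):
        self.order = order
        self.spacing = spacing

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.order not in (1, 2):
            raise OilspecError("derivative order must be 1 or 2")
        for _ in range(self.order):
            X = np.diff(X, axis=1) / self.spacing
        return X

    def transform_axis(self, axis):
        axis = np.asarray(axis, dtype=float)
        for _ in range(self.order):
            axis = 0.5 * (axis[:-1] + axis[1:])
        return axis


class HaarWavelet(_RowTransformer):
    """Row-wise single-level Haar transform keeping one coefficient set."""

    def __init__(self, part: str = "approx"):
        self.part = part

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        approx, detail = pywt.dwt(X, "haar", mode="constant", axis=1)
        if self.part == "approx":
            return approx
        if self.part == "detail":
            return detail
        raise OilspecError(f"part must be 'approx' or 'detail', got {self.part!r}")

    def transform_axis(self, axis):
        return haar_axis(axis)


# ---------------------------------------------------------------------------
# variant application
# ---------------------------------------------------------------------------


def apply_preprocess(
    m: SpectraMatrix, spec: PreprocessSpec, seed: int | None = None
) -> FeatureMatrix:
    """Apply one preprocessing variant row-wise to a spectra container.

    The RANDOM control ignores the spectral values but keeps their shape
    and wavenumber axis (so downstream selection behaves identically);
    it requires ``seed``.
    """
    if spec.base == "RANDOM":
        if seed is None:
            raise OilspecError("RANDOM preprocessing requires a seed")
        fm = random_features(m.n_spectra, m.n_points, seed)
        return FeatureMatrix(fm.features, m.axis.copy(), spec)

    X = m.values
    axis = m.axis
    try:
        if spec.base == "NOR":
            X = RowL2Normalizer().fit(X).transform(X)
        elif spec.base == "SNV":
            X = StandardNormalVariate().fit(X).transform(X)
        elif spec.base in ("WA", "WD"):
            hw = HaarWavelet(part="approx" if spec.base == "WA" else "detail")
            X = hw.fit(X).transform(X)
            axis = hw.transform_axis(axis)
        if spec.derivative:
            fd = FiniteDifference(order=spec.derivative, spacing=float(np.diff(axis)[0]))
            X = fd.fit(X).transform(X)
            axis = fd.transform_axis(axis)
    except DegenerateSpectrumError as exc:
        # name the offending container for the grid log
        raise DegenerateSpectrumError(f"{exc} (container {m.technique}/R{m.resolution})") from exc
    return FeatureMatrix(np.ascontiguousarray(X), axis, spec)


__all__ = [
    "BASES",
    "FeatureMatrix",
    "FiniteDifference",
    "HaarWavelet",
    "PreprocessSpec",
    "RowL2Normalizer",
    "StandardNormalVariate",
    "VARIANTS",
    "VARIANT_CODES",
    "apply_preprocess",
    "derivative_row",
    "haar_axis",
    "haar_row",
    "normalize_row",
    "random_features",
    "snv_row",
]
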