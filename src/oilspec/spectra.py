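"""Core data containers and I/O for FT-IR oil-calibration datasets.

A dataset couples absorbance spectra (:class:`SpectraMatrix`, one container
per acquisition technique x nominal resolution) with a per-sample reference
table (:class:`SampleTable`) holding the 13 dependent variables and the
calibration/validation split.

Conventions
-----------
* The wavenumber axis is always stored strictly increasing with uniform
  spacing; files with a descending axis are normalised on read.
* Spectra CSV layout: first column ``wavenumber_cm-1``; one column per
  recorded spectrum named ``<sample_id>|<technique>|R<resolution>|rep<k>``.
* ATR spectra live in 500-4000 cm-1, transmission spectra in 600-4000 cm-1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    InconsistentMetadataError,
    IrregularGridError,
    OilspecError,
    SpectraParseError,
)

TECHNIQUES = ("ATR", "TRANS")
RESOLUTIONS = (2, 4, 8)

#: axis bounds per acquisition technique, cm-1
AXIS_RANGE = {"ATR": (500.0, 4000.0), "TRANS": (600.0, 4000.0)}

FATTY_ACIDS = (
    "palmitic",
    "linoleic",
    "alpha_linolenic",
    "oleic",
    "elaidic",
    "stearic",
)

#: the 13 dependent variables, in the canonical column order
RESPONSES = FATTY_ACIDS + (
    "unsaponifiable_matter",
    "acid_value",
    "saponification_value",
    "ester_value",
    "hydroxyl_value",
    "iodine_value",
    "peroxide_value",
)

_AXIS_RTOL = 1e-6
_COLUMN_RE = re.compile(r"^(?P<sid>[^|]+)\|(?P<tech>ATR|TRANS)\|R(?P<res>\d+)\|rep(?P<rep>\d+)$")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Provenance of one recorded spectrum."""

    sample_id: str
    technique: str
    resolution: int
    replicate: int

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise InconsistentMetadataError(f"unknown technique {self.technique!r}")
        if self.resolution not in RESOLUTIONS:
            raise InconsistentMetadataError(f"unknown resolution {self.resolution!r}")
        if not 1 <= int(self.replicate) <= 3:
            raise InconsistentMetadataError(f"replicate must be 1..3, got {self.replicate}")

    @property
    def column_name(self) -> str:
        return f"{self.sample_id}|{self.technique}|R{self.resolution}|rep{self.replicate}"


def _check_axis(axis: np.ndarray) -> float:
    """Validate a strictly increasing, uniformly spaced axis; return spacing."""
    if axis.ndim != 1 or axis.size < 2:
        raise IrregularGridError("axis must be a 1-D vector with >= 2 points")
    d = np.diff(axis)
    if np.any(d <= 0):
        raise IrregularGridError("irregular grid: axis not strictly increasing")
    h = float(d[0])
    if np.any(np.abs(d - h) > _AXIS_RTOL * abs(h)):
        raise IrregularGridError("irregular grid: non-uniform wavenumber spacing")
    return h


@dataclass
class SpectraMatrix:
    """Aligned absorbance spectra sharing one axis, technique and resolution.

    Parameters
    ----------
    axis : (p,) array of wavenumbers in cm-1, strictly increasing, uniform.
    values : (n, p) array of absorbance, one spectrum per row.
    meta : list of :class:`AcquisitionMeta`, one per row.
    """

    axis: np.ndarray
    values: np.ndarray
    meta: list[AcquisitionMeta]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise OilspecError("values must be a 2-D matrix (n_spectra x p)")
        _check_axis(self.axis)
        if self.values.shape[1] != self.axis.size:
            raise OilspecError(
                f"axis length {self.axis.size} != n columns {self.values.shape[1]}"
            )
        if len(self.meta) != self.values.shape[0]:
            raise OilspecError("one AcquisitionMeta required per spectrum row")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise OilspecError("non-finite absorbance values")
        techs = {m.technique for m in self.meta}
        ress = {m.resolution for m in self.meta}
        if len(techs) > 1 or len(ress) > 1:
            raise InconsistentMetadataError(
                "inconsistent metadata: mixed techniques or resolutions in one matrix"
            )
        if self.meta:
            lo, hi = AXIS_RANGE[self.technique]
            if self.axis[0] < lo - 1e-9 or self.axis[-1] > hi + 1e-9:
                raise OilspecError(
                    f"{self.technique} axis must lie within [{lo:g}, {hi:g}] cm-1"
                )

    # -- convenience ------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.axis.size

    @property
    def technique(self) -> str:
        return self.meta[0].technique

    @property
    def resolution(self) -> int:
        return self.meta[0].resolution

    @property
    def spacing(self) -> float:
        return float(self.axis[1] - self.axis[0])

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]


def read_spectra_table(path: str | Path) -> SpectraMatrix:
    """Read a wide-format spectra CSV into a :class:`SpectraMatrix`.

    The first column is the wavenumber axis; every further column is one
    spectrum whose header encodes ``sample_id|technique|R<res>|rep<k>``.
    A descending axis is accepted and stored ascending.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)  # numerics parsed below, correctly rounded
    if df.shape[1] < 1:
        raise SpectraParseError(f"{path}: no columns")
    cols = list(df.columns)
    parsed: dict[str, np.ndarray] = {}
    for col in cols:
        try:
            parsed[col] = np.asarray(df[col], dtype=float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) + 2  # 1-based, + header line
            raise SpectraParseError(
                f"{path}: non-numeric cell in column {col!r}, file line {row}"
            ) from None
    axis = parsed[cols[0]]
    meta: list[AcquisitionMeta] = []
    for col in cols[1:]:
        m = _COLUMN_RE.match(col)
        if m is None:
            raise SpectraParseError(
                f"{path}: column header {col!r} does not match "
                "'<sample_id>|<technique>|R<resolution>|rep<k>'"
            )
        meta.append(
            AcquisitionMeta(
                sample_id=m.group("sid"),
                technique=m.group("tech"),
                resolution=int(m.group("res")),
                replicate=int(m.group("rep")),
            )
        )
    values = (
        np.column_stack([parsed[c] for c in cols[1:]]).T
        if len(cols) > 1
        else np.empty((0, axis.size))
    )
    if axis.size >= 2 and axis[0] > axis[-1]:  # descending file: normalise
        axis = axis[::-1].copy()
        values = values[:, ::-1].copy()
    return SpectraMatrix(axis=axis, values=values, meta=meta)


def write_spectra_table(m: SpectraMatrix, path: str | Path) -> None:
    """Write a :class:`SpectraMatrix` as wide CSV; round-trips bit-exactly."""
    if m.values.size and not np.all(np.isfinite(m.values)):
        raise OilspecError("refusing to write non-finite absorbance values")
    path = Path(path)
    data = {"wavenumber_cm-1": m.axis}
    for i, am in enumerate(m.meta):
        data[am.column_name] = m.values[i]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def average_replicates(m: SpectraMatrix) -> SpectraMatrix:
    """Average replicate spectra of each sample into one row.

    Rows are grouped by ``sample_id`` (order of first appearance); the
    result carries ``replicate=1`` for every averaged row.
    """
    order: dict[str, list[int]] = {}
    for i, am in enumerate(m.meta):
        order.setdefault(am.sample_id, []).append(i)
    rows = np.empty((len(order), m.n_points))
    meta = []
    for j, (sid, idx) in enumerate(order.items()):
        rows[j] = m.values[idx].mean(axis=0)
        meta.append(replace(m.meta[idx[0]], replicate=1))
    return SpectraMatrix(axis=m.axis.copy(), values=rows, meta=meta)


def validate_resolution(m: SpectraMatrix) -> bool:
    """True iff axis spacing is consistent with the nominal resolution.

    FT-IR point spacing is typically resolution/2, but whole-resolution
    spacing is also accepted; both within 50% relative tolerance.
    """
    h = m.spacing
    res = float(m.resolution)
    return bool(
        abs(h - res) <= 0.5 * res or abs(h - res / 2.0) <= 0.5 * (res / 2.0)
    )


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = ("sample_id", "oil_type") + RESPONSES


@dataclass
class SampleTable:
    """Per-sample oil type, the 13 reference values, and an optional split.

    Wraps a :class:`pandas.DataFrame` with columns ``sample_id``,
    ``oil_type``, the 13 response columns and (optionally) ``split`` taking
    values ``calibration``/``validation``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise OilspecError(f"sample table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise OilspecError("duplicate sample_id in sample table")
        y = df.loc[:, list(RESPONSES)].to_numpy(dtype=float)
        if y.size and not np.all(np.isfinite(y)):
            raise OilspecError("non-finite reference values")
        if y.size and np.any(y < 0):
            raise OilspecError("negative reference values")
        fa = df.loc[:, list(FATTY_ACIDS)].to_numpy(dtype=float)
        if fa.size and np.any(fa > 100):
            raise OilspecError("fatty-acid percentage above 100")
        if self.has_split:
            bad = set(df["split"]) - {"calibration", "validation"}
            if bad:
                raise OilspecError(f"unknown split labels: {sorted(bad)}")
            for oil, grp in df.groupby("oil_type"):
                ncal = int((grp["split"] == "calibration").sum())
                if ncal not in (1, 2):
                    raise OilspecError(
                        f"oil type {oil!r}: {ncal} calibration samples (must be 1 or 2)"
                    )
                if (grp["split"] == "validation").any() and len(grp) < 3:
                    raise OilspecError(
                        f"oil type {oil!r}: validation sample but fewer than 3 samples"
                    )

    @property
    def has_split(self) -> bool:
        return "split" in self.data.columns

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def responses(self, name: str) -> Mapping[str, float]:
        """Map sample_id -> value for one dependent variable."""
        if name not in RESPONSES:
            raise OilspecError(f"unknown dependent variable {name!r}")
        return dict(zip(self.data["sample_id"], self.data[name].astype(float)))

    def split_of(self) -> Mapping[str, str]:
        if not self.has_split:
            raise OilspecError("sample table has no split column")
        return dict(zip(self.data["sample_id"], self.data["split"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        cols = list(_SAMPLE_COLUMNS) + (["split"] if self.has_split else [])
        self.data.loc[:, cols].to_csv(path, index=False)


def assign_split(table: SampleTable, seed: int) -> SampleTable:
    """Assign the oil-type-aware calibration/validation split.

    Per oil type: with <= 2 samples all go to calibration; with >= 3, two
    stay in calibration and the rest are drawn into validation with the
    seeded generator, preferring samples that do not hold the global
    minimum or maximum of any of the 13 dependent variables ("where
    possible"); if too few such samples exist for a type the draw falls
    back to all of that type's samples.
    """
    df = table.data.copy().reset_index(drop=True)
    if len(df) == 0:
        raise OilspecError("empty sample table")
    rng = np.random.default_rng(seed)
    y = df.loc[:, list(RESPONSES)].to_numpy(dtype=float)
    extreme = np.zeros(len(df), dtype=bool)
    for j in range(y.shape[1]):
        extreme |= y[:, j] == y[:, j].min()
        extreme |= y[:, j] == y[:, j].max()
    split = np.array(["calibration"] * len(df), dtype=object)
    # deterministic type order: first appearance
    for oil in dict.fromkeys(df["oil_type"]):
        idx = np.flatnonzero((df["oil_type"] == oil).to_numpy())
        n_val = len(idx) - 2
        if n_val <= 0:
            continue
        eligible = idx[~extreme[idx]]
        pool = eligible if len(eligible) >= n_val else idx
        chosen = rng.choice(pool, size=n_val, replace=False)
        split[np.sort(chosen)] = "validation"
    df["split"] = split
    return SampleTable(df)


__all__ = [
    "AXIS_RANGE",
    "AcquisitionMeta",
    "FATTY_ACIDS",
    "RESOLUTIONS",
    "RESPONSES",
    "SampleTable",
    "SpectraMatrix",
    "TECHNIQUES",
    "assign_split",
    "average_replicates",
    "read_spectra_table",
    "validate_resolution",
    "write_spectra_table",
]
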