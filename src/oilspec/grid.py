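"""Exhaustive model grid over acquisition and processing parameters.

One grid cell fixes six axes - acquisition technique (ATR/TRANS), nominal
resolution (2/4/8 cm-1), replicate handling (three separate spectra or
their average), variable selection (STD/CORR/CHEM), preprocessing variant
(15 spectral + random control) and dependent variable (13 responses) -
and yields one calibrated PLS model with its quality metrics.  The full
grid has 2*3*2*3*16*13 = 7488 cells.

Per cell the pipeline is: optional replicate averaging -> preprocessing
-> variable selection fitted on calibration rows -> leave-one-sample-out
choice of 1..20 latent factors -> final NIPALS PLS1 fit -> metrics on the
calibration and validation sets.  Degenerate cells (constant response,
empty selection, ...) produce a flagged record rather than an exception.

Reporting helpers reproduce the study-style summary tables: percentage
of models exceeding R^2 thresholds per preprocessing variant, percentage
of good models per grouping factor, and the top models per response.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, OilspecError
from .pls import PLS1RegressionCV, ModelMetrics, r_squared, rmse
from .preprocess import PreprocessSpec, VARIANT_CODES, apply_preprocess
from .selection import (
    DEFAULT_CHEM_WINDOWS,
    select_by_chem,
    select_by_corr,
    select_by_std,
)
from .simulate import SyntheticDataset
from .spectra import (
    RESOLUTIONS,
    RESPONSES,
    SampleTable,
    SpectraMatrix,
    TECHNIQUES,
    average_replicates,
)

logger = logging.getLogger(__name__)

REPLICATE_MODES = ("ALL", "AVG")
SELECTION_METHODS = ("STD", "CORR", "CHEM")

MAX_FACTORS = 20
SELECTION_FRACTION = 0.4

#: R^2 thresholds of the variant-comparison summary
DEFAULT_THRESHOLDS = (0.99, 0.95, 0.90, 0.80, 0.70, 0.60, 0.50)


@dataclass(frozen=True)
class ModelConfig:
    """One cell of the model grid."""

    technique: str
    resolution: int
    replicate_mode: str
    selection: str
    preprocess: str  # variant code, e.g. "SNV+D1"
    response: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise OilspecError(f"unknown technique {self.technique!r}")
        if self.resolution not in RESOLUTIONS:
            raise OilspecError(f"unknown resolution {self.resolution!r}")
        if self.replicate_mode not in REPLICATE_MODES:
            raise OilspecError(f"unknown replicate mode {self.replicate_mode!r}")
        if self.selection not in SELECTION_METHODS:
            raise OilspecError(f"unknown selection {self.selection!r}")
        PreprocessSpec.from_code(self.preprocess)  # validates
        if self.response not in RESPONSES:
            raise OilspecError(f"unknown response {self.response!r}")

    @property
    def key(self) -> tuple:
        return (
            self.technique,
            self.resolution,
            self.replicate_mode,
            self.selection,
            self.preprocess,
            self.response,
        )


@dataclass
class ModelRecord:
    """A fitted grid cell: configuration, factor count, metrics, status."""

    config: ModelConfig
    n_factors: int
    metrics: ModelMetrics
    status: str = "ok"  # "ok" | "degenerate"
    note: str = ""

    def to_dict(self) -> dict:
        c, m = self.config, self.metrics
        return {
            "technique": c.technique,
            "resolution": c.resolution,
            "replicate_mode": c.replicate_mode,
            "selection": c.selection,
            "preprocess": c.preprocess,
            "response": c.response,
            "seed": c.seed,
            "n_factors": self.n_factors,
            "rmsecv": m.rmsecv,
            "rmsec": m.rmsec,
            "rmsep": m.rmsep,
            "r2_c": m.r2_c,
            "r2_v": m.r2_v,
            "cal_range_lo": m.calibration_range[0],
            "cal_range_hi": m.calibration_range[1],
            "status": self.status,
            "note": self.note,
        }


RECORD_COLUMNS = (
    "technique",
    "resolution",
    "replicate_mode",
    "selection",
    "preprocess",
    "response",
    "seed",
    "n_factors",
    "rmsecv",
    "rmsec",
    "rmsep",
    "r2_c",
    "r2_v",
    "cal_range_lo",
    "cal_range_hi",
    "status",
    "note",
)


def enumerate_grid(
    responses: Sequence[str] = RESPONSES, seed: int = 0
) -> list[ModelConfig]:
    """Full Cartesian grid in the fixed order technique x resolution x
    replicate mode x selection x preprocessing x response."""
    if not responses:
        raise OilspecError("responses must be non-empty")
    return [
        ModelConfig(t, r, m, s, p, y, seed)
        for t, r, m, s, p, y in itertools.product(
            TECHNIQUES,
            RESOLUTIONS,
            REPLICATE_MODES,
            SELECTION_METHODS,
            VARIANT_CODES,
            responses,
        )
    ]


# ---------------------------------------------------------------------------
# single-cell execution
# ---------------------------------------------------------------------------


def _nan_metrics() -> ModelMetrics:
    nan = float("nan")
    return ModelMetrics(nan, nan, nan, nan, nan, (nan, nan))


def _random_seed_for(seed: int, technique: str, resolution: int, mode: str) -> int:
    # stable small sub-seed per (technique, resolution, replicate-mode) cell
    base = (
        TECHNIQUES.index(technique) * 8
        + RESOLUTIONS.index(resolution) * 2
        + REPLICATE_MODES.index(mode)
    )
    return (int(seed) * 97 + base * 1009 + 17) % (2**31 - 1)


class _GridData:
    """Prepared spectra blocks with memoised preprocessing products."""

    def __init__(
        self,
        spectra: Mapping[tuple[str, int], SpectraMatrix],
        samples: SampleTable,
        seed: int = 0,
        chem_windows=DEFAULT_CHEM_WINDOWS,
        fraction: float = SELECTION_FRACTION,
    ):
        if not samples.has_split:
            raise OilspecError("sample table needs a calibration/validation split")
        self.spectra = dict(spectra)
        self.samples = samples
        self.seed = int(seed)
        self.chem_windows = chem_windows
        self.fraction = fraction
        self._avg: dict = {}
        self._features: dict = {}

    def block(self, technique: str, resolution: int, mode: str) -> SpectraMatrix:
        try:
            m = self.spectra[(technique, resolution)]
        except KeyError:
            raise OilspecError(
                f"no spectra block for ({technique}, R{resolution})"
            ) from None
        if mode == "AVG":
            key = (technique, resolution)
            if key not in self._avg:
                self._avg[key] = average_replicates(m)
            return self._avg[key]
        return m

    def features(self, technique: str, resolution: int, mode: str, code: str):
        key = (technique, resolution, mode, code)
        if key not in self._features:
            m = self.block(technique, resolution, mode)
            spec = PreprocessSpec.from_code(code)
            seed = (
                _random_seed_for(self.seed, technique, resolution, mode)
                if spec.base == "RANDOM"
                else None
            )
            self._features[key] = (apply_preprocess(m, spec, seed=seed), m)
        return self._features[key]


def run_model(
    config: ModelConfig,
    data: SyntheticDataset | _GridData,
    max_factors: int = MAX_FACTORS,
) -> ModelRecord:
    """Execute the full pipeline for one grid cell."""
    if isinstance(data, SyntheticDataset):
        data = _GridData(data.spectra, data.samples, seed=config.seed)
    try:
        F, m = data.features(
            config.technique, config.resolution, config.replicate_mode, config.preprocess
        )
        sids = m.sample_ids
        split = data.samples.split_of()
        ymap = data.samples.responses(config.response)
        cal = np.array([split[s] == "calibration" for s in sids])
        val = ~cal
        y_rows = np.array([ymap[s] for s in sids], dtype=float)
        X_cal = F.features[cal]
        y_cal = y_rows[cal]
        groups = [s for s, c in zip(sids, cal) if c]

        if config.selection == "STD":
            sel = select_by_std(
                _subset_fm(F, cal), fraction=data.fraction
            )
        elif config.selection == "CORR":
            sel = select_by_corr(_subset_fm(F, cal), y_cal, fraction=data.fraction)
        else:
            sel = select_by_chem(F.feature_axis, windows=data.chem_windows)
        Xs_cal = X_cal[:, sel.indices]
        Xs_val = F.features[val][:, sel.indices]
        y_val = y_rows[val]

        est = PLS1RegressionCV(max_components=max_factors).fit(
            Xs_cal, y_cal, groups=groups
        )
        yhat_cal = est.predict(Xs_cal)
        yhat_val = est.predict(Xs_val)
        metrics = ModelMetrics(
            r2_c=r_squared(y_cal, yhat_cal),
            r2_v=r_squared(y_val, yhat_val) if y_val.size >= 2 else float("nan"),
            rmsec=rmse(y_cal, yhat_cal),
            rmsecv=float(est.rmsecv_[est.best_k_ - 1]),
            rmsep=rmse(y_val, yhat_val) if y_val.size else float("nan"),
            calibration_range=(float(y_cal.min()), float(y_cal.max())),
        )
        return ModelRecord(config, n_factors=est.n_components_, metrics=metrics)
    except DegenerateInputError as exc:
        return ModelRecord(
            config, n_factors=0, metrics=_nan_metrics(), status="degenerate", note=str(exc)
        )


def _subset_fm(F, mask):
    from .preprocess import FeatureMatrix

    return FeatureMatrix(F.features[mask], F.feature_axis, F.provenance)


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------


def run_grid(
    configs: Iterable[ModelConfig],
    data: SyntheticDataset | _GridData,
    out_path: str | Path | None = None,
    resume: bool = True,
    log_every: int = 500,
) -> pd.DataFrame:
    """Run every configuration; results are order-independent.

    With ``out_path`` the records are checkpointed to CSV as the run
    proceeds; an existing file is treated as a partial result and only
    the remaining configurations are executed (``resume=True``).
    """
    configs = list(configs)
    if isinstance(data, SyntheticDataset):
        seed = configs[0].seed if configs else 0
        data = _GridData(data.spectra, data.samples, seed=seed)
    done: dict[tuple, dict] = {}
    out_path = Path(out_path) if out_path is not None else None
    if out_path is not None and out_path.exists() and resume:
        prev = pd.read_csv(out_path, keep_default_na=True)
        for _, row in prev.iterrows():
            key = (
                row["technique"],
                int(row["resolution"]),
                row["replicate_mode"],
                row["selection"],
                row["preprocess"],
                row["response"],
            )
            done[key] = row.to_dict()
        logger.info("resuming: %d of %d records already present", len(done), len(configs))

    records: list[dict] = []
    n_new = 0
    for i, cfg in enumerate(configs):
        if cfg.key in done:
            records.append(done[cfg.key])
            continue
        rec = run_model(cfg, data).to_dict()
        records.append(rec)
        n_new += 1
        if out_path is not None and n_new % log_every == 0:
            pd.DataFrame(records, columns=RECORD_COLUMNS).to_csv(out_path, index=False)
        if (i + 1) % log_every == 0:
            logger.info("grid progress: %d / %d", i + 1, len(configs))
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def _ok(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["status"] == "ok"]


def threshold_summary(
    records: pd.DataFrame, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Percent of models with R^2 at or above each threshold, per
    preprocessing variant and R^2 type (inclusive boundaries)."""
    ok = _ok(records)
    if len(ok) == 0:
        raise OilspecError("no successful records to summarise")
    rows = []
    for code in [c for c in VARIANT_CODES if c in set(ok["preprocess"])]:
        grp = ok[ok["preprocess"] == code]
        for r2col, label in (("r2_c", "r2_c"), ("r2_v", "r2_v")):
            vals = grp[r2col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row = {"preprocess": code, "r2_type": label, "n_models": len(vals)}
            for thr in thresholds:
                pct = 100.0 * float(np.mean(vals >= thr)) if len(vals) else float("nan")
                row[f">={thr:g}"] = pct
            rows.append(row)
    return pd.DataFrame(rows)


_FACTOR_LEVELS = (
    ("technique", "ATR"),
    ("technique", "TRANS"),
    ("resolution", 2),
    ("resolution", 4),
    ("resolution", 8),
    ("replicate_mode", "ALL"),
    ("replicate_mode", "AVG"),
    ("selection", "STD"),
    ("selection", "CORR"),
    ("selection", "CHEM"),
)


def good_model_summary(
    records: pd.DataFrame, criteria: Sequence[float] = (0.9, 0.5)
) -> pd.DataFrame:
    """Percent of models whose calibration AND validation R^2 both reach a
    criterion, per response and grouping-factor level.

    The random-data control is excluded: this table compares spectral
    acquisition/processing choices.  Empty groups are flagged through
    ``n_models = 0`` (percent 0).
    """
    ok = _ok(records)
    ok = ok[ok["preprocess"] != "RANDOM"]
    rows = []
    for response in [r for r in RESPONSES if r in set(ok["response"])]:
        sub = ok[ok["response"] == response]
        for crit in criteria:
            for col, level in _FACTOR_LEVELS:
                grp = sub[sub[col] == level]
                both = (grp["r2_c"] >= crit) & (grp["r2_v"] >= crit)
                rows.append(
                    {
                        "response": response,
                        "criterion": crit,
                        "factor": col,
                        "level": str(level),
                        "percent": 100.0 * float(both.mean()) if len(grp) else 0.0,
                        "n_models": int(len(grp)),
                    }
                )
    return pd.DataFrame(rows)


def best_models(records: pd.DataFrame, top_n: int = 3) -> pd.DataFrame:
    """Top models per response: descending validation R^2, then ascending
    RMSEP, then ascending factor count."""
    ok = _ok(records).copy()
    ok = ok[np.isfinite(ok["r2_v"].astype(float))]
    out = []
    for response in [r for r in RESPONSES if r in set(ok["response"])]:
        sub = ok[ok["response"] == response].sort_values(
            by=["r2_v", "rmsep", "n_factors"], ascending=[False, True, True]
        )
        out.append(sub.head(top_n))
    if not out:
        return ok.head(0)
    return pd.concat(out, ignore_index=True)


__all__ = [
    "DEFAULT_THRESHOLDS",
    "MAX_FACTORS",
    "ModelConfig",
    "ModelRecord",
    "RECORD_COLUMNS",
    "REPLICATE_MODES",
    "SELECTION_METHODS",
    "best_models",
    "enumerate_grid",
    "good_model_summary",
    "run_grid",
    "run_model",
    "threshold_summary",
]
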