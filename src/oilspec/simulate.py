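"""Synthetic vegetable-oil FT-IR datasets.

The generator produces spectra and reference tables with exactly the
statistical structure the calibration pipeline assumes, so every stage
can be exercised end-to-end:

* Beer-Lambert linearity - a sample's noiseless spectrum is the
  composition-weighted sum of pure-component spectra, each a sum of
  Gaussian absorption bands;
* replicate noise - per-replicate multiplicative scatter
  exp(N(0, scatter_sd)), a random low-order polynomial baseline, and
  additive white noise whose sd grows at finer resolution (more
  points, less co-added signal per point);
* an acquisition-mode contrast - ATR spectra receive a smooth
  1/wavenumber attenuation envelope (a penetration-depth proxy) and
  extend down to 500 cm-1, transmission spectra to 600 cm-1;
* responses with tunable spectral linkage - fatty-acid contents are the
  composition itself and the iodine value is a fixed linear functional
  of it (fully spectrum-determined), whereas the pharmacopoeial values
  mix a composition-derived signal with independent noise according to
  a linkage weight in [0, 1].  With the default linkage map the
  unsaturation-related responses are recoverable from the spectra and
  the peroxide/acid-type values essentially are not, emulating which
  oil-quality parameters infrared calibration can and cannot predict.

The default design emulates the study scale: 17 oil types with one to
four samples each (37 samples), three replicate spectra per sample, two
acquisition techniques and three nominal resolutions (point spacing =
resolution/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import OilspecError
from .spectra import (
    AXIS_RANGE,
    AcquisitionMeta,
    FATTY_ACIDS,
    RESPONSES,
    SampleTable,
    SpectraMatrix,
    assign_split,
)

COMPONENTS = FATTY_ACIDS + ("unsaponifiable", "hydroperoxide")


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: amplitude * exp(-(v-center)^2 / 2 width^2)."""

    center: float  # cm-1
    width: float  # Gaussian sigma, cm-1
    amplitude: float  # absorbance, a.u.

    def __post_init__(self) -> None:
        if self.width <= 0 or self.amplitude < 0:
            raise OilspecError("band width must be > 0 and amplitude >= 0")


#: iodine value contributed per % of each component (generator definition:
#: chosen so a pure unsaturated acid lands at textbook iodine magnitudes)
IODINE_COEFFICIENTS: dict[str, float] = {
    "palmitic": 0.0,
    "stearic": 0.0,
    "oleic": 0.90,
    "elaidic": 0.90,
    "linoleic": 1.81,
    "alpha_linolenic": 2.74,
    "unsaponifiable": 0.0,
    "hydroperoxide": 0.0,
}


def _acyl_backbone(ch2: float = 1.0) -> list[BandSpec]:
    """Bands shared by all acyl chains; ch2 scales the CH2-stretch envelope."""
    return [
        BandSpec(2855.0, 15.0, 0.80 * ch2),  # sym CH2 stretch
        BandSpec(2925.0, 18.0, 1.00 * ch2),  # asym CH2 stretch
        BandSpec(2956.0, 10.0, 0.30),  # CH3 stretch
        BandSpec(1745.0, 12.0, 1.00),  # ester C=O
        BandSpec(1463.0, 14.0, 0.30),  # CH2 scissoring
        BandSpec(1377.0, 10.0, 0.15),  # CH3 umbrella
        BandSpec(1160.0, 20.0, 0.50),  # C-O stretch
        BandSpec(1100.0, 15.0, 0.20),
        BandSpec(722.0, 10.0, 0.18),  # CH2 rocking
    ]


def default_library() -> dict[str, list[BandSpec]]:
    """Built-in component band library.

    Unsaturated acyl components carry a cis =C-H stretch near 3010 cm-1
    whose amplitude grows with double-bond count, plus C=C stretch near
    1655 cm-1; the trans isomer instead shows the 966 cm-1 out-of-plane
    bend.  Small component-specific fingerprint bands keep the pure
    spectra linearly independent.
    """
    lib: dict[str, list[BandSpec]] = {
        "palmitic": _acyl_backbone(1.10) + [BandSpec(1120.0, 8.0, 0.12)],
        "stearic": _acyl_backbone(1.15) + [BandSpec(1068.0, 8.0, 0.12)],
        "oleic": _acyl_backbone(1.00)
        + [
            BandSpec(3008.0, 12.0, 0.14),
            BandSpec(1655.0, 9.0, 0.06),
            BandSpec(1085.0, 8.0, 0.10),
        ],
        "elaidic": _acyl_backbone(1.00)
        + [
            BandSpec(3002.0, 12.0, 0.10),
            BandSpec(1668.0, 9.0, 0.05),
            BandSpec(966.0, 9.0, 0.45),  # trans =C-H bend
        ],
        "linoleic": _acyl_backbone(0.92)
        + [
            BandSpec(3010.0, 12.0, 0.28),
            BandSpec(1655.0, 9.0, 0.10),
            BandSpec(914.0, 8.0, 0.10),
        ],
        "alpha_linolenic": _acyl_backbone(0.85)
        + [
            BandSpec(3012.0, 12.0, 0.42),
            BandSpec(1656.0, 9.0, 0.15),
            BandSpec(868.0, 8.0, 0.10),
        ],
        "unsaponifiable": [
            BandSpec(3450.0, 60.0, 0.50),  # O-H stretch, broad
            BandSpec(1630.0, 15.0, 0.10),
            BandSpec(1050.0, 25.0, 0.40),
        ],
        "hydroperoxide": [
            BandSpec(3445.0, 50.0, 0.60),  # O-O-H stretch
            BandSpec(880.0, 15.0, 0.30),  # O-O stretch
        ],
    }
    return lib


def library_to_yaml(lib: Mapping[str, Sequence[BandSpec]], path: str | Path) -> None:
    data = {
        name: [[b.center, b.width, b.amplitude] for b in bands]
        for name, bands in lib.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def library_from_yaml(path: str | Path) -> dict[str, list[BandSpec]]:
    data = yaml.safe_load(Path(path).read_text())
    return {
        name: [BandSpec(*map(float, row)) for row in bands]
        for name, bands in data.items()
    }


def component_spectrum(bands: Sequence[BandSpec], axis: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the wavenumber axis."""
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for b in bands:
        out += b.amplitude * np.exp(-((axis - b.center) ** 2) / (2.0 * b.width**2))
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: samples per oil type in the default 17-type design (sums to 37)
DEFAULT_TYPE_COUNTS: tuple[int, ...] = (3, 2, 4, 2, 3, 3, 1, 2, 2, 4, 2, 2, 1, 1, 1, 1, 3)

#: spectral linkage per response: 1 = fully spectrum-determined
DEFAULT_LINKAGE: dict[str, float] = {
    **{fa: 1.0 for fa in FATTY_ACIDS},
    "iodine_value": 1.0,
    "unsaponifiable_matter": 0.8,
    "acid_value": 0.1,
    "saponification_value": 0.1,
    "ester_value": 0.1,
    "hydroxyl_value": 0.1,
    "peroxide_value": 0.1,
}

#: target output ranges (units of each response) for the noise-mixed values
_RESPONSE_RANGES: dict[str, tuple[float, float]] = {
    "unsaponifiable_matter": (0.33, 2.20),
    "acid_value": (0.112, 11.2),
    "saponification_value": (178.0, 196.0),
    "ester_value": (176.0, 194.0),
    "hydroxyl_value": (2.70, 19.4),
    "peroxide_value": (9.29, 123.0),
}

# latent ranges used to standardise composition-derived signals
_UNSAP_RANGE = (0.3, 2.2)  # % unsaponifiable component
_MARKER_RANGE = (0.05, 1.2)  # % hydroperoxide marker


@dataclass
class NoiseConfig:
    """Replicate-level instrumental noise magnitudes."""

    additive_sd: float = 0.002  # white noise, a.u., at 8 cm-1 resolution
    baseline_order: int = 2  # polynomial baseline degree
    baseline_sd: float = 0.01  # sd of baseline polynomial coefficients
    scatter_sd: float = 0.05  # log-sd of the multiplicative scatter factor


@dataclass
class SyntheticConfig:
    """Design of a synthetic oil dataset (defaults emulate the study scale)."""

    n_types: int = 17
    type_counts: tuple[int, ...] | None = None  # default: the 17-type pattern
    replicates: int = 3
    techniques: tuple[str, ...] = ("ATR", "TRANS")
    resolutions: tuple[int, ...] = (2, 4, 8)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    linkage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LINKAGE))
    composition_jitter: float = 0.08  # per-sample log-scale jitter of type means
    seed: int = 0

    def resolved_counts(self, rng: np.random.Generator) -> tuple[int, ...]:
        if self.type_counts is not None:
            if len(self.type_counts) != self.n_types:
                raise OilspecError("type_counts length must equal n_types")
            if any(not 1 <= c <= 4 for c in self.type_counts):
                raise OilspecError("samples per type must be 1..4")
            return tuple(self.type_counts)
        if self.n_types == len(DEFAULT_TYPE_COUNTS):
            return DEFAULT_TYPE_COUNTS
        return tuple(int(c) for c in rng.integers(1, 5, size=self.n_types))

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.replicates < 1:
            raise OilspecError("n_types and replicates must be >= 1")
        unknown = set(self.linkage) - set(RESPONSES)
        if unknown:
            raise OilspecError(f"linkage keys not among responses: {sorted(unknown)}")
        for k, v in self.linkage.items():
            if not 0.0 <= v <= 1.0:
                raise OilspecError(f"linkage[{k!r}] must be in [0, 1]")


# Dirichlet concentration of the fatty-acid mean composition across types;
# small values give the wide between-type spread real oil panels show
# (high-linolenic linseed/chia analogues vs high-linoleic seed oils).
_FA_ALPHA = np.array([0.8, 0.5, 1.0, 0.15, 1.2, 1.0])  # palmitic..stearic order below
_FA_ORDER = ("palmitic", "stearic", "oleic", "elaidic", "linoleic", "alpha_linolenic")


def _scale01(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def derive_quality_values(
    composition: Mapping[str, float],
    linkage: Mapping[str, float],
    rng: np.random.Generator,
) -> dict[str, float]:
    """The 13 reference values implied by one sample's composition.

    Fatty-acid contents equal the composition; the iodine value is the
    composition-weighted sum of the iodine coefficients; every other
    response is ``linkage * signal + (1 - linkage) * uniform noise``
    mapped into its plausible pharmacopoeial range, where ``signal`` is a
    fixed linear functional of the composition/marker levels.
    """
    comp = {k: float(composition[k]) for k in COMPONENTS}
    total = sum(comp.values())
    if abs(total - 100.0) > 1e-6:
        raise OilspecError(f"composition must sum to 100, got {total}")
    y: dict[str, float] = {fa: comp[fa] for fa in FATTY_ACIDS}
    y["iodine_value"] = sum(comp[c] * IODINE_COEFFICIENTS[c] for c in COMPONENTS)

    unsap01 = float(_scale01(np.array(comp["unsaponifiable"]), *_UNSAP_RANGE))
    marker01 = float(_scale01(np.array(comp["hydroperoxide"]), *_MARKER_RANGE))
    sat01 = float(np.clip((comp["palmitic"] + comp["stearic"]) / 40.0, 0.0, 1.0))
    signals = {
        "unsaponifiable_matter": unsap01,
        "acid_value": marker01,
        "saponification_value": sat01,
        "ester_value": 1.0 - 0.5 * marker01 - 0.5 * unsap01,
        "hydroxyl_value": 0.5 * unsap01 + 0.5 * marker01,
        "peroxide_value": marker01,
    }
    for name, (lo, hi) in _RESPONSE_RANGES.items():
        lam = float(linkage.get(name, 1.0))
        mix = lam * signals[name] + (1.0 - lam) * float(rng.uniform())
        y[name] = lo + (hi - lo) * mix
    return y


def _axis_for(technique: str, resolution: int) -> np.ndarray:
    lo, hi = AXIS_RANGE[technique]
    h = resolution / 2.0
    n = int(round((hi - lo) / h)) + 1
    return lo + h * np.arange(n)


@dataclass
class SyntheticDataset:
    """Bundle of spectra blocks, the sample table and the latent truth."""

    spectra: dict[tuple[str, int], SpectraMatrix]
    samples: SampleTable
    ground_truth: pd.DataFrame  # per-sample composition and latent signals


def simulate_dataset(
    cfg: SyntheticConfig,
    library: Mapping[str, Sequence[BandSpec]] | None = None,
) -> SyntheticDataset:
    """Generate a full synthetic dataset (all technique x resolution blocks).

    All randomness derives from ``cfg.seed``; the calibration/validation
    split is assigned with the oil-type-aware seeded rule.
    """
    lib = dict(library) if library is not None else default_library()
    missing = set(COMPONENTS) - set(lib)
    if missing:
        raise OilspecError(f"band library missing components: {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed)
    counts = cfg.resolved_counts(rng)

    # --- latent composition design ------------------------------------
    rows = []
    sample_no = 0
    for t, count in enumerate(counts):
        oil = f"oil_type_{t + 1:02d}"
        unsap = rng.uniform(*_UNSAP_RANGE)
        marker = rng.uniform(*_MARKER_RANGE)
        fa_mean = rng.dirichlet(_FA_ALPHA) * (100.0 - unsap - marker)
        type_mean = dict(zip(_FA_ORDER, fa_mean))
        type_mean["unsaponifiable"] = unsap
        type_mean["hydroperoxide"] = marker
        for _ in range(count):
            sample_no += 1
            jit = np.exp(rng.normal(0.0, cfg.composition_jitter, size=len(COMPONENTS)))
            vec = np.array([type_mean[c] for c in COMPONENTS]) * jit
            vec = vec / vec.sum() * 100.0
            comp = dict(zip(COMPONENTS, vec))
            y = derive_quality_values(comp, cfg.linkage, rng)
            rows.append(
                {"sample_id": f"s{sample_no:02d}", "oil_type": oil, **comp, **y}
            )
    truth = pd.DataFrame(rows)
    sample_df = truth.loc[:, ["sample_id", "oil_type", *RESPONSES]].copy()
    samples = assign_split(
        SampleTable(sample_df), seed=int(rng.integers(0, 2**31 - 1))
    )

    # --- spectra blocks ------------------------------------------------
    comp_frac = truth.loc[:, list(COMPONENTS)].to_numpy(dtype=float) / 100.0
    spectra: dict[tuple[str, int], SpectraMatrix] = {}
    for technique in cfg.techniques:
        for resolution in cfg.resolutions:
            axis = _axis_for(technique, resolution)
            C = np.stack([component_spectrum(lib[c], axis) for c in COMPONENTS])
            clean = comp_frac @ C
            if technique == "ATR":
                clean = clean * (2000.0 / axis)  # penetration-depth proxy
            add_sd = cfg.noise.additive_sd * np.sqrt(8.0 / resolution)
            xnorm = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0
            vand = np.vander(xnorm, cfg.noise.baseline_order + 1, increasing=True)
            n_rows = len(truth) * cfg.replicates
            values = np.empty((n_rows, axis.size))
            meta = []
            i = 0
            for s_idx, sid in enumerate(truth["sample_id"]):
                for rep in range(1, cfg.replicates + 1):
                    scatter = np.exp(rng.normal(0.0, cfg.noise.scatter_sd))
                    coeffs = rng.normal(0.0, cfg.noise.baseline_sd, vand.shape[1])
                    noise = rng.normal(0.0, add_sd, axis.size) if add_sd > 0 else 0.0
                    values[i] = clean[s_idx] * scatter + vand @ coeffs + noise
                    meta.append(
                        AcquisitionMeta(
                            sample_id=sid,
                            technique=technique,
                            resolution=resolution,
                            replicate=rep,
                        )
                    )
                    i += 1
            spectra[(technique, resolution)] = SpectraMatrix(
                axis=axis, values=values, meta=meta
            )
    return SyntheticDataset(spectra=spectra, samples=samples, ground_truth=truth)


__all__ = [
    "BandSpec",
    "COMPONENTS",
    "DEFAULT_LINKAGE",
    "DEFAULT_TYPE_COUNTS",
    "IODINE_COEFFICIENTS",
    "NoiseConfig",
    "SyntheticConfig",
    "SyntheticDataset",
    "component_spectrum",
    "default_library",
    "derive_quality_values",
    "library_from_yaml",
    "library_to_yaml",
    "simulate_dataset",
]
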