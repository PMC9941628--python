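"""Synthetic NIR spectra and climate/saponin tables.

The generators emulate the statistical structure of a field study of
*Panax notoginseng* roots: diffuse-reflectance NIR spectra of powdered
root from several geographic origins, scanned in duplicate on a
10000–4000 cm^-1 grid at 4 cm^-1 resolution, and a per-sample table of
screened WorldClim bioclimatic variables with four saponin contents
(notoginsenoside R1 and ginsenosides Rg1/Rb1/Rd, mg/g) tied to the
climate factors by linear regression equations.

Spectra are sums of Gaussian overtone/combination bands at the
characteristic NIR wavenumbers of plant-root matrices (C-H, O-H, N-H
overtones and combinations), plus a linear baseline, a per-replicate
multiplicative scatter gain, and i.i.d. Gaussian noise.  Geographic
classes differ only by small amplitude shifts on designated bands —
differences that are subtle in the raw spectra yet recoverable by the
downstream correlation-image classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd

from .spectra import SpectrumSeries, write_spectra

__all__ = [
    "SpectraSimConfig",
    "ClimateSimConfig",
    "simulate_spectra",
    "simulate_climate_table",
    "write_fixture",
    "SAPONINS",
    "BIO_VARS",
    "EQUATION_COEFFICIENTS",
]

SAPONINS = ("NG-R1", "G-Rg1", "G-Rb1", "G-Rd")

#: climate factors retained by the collinearity screen, WorldClim naming
BIO_VARS = ("Bio1", "Bio4", "Bio7", "Bio12", "Bio14", "Bio15", "Bio17")

#: linear regression coefficients (intercept, then one slope per factor in
#: BIO_VARS order) tying each saponin content (mg/g) to the climate factors
EQUATION_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "NG-R1": (18.806, -0.545, 0.04, -0.505, -0.001, -0.903, 0.133, 0.226),
    "G-Rg1": (197.720, -2.552, -0.043, -4.425, 0.029, -0.927, -0.196, -0.104),
    "G-Rb1": (110.283, -1.221, -0.046, -1.185, 0.037, -1.144, -0.406, -0.141),
    "G-Rd": (38.450, -0.477, 0.012, -0.728, 0.012, -1.055, -0.156, -0.102),
}

#: plausible Yunnan-highland locations/scales for the screened factors
#: (Bio1/Bio7 in degC, Bio4 in 100*degC, Bio12/14/17 in mm, Bio15 in CV %)
_BIO_MEANS = {
    "Bio1": 16.0,
    "Bio4": 450.0,
    "Bio7": 22.0,
    "Bio12": 1100.0,
    "Bio14": 15.0,
    "Bio15": 75.0,
    "Bio17": 60.0,
}
_BIO_SDS = {
    "Bio1": 1.8,
    "Bio4": 55.0,
    "Bio7": 2.0,
    "Bio12": 180.0,
    "Bio14": 6.0,
    "Bio15": 7.0,
    "Bio17": 18.0,
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _default_class_effect(n_classes: int, n_bands: int) -> np.ndarray:
    """Per-class relative amplitude offsets: two designated bands per class
    shifted by +10% / -8%, all other bands untouched."""
    eff = np.zeros((n_classes, n_bands))
    for c in range(n_classes):
        b1 = c % n_bands
        b2 = (c + 2) % n_bands
        eff[c, b1] = 0.10
        eff[c, b2] = -0.08
    return eff


@dataclass
class SpectraSimConfig:
    """Configuration of the spectra simulator (defaults = study conditions)."""

    grid_start: float = 10000.0  # cm^-1, high end
    grid_end: float = 4000.0  # cm^-1, low end
    resolution: float = 4.0  # cm^-1 step
    n_classes: int = 4
    n_per_class: int = 32
    n_replicates: int = 2
    band_centers: tuple[float, ...] = (8320.0, 6800.0, 6356.0, 5168.0, 4756.0, 4300.0)
    band_amplitudes: tuple[float, ...] = (0.25, 0.45, 0.50, 0.95, 0.70, 0.55)
    band_fwhm: float = 120.0  # cm^-1
    class_effect: np.ndarray | None = None  # (n_classes, n_bands) relative offsets
    noise_sd: float = 0.004  # absorbance units
    baseline_slope: float = 1.5e-5  # absorbance per cm^-1
    baseline_offset: float = 0.15
    scatter_sd: float = 0.02  # sd of multiplicative gain (1 + N(0, sd))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.grid_start > self.grid_end > 0):
            raise ValueError("require grid_start > grid_end > 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_classes < 1 or self.n_per_class < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if len(self.band_amplitudes) != len(self.band_centers):
            raise ValueError("one amplitude per band center required")
        if self.class_effect is None:
            self.class_effect = _default_class_effect(
                self.n_classes, len(self.band_centers)
            )
        self.class_effect = np.asarray(self.class_effect, dtype=float)
        if self.class_effect.shape != (self.n_classes, len(self.band_centers)):
            raise ValueError("class_effect must be (n_classes, n_bands)")

    @property
    def grid(self) -> np.ndarray:
        """Descending wavenumber grid, inclusive of grid_start."""
        return np.arange(self.grid_start, self.grid_end - 0.5 * self.resolution,
                         -self.resolution)


def class_mean_spectrum(config: SpectraSimConfig, cls: int) -> np.ndarray:
    """Noise-free mean spectrum of class ``cls`` on the config grid."""
    grid = config.grid
    sigma = config.band_fwhm * _FWHM_TO_SIGMA
    amps = np.asarray(config.band_amplitudes) * (1.0 + config.class_effect[cls])
    bands = amps[:, None] * np.exp(
        -0.5 * ((grid[None, :] - np.asarray(config.band_centers)[:, None]) / sigma) ** 2
    )
    baseline = config.baseline_offset + config.baseline_slope * (grid - config.grid_end)
    return bands.sum(axis=0) + baseline


def simulate_spectra(
    config: SpectraSimConfig,
) -> tuple[list[SpectrumSeries], pd.DataFrame]:
    """Draw the spectra fixture.

    Returns one :class:`SpectrumSeries` per sample (rows = replicate
    scans) and a label table with columns ``sample_id, label, class_index``.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    collection: list[SpectrumSeries] = []
    labels = []
    for c in range(config.n_classes):
        mean = class_mean_spectrum(config, c)
        label = f"C{c + 1}"
        for i in range(config.n_per_class):
            sid = f"{label}-{i + 1:03d}"
            gains = 1.0 + rng.normal(0.0, config.scatter_sd, size=config.n_replicates)
            noise = rng.normal(
                0.0, config.noise_sd, size=(config.n_replicates, grid.size)
            )
            inten = gains[:, None] * mean[None, :] + noise
            collection.append(
                SpectrumSeries(grid.copy(), inten, {"sample_id": sid, "label": label})
            )
            labels.append({"sample_id": sid, "label": label, "class_index": c})
    return collection, pd.DataFrame(labels)


@dataclass
class ClimateSimConfig:
    """Configuration of the climate/saponin table simulator."""

    n_samples: int = 200
    bio_means: dict[str, float] = field(default_factory=lambda: dict(_BIO_MEANS))
    bio_sds: dict[str, float] = field(default_factory=lambda: dict(_BIO_SDS))
    equation_coefficients: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in EQUATION_COEFFICIENTS.items()}
    )
    noise_sd: float = 1.5  # mg/g, residual sd around the regression surface
    n_groups: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("need n_samples >= 8 for a full-rank design")
        if self.noise_sd < 0 or any(s < 0 for s in self.bio_sds.values()):
            raise ValueError("all sds must be >= 0")
        for name, coefs in self.equation_coefficients.items():
            coefs = tuple(float(c) for c in coefs)
            if not all(np.isfinite(coefs)):
                raise ValueError(f"non-finite coefficient in equation for {name}")
            if len(coefs) != len(BIO_VARS) + 1:
                raise ValueError(
                    f"equation for {name} needs intercept + {len(BIO_VARS)} slopes"
                )
            self.equation_coefficients[name] = coefs


def simulate_climate_table(config: ClimateSimConfig) -> pd.DataFrame:
    """Draw a per-sample table of climate factors and saponin contents.

    Climate factors are drawn independently (the collinearity screen has,
    by construction, already removed strongly correlated pairs); each
    saponin is its linear equation evaluated on the drawn factors plus
    Gaussian noise.  The generating coefficients are attached under
    ``df.attrs['equation_coefficients']`` for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    data = {"sample_id": [f"S{i + 1:04d}" for i in range(n)]}
    data["group"] = [f"G{(i % config.n_groups) + 1}" for i in range(n)]
    X = np.column_stack(
        [
            rng.normal(config.bio_means[b], config.bio_sds[b], size=n)
            for b in BIO_VARS
        ]
    )
    for j, b in enumerate(BIO_VARS):
        data[b] = X[:, j]
    for name, coefs in config.equation_coefficients.items():
        y = coefs[0] + X @ np.asarray(coefs[1:])
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=n)
        data[name] = y
    df = pd.DataFrame(data)
    df.attrs["equation_coefficients"] = {
        k: tuple(v) for k, v in config.equation_coefficients.items()
    }
    df.attrs["noise_sd"] = config.noise_sd
    return df


def correlated_climate_table(
    config: ClimateSimConfig, pairs: Sequence[tuple[str, str, float]]
) -> pd.DataFrame:
    """Variant with planted collinear pairs, for exercising the screen.

    ``pairs`` lists (source, target, r): after the independent draw, the
    target column is rebuilt as a linear blend of the source achieving
    correlation ~r.
    """
    df = simulate_climate_table(config)
    rng = np.random.default_rng(config.seed + 1)
    for src, tgt, r in pairs:
        if not (0 < abs(r) <= 1):
            raise ValueError("planted correlation must be in (0, 1]")
        z = (df[src] - df[src].mean()) / df[src].std()
        e = rng.normal(size=len(df))
        e = (e - e.mean()) / np.std(e)
        mixed = r * z + np.sqrt(max(0.0, 1 - r * r)) * e
        df[tgt] = df[tgt].mean() + df[tgt].std() * mixed
    return df


def write_fixture(
    outdir: str | Path,
    spectra_config: SpectraSimConfig | None = None,
    climate_config: ClimateSimConfig | None = None,
    hdf5: bool = False,
) -> dict:
    """Write the full synthetic fixture (spectra, labels, climate table)
    to ``outdir`` as CSV, plus a JSON manifest recording configs + seeds.
    With ``hdf5=True`` an additional single-file container is written
    (requires h5py)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spectra_config = spectra_config or SpectraSimConfig()
    climate_config = climate_config or ClimateSimConfig()
    collection, labels = simulate_spectra(spectra_config)
    table = simulate_climate_table(climate_config)
    write_spectra(collection, outdir / "spectra_long.csv", format="long")
    labels.to_csv(outdir / "labels.csv", index=False)
    table.to_csv(outdir / "climate_table.csv", index=False)
    files = ["spectra_long.csv", "labels.csv", "climate_table.csv"]
    manifest = {
        "spectra_config": _jsonable(spectra_config),
        "climate_config": _jsonable(climate_config),
        "files": files,
    }
    if hdf5:
        import h5py

        with h5py.File(outdir / "fixture.h5", "w") as f:
            f.attrs["config"] = json.dumps(
                {k: manifest[k] for k in ("spectra_config", "climate_config")}
            )
            f.create_dataset("grid", data=collection[0].grid)
            f.create_dataset(
                "intensities", data=np.stack([s.intensities for s in collection])
            )
            f.create_dataset(
                "sample_id",
                data=np.array([s.sample_id for s in collection], dtype="S"),
            )
            f.create_dataset(
                "label", data=labels["label"].to_numpy(dtype="S")
            )
        files.append("fixture.h5")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonable(cfg) -> dict:
    out = {}
    for k, v in vars(cfg).items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, dict):
            out[k] = {kk: list(vv) if isinstance(vv, tuple) else vv for kk, vv in v.items()}
        elif isinstance(v, tuple):
            out[k] = list(v)
        else:
            out[k] = v
    return out
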