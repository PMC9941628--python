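"""Generalized two-dimensional correlation spectroscopy (synchronous maps).

Given a perturbation series of m spectra y(v, t_1..t_m) on a common
wavenumber grid, the dynamic spectra are the series members minus the
series mean spectrum, and the synchronous correlation intensity between
two wavenumbers is

    Phi(v1, v2) = 1/(m-1) * sum_t S(v1, t) * S(v2, t),

i.e. the sample covariance of intensity variation at v1 and v2 across the
perturbation.  Phi is symmetric with non-negative autopeaks on the
diagonal; cross-peaks flag wavenumber pairs whose intensities vary in
phase.  Maps are rendered to fixed-size RGB images (default 128x128) via
min-max normalization, a rainbow lookup table shipped with the package,
and bilinear resampling — the inputs the origin classifier consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .spectra import SpectrumSeries, average_replicates

__all__ = [
    "SyncMap",
    "RenderedImage",
    "dynamic_spectra",
    "sync_corr",
    "per_sample_map",
    "render_image",
    "save_image",
    "jet_table",
]


class SeriesSizeError(ValueError):
    """Perturbation series too short for a correlation map."""


@dataclass
class SyncMap:
    """Symmetric v x v synchronous correlation matrix on a wavenumber grid."""

    grid: np.ndarray
    phi: np.ndarray
    meta: dict

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        v = self.grid.shape[0]
        if self.phi.shape != (v, v):
            raise ValueError(f"phi must be {v}x{v}, got {self.phi.shape}")


@dataclass
class RenderedImage:
    """Quantized RGB image of a synchronous map.

    ``pixels`` is (size, size, 3) uint8; ``provenance`` records the sample
    id and the normalization bounds so a render can be audited.
    """

    pixels: np.ndarray
    provenance: dict


def dynamic_spectra(series: SpectrumSeries) -> SpectrumSeries:
    """Subtract the series-mean (reference) spectrum from every member."""
    if series.n_rows < 2:
        raise SeriesSizeError(
            "dynamic spectra need a series of m >= 2; for a single sample "
            "use per_sample_map"
        )
    centered = series.intensities - series.intensities.mean(axis=0, keepdims=True)
    return SpectrumSeries(series.grid.copy(), centered, dict(series.meta))


def sync_corr(dynamic: SpectrumSeries) -> SyncMap:
    """Synchronous correlation map of an (already centered) dynamic series."""
    if dynamic.n_rows < 2:
        raise SeriesSizeError("synchronous correlation needs m >= 2 members")
    S = dynamic.intensities  # (m, v)
    phi = S.T @ S / (S.shape[0] - 1)
    phi = 0.5 * (phi + phi.T)  # enforce exact symmetry against rounding
    return SyncMap(dynamic.grid.copy(), phi, dict(dynamic.meta))


def per_sample_map(sample: SpectrumSeries, mode: str = "self-outer") -> SyncMap:
    """One synchronous map per sample.

    ``self-outer`` (default): average the replicate scans, center the
    averaged spectrum about its mean intensity *over wavenumbers*, and
    return the outer product with itself — a rank-1 symmetric map whose
    autopeaks sit on the absorption bands.  ``replicates``: treat the
    replicate scans as the perturbation series (requires m >= 2).
    """
    if mode == "self-outer":
        avg = average_replicates(sample)
        x = avg.intensities[0]
        xc = x - x.mean()
        phi = np.outer(xc, xc)
        return SyncMap(sample.grid.copy(), phi, dict(sample.meta))
    if mode == "replicates":
        return sync_corr(dynamic_spectra(sample))
    raise ValueError(f"unknown per-sample map mode '{mode}'")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_JET: np.ndarray | None = None


def jet_table() -> np.ndarray:
    """The package's 256x3 rainbow lookup table (uint8, shipped as CSV)."""
    global _JET
    if _JET is None:
        with resources.files("sanqitrace.data").joinpath("jet256.csv").open() as fh:
            rows = [line.strip().split(",") for line in fh][1:]
        _JET = np.array([[int(r), int(g), int(b)] for _, r, g, b in rows], dtype=np.uint8)
        assert _JET.shape == (256, 3)
    return _JET


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resample of an (h, w, c) float array to (size, size, c).

    Align-corners convention: output corner pixels sample the input
    corners exactly; interior samples sit at i*(n-1)/(size-1).
    """
    h, w = img.shape[:2]
    out = img
    for axis, n in ((0, h), (1, w)):
        if n == size:
            continue
        if n == 1:
            out = np.repeat(out, size, axis=axis)
            continue
        pos = np.arange(size) * (n - 1) / (size - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = pos - lo
        take_lo = np.take(out, lo, axis=axis)
        take_hi = np.take(out, hi, axis=axis)
        shape = [1, 1, 1]
        shape[axis] = size
        f = frac.reshape(shape[: out.ndim])
        out = take_lo * (1 - f) + take_hi * f
    return out


def render_image(
    smap: SyncMap, size: int = 128, colormap: np.ndarray | None = None
) -> RenderedImage:
    """Render a synchronous map as a ``size`` x ``size`` RGB image.

    Min-max normalizes phi to [0, 1] (a constant map degenerates to 0),
    looks each value up in the 256-entry colormap (nearest index), resamples
    the RGB plane bilinearly, and quantizes to uint8.  Deterministic.
    """
    phi = smap.phi
    if not np.all(np.isfinite(phi)):
        bad = np.argwhere(~np.isfinite(phi))[0]
        raise ValueError(f"non-finite phi at index ({bad[0]}, {bad[1]})")
    lut = jet_table() if colormap is None else np.asarray(colormap, dtype=np.uint8)
    lo, hi = float(phi.min()), float(phi.max())
    if hi > lo:
        norm = (phi - lo) / (hi - lo)
    else:
        norm = np.zeros_like(phi)
    idx = np.rint(norm * (lut.shape[0] - 1)).astype(int)
    rgb = lut[idx].astype(float)  # (v, v, 3)
    resized = _bilinear_resize(rgb, size)
    pixels = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    return RenderedImage(
        pixels,
        {
            "sample_id": smap.meta.get("sample_id", ""),
            "label": smap.meta.get("label", ""),
            "norm_lo": lo,
            "norm_hi": hi,
            "size": size,
        },
    )


def save_image(image: RenderedImage, path: str | Path, quality: int = 95) -> Path:
    """Write a rendered map as PNG (lossless default) or JPEG (.jpg/.jpeg)."""
    from PIL import Image

    path = Path(path)
    im = Image.fromarray(image.pixels, mode="RGB")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        im.save(path, format="JPEG", quality=quality)
    else:
        im.save(path, format="PNG")
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file back as (h, w, 3) uint8."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))
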