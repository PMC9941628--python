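"""Spectral series container and file I/O.

All spectra in the package live on a shared wavenumber grid stored in
strictly *descending* order (the convention of FT-NIR instruments, which
scan from high to low wavenumber).  A :class:`SpectrumSeries` holds one or
more intensity rows on that grid — typically the replicate scans of one
sample, or the member spectra of a perturbation series.

Supported file formats:

* long CSV   — columns ``sample_id, replicate, wavenumber, intensity``
* wide CSV   — first column ``sample_id``, remaining columns are wavenumbers
* JCAMP-DX   — one ``##XYDATA=(X++(Y..Y))`` block per file/sample

Grids are never resampled: samples whose grids differ raise an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSeries",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "select_band",
]


class SpectraFormatError(ValueError):
    """Raised when an input file violates the spectral-format contract."""


@dataclass
class SpectrumSeries:
    """m intensity rows on a shared, strictly descending wavenumber grid.

    Parameters
    ----------
    grid
        Wavenumbers in cm^-1, strictly monotone descending, length v.
    intensities
        Array of shape (m, v); absorbance-like units.
    meta
        Free-form identifiers (``sample_id``, ``label`` ...), carried
        through every transformation untouched.
    """

    grid: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.grid.ndim != 1:
            raise SpectraFormatError("grid must be one-dimensional")
        if self.intensities.shape[1] != self.grid.shape[0]:
            raise SpectraFormatError(
                f"intensity rows have {self.intensities.shape[1]} points, "
                f"grid has {self.grid.shape[0]}"
            )
        if self.intensities.shape[0] < 1:
            raise SpectraFormatError("need at least one intensity row")
        if not np.all(np.isfinite(self.grid)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise SpectraFormatError("non-finite values in grid or intensities")
        if self.grid.size > 1:
            d = np.diff(self.grid)
            if np.all(d > 0):  # ascending input: flip to the package convention
                self.grid = self.grid[::-1].copy()
                self.intensities = self.intensities[:, ::-1].copy()
            elif not np.all(d < 0):
                raise SpectraFormatError("grid must be strictly monotone")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]

    @property
    def sample_id(self) -> str:
        return str(self.meta.get("sample_id", ""))


def average_replicates(series: SpectrumSeries) -> SpectrumSeries:
    """Pointwise arithmetic mean across rows; returns an m=1 series.

    Mirrors the acquisition protocol in which each sample is scanned
    twice and the average spectrum is carried forward.
    """
    mean = series.intensities.mean(axis=0, keepdims=True)
    return SpectrumSeries(series.grid.copy(), mean, dict(series.meta))


def select_band(series: SpectrumSeries, high: float, low: float) -> SpectrumSeries:
    """Restrict a series to the closed wavenumber window [low, high].

    The fingerprint region used for 2D correlation images is
    7000–4000 cm^-1; both endpoints are retained when present on the grid.
    """
    if not high > low:
        raise ValueError(f"window requires high > low, got [{low}, {high}]")
    mask = (series.grid >= low) & (series.grid <= high)
    if not mask.any():
        raise ValueError(
            f"window [{low}, {high}] cm^-1 selects no grid points "
            f"(grid spans {series.grid.max()}..{series.grid.min()})"
        )
    return SpectrumSeries(
        series.grid[mask].copy(), series.intensities[:, mask].copy(), dict(series.meta)
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _check_shared_grid(collection: Sequence[SpectrumSeries]) -> None:
    if not collection:
        return
    ref = collection[0]
    for s in collection[1:]:
        if s.n_points != ref.n_points or not np.array_equal(s.grid, ref.grid):
            raise SpectraFormatError(
                "samples are on different wavenumber grids: "
                f"'{ref.sample_id}' vs '{s.sample_id}'"
            )


def _read_long_csv(path: Path) -> list[SpectrumSeries]:
    df = pd.read_csv(path)
    required = {"sample_id", "replicate", "wavenumber", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraFormatError(f"long CSV missing columns: {sorted(missing)}")
    bad = pd.to_numeric(df["intensity"], errors="coerce").isna() & df[
        "intensity"
    ].notna()
    if bad.any():
        raise SpectraFormatError(
            f"non-numeric intensity at row {int(np.flatnonzero(bad.values)[0])}"
        )
    out: list[SpectrumSeries] = []
    for sid, g in df.groupby("sample_id", sort=False):
        pivot = g.pivot_table(
            index="replicate", columns="wavenumber", values="intensity", sort=True
        )
        if pivot.isna().any().any():
            raise SpectraFormatError(f"ragged grid within sample '{sid}'")
        grid = pivot.columns.to_numpy(dtype=float)[::-1]
        inten = pivot.to_numpy(dtype=float)[:, ::-1]
        meta = {"sample_id": str(sid)}
        for extra in ("label", "group", "class"):
            if extra in g.columns:
                meta[extra] = str(g[extra].iloc[0])
        out.append(SpectrumSeries(grid, inten, meta))
    _check_shared_grid(out)
    return out


def _read_wide_csv(path: Path) -> list[SpectrumSeries]:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectraFormatError("wide CSV needs sample_id plus wavenumber columns")
    id_col = df.columns[0]
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber column: {exc}") from exc
    values = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise SpectraFormatError(f"non-numeric intensity at row {int(r)}")
    return [
        SpectrumSeries(grid, values.iloc[i].to_numpy(), {"sample_id": str(df[id_col].iloc[i])})
        for i in range(len(df))
    ]


def _read_jcamp(path: Path) -> list[SpectrumSeries]:
    """Minimal JCAMP-DX reader for a single ``(X++(Y..Y))`` XYDATA block."""
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = "(X++(Y..Y))" in val.replace(" ", "")
                if not in_data:
                    raise SpectraFormatError(
                        f"unsupported XYDATA form: {val.strip()}"
                    )
                continue
            if key == "END":
                in_data = False
            fields[key] = val.strip()
        elif in_data and line:
            data_lines.append(line)
    if not data_lines:
        raise SpectraFormatError(f"no XYDATA block in {path}")
    xfac = float(fields.get("XFACTOR", 1.0))
    yfac = float(fields.get("YFACTOR", 1.0))
    step = _jcamp_step(fields)
    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        parts = line.replace(",", " ").split()
        x0 = float(parts[0]) * xfac
        for j, p in enumerate(parts[1:]):
            xs.append(x0 + j * step)
            ys.append(float(p) * yfac)
    grid = np.array(xs)
    meta = {"sample_id": fields.get("TITLE", Path(path).stem)}
    return [SpectrumSeries(grid, np.array(ys)[None, :], meta)]


def _jcamp_step(fields: Mapping[str, str]) -> float:
    if "DELTAX" in fields:
        return float(fields["DELTAX"])
    first = float(fields["FIRSTX"])
    last = float(fields["LASTX"])
    npts = int(float(fields["NPOINTS"]))
    return (last - first) / (npts - 1)


_READERS = {
    "long": _read_long_csv,
    "wide": _read_wide_csv,
    "jcamp": _read_jcamp,
}


def read_spectra(path: str | Path, format: str = "long") -> list[SpectrumSeries]:
    """Read a spectra file into a list of :class:`SpectrumSeries`.

    ``format`` is one of ``"long"``, ``"wide"``, ``"jcamp"``.  All samples
    must share one grid; the returned grids are descending.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format '{format}'; expected one of {sorted(_READERS)}"
        ) from None
    collection = reader(path)
    _check_shared_grid(collection)
    return collection


def write_spectra(
    collection: Iterable[SpectrumSeries], path: str | Path, format: str = "long"
) -> Path:
    """Write a collection to CSV (long or wide)."""
    path = Path(path)
    collection = list(collection)
    if format == "long":
        rows = []
        for s in collection:
            for r in range(s.n_rows):
                rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": s.sample_id,
                            "replicate": r,
                            "wavenumber": s.grid,
                            "intensity": s.intensities[r],
                            **(
                                {"label": s.meta["label"]}
                                if "label" in s.meta
                                else {}
                            ),
                        }
                    )
                )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    elif format == "wide":
        grid = collection[0].grid
        df = pd.DataFrame(
            np.vstack([s.intensities.mean(axis=0) for s in collection]),
            columns=[f"{w:g}" for w in grid],
        )
        df.insert(0, "sample_id", [s.sample_id for s in collection])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format '{format}'")
    return path
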