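"""Reading and writing MSI rasters, masks, hyperspectral cubes and peak tables.

Two on-disk layouts are supported for raw data:

* imzML/ibd pairs (continuous or processed, centroided) — the canonical
  interchange format;
* one spectrum file per image row in netCDF (ANDI-MS style ``mass_values`` /
  ``intensity_values`` / ``scan_index`` variables), mirroring acquisitions
  where the stage rasters a full row per run.

Coordinate convention: 0-based ``(row, col)``, row-major.  Row 0 is the root
tip end of the developmental axis; spatial metadata (pixel pitch, polarity)
rides along but is never interpreted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from dimple.errors import FormatError, MaskError, ShapeError, UnsupportedModeError

__all__ = [
    "PixelSpectrum",
    "MSIGrid",
    "Mask",
    "read_imzml",
    "write_imzml",
    "read_rowfile_set",
    "write_rowfile_set",
    "write_hyperspectral_tiff",
    "read_hyperspectral_tiff",
    "write_peaklist",
    "read_peaklist",
    "write_mask",
    "read_mask",
]


@dataclass(frozen=True)
class PixelSpectrum:
    """One centroided spectrum: ascending m/z (Th) with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        intensity = np.asarray(self.intensity, dtype=np.float64)
        if mz.ndim != 1 or intensity.ndim != 1 or len(mz) != len(intensity):
            raise ValueError("mz and intensity must be 1D arrays of equal length")
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("m/z values must be strictly ascending")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    @classmethod
    def empty(cls) -> "PixelSpectrum":
        return cls(np.empty(0), np.empty(0))

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities in this pixel."""
        return float(self.intensity.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PixelSpectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )


@dataclass
class MSIGrid:
    """A 2D raster of pixel spectra plus acquisition metadata."""

    rows: int
    cols: int
    spectra: list[list[PixelSpectrum]]
    pixel_size_x: float = 50.0  # µm, metadata only
    pixel_size_y: float = 50.0
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if len(self.spectra) != self.rows or any(len(r) != self.cols for r in self.spectra):
            raise ShapeError("spectra layout does not match declared rows x cols")

    @classmethod
    def empty(cls, rows: int, cols: int, **meta) -> "MSIGrid":
        spectra = [[PixelSpectrum.empty() for _ in range(cols)] for _ in range(rows)]
        return cls(rows, cols, spectra, **meta)

    def __getitem__(self, rc: tuple[int, int]) -> PixelSpectrum:
        r, c = rc
        return self.spectra[r][c]

    def __setitem__(self, rc: tuple[int, int], spec: PixelSpectrum) -> None:
        r, c = rc
        self.spectra[r][c] = spec

    def pixels(self) -> Iterator[tuple[int, int, PixelSpectrum]]:
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c, self.spectra[r][c]

    def tic_image(self) -> np.ndarray:
        """Per-pixel total ion current as a rows x cols float image."""
        img = np.zeros((self.rows, self.cols))
        for r, c, spec in self.pixels():
            img[r, c] = spec.tic
        return img

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MSIGrid):
            return NotImplemented
        return (
            self.rows == other.rows
            and self.cols == other.cols
            and all(
                self.spectra[r][c] == other.spectra[r][c]
                for r in range(self.rows)
                for c in range(self.cols)
            )
        )


@dataclass(frozen=True)
class Mask:
    """Boolean foreground (sample) indicator over the raster."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2:
            raise MaskError("mask must be a 2D boolean array")
        object.__setattr__(self, "grid", g)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())

    @property
    def n_background(self) -> int:
        return int((~self.grid).sum())

    def require_foreground(self) -> None:
        if self.n_foreground == 0:
            raise MaskError("sample mask has no foreground pixels")

    def validate_against(self, grid: MSIGrid) -> None:
        if self.shape != (grid.rows, grid.cols):
            raise MaskError(
                f"mask shape {self.shape} does not match grid "
                f"({grid.rows}, {grid.cols})"
            )

    def __invert__(self) -> "Mask":
        return Mask(~self.grid)


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

_PROFILE_ACCESSION = "MS:1000128"  # PSI-MS controlled vocabulary: profile spectrum


def read_imzml(path: str | os.PathLike) -> MSIGrid:
    """Read an imzML/ibd pair into an :class:`MSIGrid`.

    imzML stores 1-based (x, y) coordinates; x maps to the column index and
    y to the row index, both shifted to 0-based.  Coordinates absent from the
    file become empty spectra.  Profile-mode data are rejected: the pipeline
    assumes centroided peaks.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    with open(path, "r", errors="replace") as fh:
        header = fh.read()
    if _PROFILE_ACCESSION in header or "profile spectrum" in header:
        raise UnsupportedModeError(
            f"{path}: profile-mode imzML is not supported; centroid the data first"
        )
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # pyimzml raises assorted XML/IO errors
        raise FormatError(f"could not parse imzML file {path}: {exc}") from exc

    if not parser.coordinates:
        raise FormatError(f"{path}: imzML file contains no spectra")
    xs = [c[0] for c in parser.coordinates]
    ys = [c[1] for c in parser.coordinates]
    grid = MSIGrid.empty(rows=max(ys), cols=max(xs))
    for idx, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(idx)
        order = np.argsort(mz, kind="stable")
        grid[y - 1, x - 1] = PixelSpectrum(np.asarray(mz)[order], np.asarray(inten)[order])
    return grid


def write_imzml(grid: MSIGrid, path: str | os.PathLike) -> None:
    """Write a grid to an imzML/ibd pair (processed mode, float64, centroided).

    Empty spectra are skipped, so they read back as missing coordinates and
    the imzML round trip is bit-identical for non-empty pixels.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = os.fspath(path)
    with ImzMLWriter(
        path,
        polarity=grid.polarity,
        mode="processed",
        spec_type="centroid",
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
    ) as writer:
        for r, c, spec in grid.pixels():
            if len(spec) == 0:
                continue
            writer.addSpectrum(spec.mz, spec.intensity, (c + 1, r + 1, 1))


# ---------------------------------------------------------------------------
# per-row spectrum files (netCDF / ANDI-MS layout)
# ---------------------------------------------------------------------------


def read_rowfile_set(paths: Sequence[str | os.PathLike]) -> MSIGrid:
    """Assemble a grid from one netCDF spectrum file per image row.

    The list order defines row order (first file = row 0 = root tip end);
    within a file, scan order defines the column index.  All files must hold
    the same number of scans.
    """
    if len(paths) == 0:
        raise FormatError("empty row-file list: at least one per-row file is required")
    rows_data: list[list[PixelSpectrum]] = []
    counts: list[int] = []
    for path in paths:
        rows_data.append(_read_rowfile(os.fspath(path)))
        counts.append(len(rows_data[-1]))
    if len(set(counts)) > 1:
        expected = counts[0]
        offenders = [
            f"{os.fspath(p)} ({n} scans)" for p, n in zip(paths, counts) if n != expected
        ]
        raise ShapeError(
            f"inconsistent pixel counts across row files (expected {expected}): "
            + ", ".join(offenders)
        )
    return MSIGrid(rows=len(paths), cols=counts[0], spectra=rows_data)


def _read_rowfile(path: str) -> list[PixelSpectrum]:
    from scipy.io import netcdf_file

    try:
        nc = netcdf_file(path, "r", mmap=False)
    except Exception as exc:
        raise FormatError(f"could not read netCDF row file {path}: {exc}") from exc
    try:
        required = {"mass_values", "intensity_values", "scan_index"}
        missing = required - set(nc.variables)
        if missing:
            raise FormatError(f"{path}: missing netCDF variables {sorted(missing)}")
        mass = np.asarray(nc.variables["mass_values"][:], dtype=np.float64)
        inten = np.asarray(nc.variables["intensity_values"][:], dtype=np.float64)
        starts = np.asarray(nc.variables["scan_index"][:], dtype=np.int64)
    finally:
        nc.close()
    bounds = np.append(starts, len(mass))
    specs = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mz = mass[lo:hi]
        order = np.argsort(mz, kind="stable")
        specs.append(PixelSpectrum(mz[order], inten[lo:hi][order]))
    return specs


def write_rowfile_set(grid: MSIGrid, directory: str | os.PathLike, stem: str = "row") -> list[str]:
    """Write a grid as one netCDF file per row; returns the file paths in row order."""
    from scipy.io import netcdf_file

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    width = max(3, len(str(grid.rows)))
    paths = []
    for r in range(grid.rows):
        specs = grid.spectra[r]
        mass = np.concatenate([s.mz for s in specs]) if specs else np.empty(0)
        inten = np.concatenate([s.intensity for s in specs]) if specs else np.empty(0)
        starts = np.cumsum([0] + [len(s) for s in specs[:-1]]).astype(np.int32)
        path = os.path.join(directory, f"{stem}{r:0{width}d}.cdf")
        nc = netcdf_file(path, "w")
        try:
            nc.createDimension("point_number", max(len(mass), 1))
            nc.createDimension("scan_number", grid.cols)
            mv = nc.createVariable("mass_values", "d", ("point_number",))
            iv = nc.createVariable("intensity_values", "d", ("point_number",))
            sv = nc.createVariable("scan_index", "i", ("scan_number",))
            if len(mass):
                mv[:] = mass
                iv[:] = inten
            else:  # netCDF needs at least one point; write a sentinel outside any scan
                mv[:] = [0.0]
                iv[:] = [0.0]
                starts = np.zeros(grid.cols, dtype=np.int32)
            sv[:] = starts
        finally:
            nc.close()
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# hyperspectral TIFF
# ---------------------------------------------------------------------------


def write_hyperspectral_tiff(hsi, path: str | os.PathLike) -> str:
    """Write a hyperspectral image as a multi-page 32-bit float TIFF.

    One page per kept channel, in ascending channel-m/z order.  The channel
    m/z list is written to a tab-separated sidecar ``<path>.channels.tsv``
    with columns (page, mz); the sidecar path is returned.
    """
    path = os.fspath(path)
    cube = np.asarray(hsi.cube, dtype=np.float32)
    mzs = np.asarray(hsi.channel_mz, dtype=np.float64)
    if cube.ndim != 3 or cube.shape[0] == 0:
        raise ValueError("hyperspectral image must contain at least one channel")
    order = np.argsort(mzs, kind="stable")
    tifffile.imwrite(path, cube[order], photometric="minisblack")
    sidecar = path + ".channels.tsv"
    pd.DataFrame({"page": np.arange(len(mzs)), "mz": mzs[order]}).to_csv(
        sidecar, sep="\t", index=False, float_format="%.6f"
    )
    return sidecar


def read_hyperspectral_tiff(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a hyperspectral TIFF and its sidecar; returns (channel_mz, cube)."""
    path = os.fspath(path)
    cube = tifffile.imread(path)
    if cube.ndim == 2:
        cube = cube[None]
    sidecar = path + ".channels.tsv"
    if not os.path.exists(sidecar):
        raise FormatError(f"missing channel sidecar {sidecar}")
    mzs = pd.read_csv(sidecar, sep="\t")["mz"].to_numpy(dtype=np.float64)
    if len(mzs) != cube.shape[0]:
        raise ShapeError(
            f"sidecar lists {len(mzs)} channels but TIFF has {cube.shape[0]} pages"
        )
    return mzs, cube.astype(np.float64)


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------


def peaklist_frame(peakset, assignments: dict[float, int] | None = None) -> pd.DataFrame:
    """Tabulate a consensus peak set (kept and removed) as a DataFrame."""
    rows = []
    for p in peakset.peaks:
        rows.append(
            {
                "mz": p.center_mz,
                "sample_intensity": p.sample_mean_intensity,
                "background_intensity": p.background_mean_intensity,
                "fold_enrichment": p.fold_enrichment,
                "kept_flag": bool(p.kept),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["mz", "sample_intensity", "background_intensity", "fold_enrichment", "kept_flag"],
    )
    if assignments is not None:
        df["cluster_id"] = [assignments.get(p.center_mz, -1) for p in peakset.peaks]
    return df


def write_peaklist(peaks, path: str | os.PathLike, assignments=None) -> None:
    """Write peaks to CSV with m/z printed to 4 decimals.

    ``peaks`` may be a ConsensusPeakSet, a PeakList, or a plain sequence of
    m/z values.
    """
    path = os.fspath(path)
    if hasattr(peaks, "peaks"):  # ConsensusPeakSet
        df = peaklist_frame(peaks, assignments)
    elif hasattr(peaks, "mz"):  # PeakList
        df = pd.DataFrame({"mz": np.asarray(peaks.mz, dtype=np.float64)})
    else:
        df = pd.DataFrame({"mz": np.asarray(list(peaks), dtype=np.float64)})
    df = df.copy()
    df["mz"] = df["mz"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def read_peaklist(path: str | os.PathLike) -> pd.DataFrame:
    """Read a peak-list CSV; always exposes a float ``mz`` column."""
    df = pd.read_csv(os.fspath(path))
    if "mz" not in df.columns:
        raise FormatError(f"{os.fspath(path)}: peak list CSV lacks an 'mz' column")
    df["mz"] = df["mz"].astype(np.float64)
    return df


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def write_mask(mask: Mask, path: str | os.PathLike) -> None:
    """Write a binary mask as a single-page image (PNG or TIFF by extension)."""
    path = os.fspath(path)
    img = (mask.grid.astype(np.uint8)) * 255
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img, photometric="minisblack")
    else:
        Image.fromarray(img, mode="L").save(path)


def read_mask(path: str | os.PathLike, grid: MSIGrid | None = None) -> Mask:
    """Read a binary mask image; nonzero pixels are foreground.

    When ``grid`` is given, the mask shape is checked against it.
    """
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    mask = Mask(arr > 0)
    if grid is not None:
        mask.validate_against(grid)
    return mask
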