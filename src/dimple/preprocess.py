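"""Pre-processing: from raw pixel spectra to a background- and sparsity-
filtered hyperspectral image.

The workflow, applied in order by :func:`run_preprocess`:

1. optional hot-pixel detection and suppression;
2. sample masking (supplied mask, or an Otsu-on-TIC fallback);
3. pseudobulk spectrum: the sum of every peak detected in every sample pixel;
4. consensus peak picking: local maxima of the (median-filtered) pseudobulk
   within a +/- ppm window (2.5 ppm default);
5. background suppression: a consensus center is kept only if its per-pixel
   mean sample intensity strictly exceeds ``min_fold`` (1.5 default) times
   the per-pixel mean background intensity in the same window;
6. per-pixel assignment of every in-window observed peak to its nearest kept
   center;
7. assembly of the channels x rows x cols hyperspectral cube;
8. removal of sparsely localised channels by binary erosion, retaining the
   removed channels separately for inspection.

All ppm windows are multiplicative about the candidate center:
half-width = center * ppm / 1e6.  Ties everywhere break toward lower m/z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from dimple._smoothing import running_median
from dimple.errors import MaskError, ParameterError
from dimple.msi_io import Mask, MSIGrid, PixelSpectrum

logger = logging.getLogger("dimple.preprocess")

__all__ = [
    "PseudobulkSpectrum",
    "ConsensusPeak",
    "ConsensusPeakSet",
    "HyperspectralImage",
    "PreprocessParams",
    "suppress_hot_pixels",
    "auto_mask",
    "build_pseudobulk",
    "smooth_pseudobulk",
    "find_consensus_peaks",
    "filter_background",
    "assign_pixel_peaks",
    "remove_sparse_channels",
    "run_preprocess",
]


@dataclass(frozen=True)
class PseudobulkSpectrum:
    """Region-wide spectrum: all pixel entries pooled, merged on identical m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if len(mz) != len(inten):
            raise ValueError("mz and intensity must have equal length")
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("pseudobulk m/z must be strictly ascending")
        if np.any(inten < 0):
            raise ValueError("pseudobulk intensities must be non-negative")
        if self.n_pixels < 1:
            raise ValueError("pseudobulk requires at least one contributing pixel")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class ConsensusPeak:
    """One harmonized m/z channel center with its enrichment statistics."""

    center_mz: float
    window_ppm: float
    sample_mean_intensity: float
    background_mean_intensity: float
    fold_enrichment: float  # inf when background mean is zero
    kept: bool


@dataclass(frozen=True)
class ConsensusPeakSet:
    """Consensus centers sorted by m/z, plus the parameters that produced them."""

    peaks: tuple[ConsensusPeak, ...]
    window_ppm: float
    min_fold: float
    median_filter_width: int

    def __post_init__(self) -> None:
        centers = [p.center_mz for p in self.peaks]
        if centers != sorted(centers):
            raise ValueError("consensus peaks must be sorted by center m/z")

    @property
    def kept_peaks(self) -> tuple[ConsensusPeak, ...]:
        return tuple(p for p in self.peaks if p.kept)

    @property
    def kept_centers(self) -> np.ndarray:
        return np.array([p.center_mz for p in self.peaks if p.kept])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class HyperspectralImage:
    """Channels x rows x cols intensity cube keyed by consensus m/z.

    ``removed_mz``/``removed_cube`` hold channels that failed the sparsity
    filter; they stay exportable but are excluded from downstream analysis.
    """

    channel_mz: np.ndarray
    cube: np.ndarray
    mask: Mask
    removed_mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    removed_cube: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_mz = np.asarray(self.channel_mz, dtype=np.float64)
        self.cube = np.asarray(self.cube, dtype=np.float64)
        if self.cube.ndim != 3 or self.cube.shape[0] != len(self.channel_mz):
            raise ValueError("cube must be channels x rows x cols matching channel_mz")
        if self.cube.shape[1:] != self.mask.shape:
            raise MaskError("cube spatial shape must match the mask")
        if self.removed_cube is None:
            self.removed_cube = np.empty((0, *self.cube.shape[1:]))
        self.removed_mz = np.asarray(self.removed_mz, dtype=np.float64)

    @property
    def n_channels(self) -> int:
        return self.cube.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[1:]

    def channel(self, mz: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.channel_mz - mz)))
        if not np.isclose(self.channel_mz[idx], mz):
            raise KeyError(f"no channel at m/z {mz}")
        return self.cube[idx]


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable knobs of the pre-processing workflow (defaults follow the
    standard analysis settings: 2.5 ppm window, 1.5-fold enrichment)."""

    window_ppm: float = 2.5
    min_fold: float = 1.5
    median_filter_width: int = 3
    hot_pixel_suppression: bool = False
    hot_pixel_k: float = 5.0
    background_normalize: str = "per_pixel"  # or "sum"
    remove_sparse: bool = True

    def __post_init__(self) -> None:
        if self.window_ppm <= 0:
            raise ParameterError("window_ppm must be positive")
        if self.min_fold < 1:
            raise ParameterError("min_fold must be >= 1")
        if self.median_filter_width < 1 or self.median_filter_width % 2 == 0:
            raise ParameterError("median_filter_width must be odd and >= 1")
        if self.background_normalize not in ("per_pixel", "sum"):
            raise ParameterError("background_normalize must be 'per_pixel' or 'sum'")


# ---------------------------------------------------------------------------
# step 1: hot pixels
# ---------------------------------------------------------------------------


def suppress_hot_pixels(grid: MSIGrid, k: float = 5.0, enabled: bool = True) -> MSIGrid:
    """Rescale anomalously intense pixels to their local TIC level.

    A pixel is hot when its TIC exceeds ``median + k * MAD`` of the TICs of
    its 8-neighbourhood (edge pixels use the neighbours that exist).  Hot
    pixels have every intensity rescaled so the pixel TIC equals the
    neighbourhood median TIC; everything else passes through unchanged.
    """
    if not enabled:
        return grid
    if k <= 0:
        raise ParameterError("hot-pixel MAD multiplier k must be positive")
    tic = grid.tic_image()
    out = MSIGrid.empty(
        grid.rows,
        grid.cols,
        pixel_size_x=grid.pixel_size_x,
        pixel_size_y=grid.pixel_size_y,
        polarity=grid.polarity,
    )
    n_hot = 0
    for r, c, spec in grid.pixels():
        neigh = _neighborhood_tics(tic, r, c)
        med = np.median(neigh)
        mad = np.median(np.abs(neigh - med))
        if tic[r, c] > med + k * mad and tic[r, c] > 0:
            scale = med / tic[r, c]
            out[r, c] = PixelSpectrum(spec.mz, spec.intensity * scale)
            n_hot += 1
        else:
            out[r, c] = spec
    logger.info("hot-pixel suppression: %d pixel(s) rescaled", n_hot)
    return out


def _neighborhood_tics(tic: np.ndarray, r: int, c: int) -> np.ndarray:
    rows, cols = tic.shape
    vals = [
        tic[rr, cc]
        for rr in range(max(0, r - 1), min(rows, r + 2))
        for cc in range(max(0, c - 1), min(cols, c + 2))
        if (rr, cc) != (r, c)
    ]
    return np.array(vals)


# ---------------------------------------------------------------------------
# step 2: masking
# ---------------------------------------------------------------------------


def _otsu_exact(values: np.ndarray) -> float:
    """Otsu's criterion evaluated at every split of the sorted sample (no
    histogram binning, so the threshold cannot land inside a data value's
    bin); returns the midpoint of the best split."""
    x = np.sort(values.ravel())
    n = len(x)
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(1, n)  # class sizes of the lower class
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu0 - mu1) ** 2
    valid = x[:-1] < x[1:]  # split only between distinct values
    if not valid.any():
        raise MaskError("cannot threshold a constant image")
    best = int(np.flatnonzero(valid)[np.argmax(between[valid])])
    return float((x[best] + x[best + 1]) / 2)


def auto_mask(grid: MSIGrid) -> Mask:
    """Otsu threshold on the TIC image, keeping the largest connected component.

    A convenience for synthetic or quick-look data; curated masks drawn on
    the sum projection remain the recommended input for real sections.
    """
    tic = grid.tic_image()
    if not np.any(tic > 0):
        raise MaskError("cannot auto-mask: all pixels have zero TIC")
    if np.allclose(tic, tic.flat[0]):
        raise MaskError("cannot auto-mask: TIC image is constant")
    thresh = _otsu_exact(tic)
    fg = tic > thresh
    if not fg.any():
        raise MaskError("auto-mask found no foreground above the Otsu threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return Mask(fg)


# ---------------------------------------------------------------------------
# step 3-4: pseudobulk and consensus peaks
# ---------------------------------------------------------------------------


def build_pseudobulk(grid: MSIGrid, region: Mask) -> PseudobulkSpectrum:
    """Sum all peaks detected in every pixel of ``region``.

    Entries are pooled across pixels, sorted ascending, and merged (summed)
    only where m/z values coincide exactly; nearby-but-distinct values stay
    separate until consensus peak picking.
    """
    region.validate_against(grid)
    rr, cc = np.nonzero(region.grid)
    if len(rr) == 0:
        raise MaskError("pseudobulk region is empty")
    mzs = [grid[r, c].mz for r, c in zip(rr, cc)]
    intens = [grid[r, c].intensity for r, c in zip(rr, cc)]
    mz = np.concatenate(mzs) if mzs else np.empty(0)
    inten = np.concatenate(intens) if intens else np.empty(0)
    if len(mz) == 0:
        return PseudobulkSpectrum(np.empty(0), np.empty(0), n_pixels=len(rr))
    uniq, inverse = np.unique(mz, return_inverse=True)
    summed = np.zeros(len(uniq))
    np.add.at(summed, inverse, inten)
    return PseudobulkSpectrum(uniq, summed, n_pixels=len(rr))


def smooth_pseudobulk(pb: PseudobulkSpectrum, width: int = 3) -> PseudobulkSpectrum:
    """Median-filter the summed spectrum over its m/z-sorted entries.

    ``width`` must be odd; 1 is the identity.  The m/z grid is unchanged —
    only intensities are smoothed.
    """
    if width < 1 or width % 2 == 0:
        raise ParameterError("median filter width must be odd and >= 1")
    return PseudobulkSpectrum(pb.mz, running_median(pb.intensity, width), pb.n_pixels)


def find_consensus_peaks(
    pb: PseudobulkSpectrum, window_ppm: float = 2.5
) -> list[tuple[float, float]]:
    """Local maxima of the pseudobulk within a +/- ppm window.

    An entry is a consensus center iff its intensity is strictly the maximum
    among all entries within ``center * window_ppm / 1e6`` of it; equal-
    intensity ties resolve toward the lower m/z.  Resulting centers are
    automatically separated pairwise by more than the window.
    """
    if window_ppm <= 0:
        raise ParameterError("window_ppm must be positive")
    mz, inten = pb.mz, pb.intensity
    n = len(mz)
    if n == 0:
        return []
    half = mz * (window_ppm / 1e6)
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    centers = []
    for i in range(n):
        window = inten[lo[i] : hi[i]]
        if len(window) == 0:
            continue
        m = window.max()
        if inten[i] == m and lo[i] + int(np.argmax(window)) == i:
            centers.append((float(mz[i]), float(inten[i])))
    return centers


# ---------------------------------------------------------------------------
# step 5: background suppression
# ---------------------------------------------------------------------------


def _window_sums(pb: PseudobulkSpectrum, centers: np.ndarray, window_ppm: float) -> np.ndarray:
    """Summed pseudobulk intensity within +/- window of each center."""
    half = centers * (window_ppm / 1e6)
    lo = np.searchsorted(pb.mz, centers - half, side="left")
    hi = np.searchsorted(pb.mz, centers + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(pb.intensity)))
    return csum[hi] - csum[lo]


def filter_background(
    sample_peaks: list[tuple[float, float]],
    sample_pb: PseudobulkSpectrum,
    background_pb: PseudobulkSpectrum,
    window_ppm: float = 2.5,
    min_fold: float = 1.5,
    normalize: str = "per_pixel",
) -> ConsensusPeakSet:
    """Keep consensus centers enriched in the sample over the background.

    Background peaks are evaluated at the sample consensus centers: for each
    center, the background intensity is the summed background-pseudobulk
    intensity within the same +/- ppm window.  With ``normalize='per_pixel'``
    (default) both sides are divided by their region pixel counts so unequal
    mask and background areas do not bias the fold; ``'sum'`` compares raw
    summed intensities.  A center is kept iff sample mean strictly exceeds
    ``min_fold`` times the background mean; zero background with positive
    sample keeps the center with fold recorded as infinity.
    """
    if min_fold < 1:
        raise ParameterError("min_fold must be >= 1")
    if normalize not in ("per_pixel", "sum"):
        raise ParameterError("normalize must be 'per_pixel' or 'sum'")
    if sample_pb.n_pixels < 1 or background_pb.n_pixels < 1:
        raise MaskError("both sample and background regions need at least one pixel")
    centers = np.array([c for c, _ in sample_peaks], dtype=np.float64)
    s_sum = _window_sums(sample_pb, centers, window_ppm)
    b_sum = _window_sums(background_pb, centers, window_ppm)
    if normalize == "per_pixel":
        s_val = s_sum / sample_pb.n_pixels
        b_val = b_sum / background_pb.n_pixels
    else:
        s_val, b_val = s_sum, b_sum
    peaks = []
    for c, s, b in zip(centers, s_val, b_val):
        if b == 0:
            fold = np.inf if s > 0 else 0.0
            kept = s > 0
        else:
            fold = s / b
            kept = s > min_fold * b  # strictly greater than
        peaks.append(
            ConsensusPeak(
                center_mz=float(c),
                window_ppm=window_ppm,
                sample_mean_intensity=float(s),
                background_mean_intensity=float(b),
                fold_enrichment=float(fold),
                kept=bool(kept),
            )
        )
    peaks.sort(key=lambda p: p.center_mz)
    return ConsensusPeakSet(
        peaks=tuple(peaks),
        window_ppm=window_ppm,
        min_fold=min_fold,
        median_filter_width=0,
    )


# ---------------------------------------------------------------------------
# step 6-7: per-pixel assignment and cube assembly
# ---------------------------------------------------------------------------


def assign_pixel_peaks(
    grid: MSIGrid, peakset: ConsensusPeakSet, mask: Mask
) -> HyperspectralImage:
    """Assign every in-window observed peak to its nearest kept center.

    For each foreground pixel, each observed entry lying within the ppm
    window of at least one kept center is added to the nearest center
    (distance ties toward the lower-m/z center); out-of-window entries are
    dropped.  Background pixels are all-zero in every channel.
    """
    mask.validate_against(grid)
    centers = peakset.kept_centers
    if len(centers) == 0:
        raise ParameterError("cannot assign pixels: peak set has no kept centers")
    half = centers * (peakset.window_ppm / 1e6)
    cube = np.zeros((len(centers), grid.rows, grid.cols))
    rr, cc = np.nonzero(mask.grid)
    for r, c in zip(rr, cc):
        spec = grid[r, c]
        if len(spec) == 0:
            continue
        idx = np.searchsorted(centers, spec.mz)
        left = np.clip(idx - 1, 0, len(centers) - 1)
        right = np.clip(idx, 0, len(centers) - 1)
        d_left = np.abs(spec.mz - centers[left])
        d_right = np.abs(spec.mz - centers[right])
        # nearest candidate; exact distance ties resolve to the lower-m/z
        # center, i.e. the left candidate (left index <= right index)
        choose_left = d_left <= d_right
        chosen = np.where(choose_left, left, right)
        dist = np.where(choose_left, d_left, d_right)
        in_window = dist <= half[chosen]
        np.add.at(cube[:, r, c], chosen[in_window], spec.intensity[in_window])
    return HyperspectralImage(channel_mz=centers, cube=cube, mask=mask)


# ---------------------------------------------------------------------------
# step 8: sparsity filter
# ---------------------------------------------------------------------------

_EROSION_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connectivity


def remove_sparse_channels(hsi: HyperspectralImage, enabled: bool = True) -> HyperspectralImage:
    """Drop channels whose nonzero pixels are all surrounded by zeros.

    Per channel, the binary presence image (intensity > 0) is eroded with a
    full 3x3 structuring element (image borders count as zero); a channel
    with an empty erosion — no pixel whose entire 8-neighbourhood is present
    — moves to ``removed_mz``/``removed_cube`` but remains exportable.
    """
    if not enabled:
        return hsi
    keep = np.zeros(hsi.n_channels, dtype=bool)
    for i in range(hsi.n_channels):
        presence = hsi.cube[i] > 0
        eroded = ndimage.binary_erosion(
            presence, structure=_EROSION_STRUCTURE, border_value=0
        )
        keep[i] = bool(eroded.any())
    return HyperspectralImage(
        channel_mz=hsi.channel_mz[keep],
        cube=hsi.cube[keep],
        mask=hsi.mask,
        removed_mz=np.concatenate([hsi.removed_mz, hsi.channel_mz[~keep]]),
        removed_cube=np.concatenate([hsi.removed_cube, hsi.cube[~keep]], axis=0),
    )


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------


def run_preprocess(
    grid: MSIGrid,
    mask: Mask | None = None,
    params: PreprocessParams | None = None,
) -> tuple[HyperspectralImage, ConsensusPeakSet]:
    """Run pre-processing steps 1-8 in order; returns (hsi, consensus peaks)."""
    params = params or PreprocessParams()
    grid = suppress_hot_pixels(grid, k=params.hot_pixel_k, enabled=params.hot_pixel_suppression)
    if mask is None:
        mask = auto_mask(grid)
        logger.info("auto-mask: %d foreground pixels", mask.n_foreground)
    mask.validate_against(grid)
    mask.require_foreground()
    if mask.n_background == 0:
        raise MaskError("mask has no background pixels; background filtering is undefined")

    sample_pb = build_pseudobulk(grid, mask)
    background_pb = build_pseudobulk(grid, ~mask)
    logger.info(
        "pseudobulk: %d sample entries over %d pixels; %d background entries over %d pixels",
        len(sample_pb), sample_pb.n_pixels, len(background_pb), background_pb.n_pixels,
    )

    # the median filter is a detection aid: centers are picked on the smoothed
    # spectrum, but enrichment statistics use the raw (mass-preserving) sums
    smoothed = smooth_pseudobulk(sample_pb, params.median_filter_width)
    candidates = find_consensus_peaks(smoothed, params.window_ppm)
    logger.info("consensus peak picking: %d candidate centers", len(candidates))

    peakset = filter_background(
        candidates,
        sample_pb,
        background_pb,
        window_ppm=params.window_ppm,
        min_fold=params.min_fold,
        normalize=params.background_normalize,
    )
    peakset = replace(peakset, median_filter_width=params.median_filter_width)
    n_kept = len(peakset.kept_centers)
    logger.info("background suppression: %d of %d centers kept", n_kept, len(peakset))
    if n_kept == 0:
        # degenerate but legal outcome: empty hyperspectral image
        empty = HyperspectralImage(
            channel_mz=np.empty(0),
            cube=np.empty((0, grid.rows, grid.cols)),
            mask=mask,
        )
        return empty, peakset

    hsi = assign_pixel_peaks(grid, peakset, mask)
    hsi = remove_sparse_channels(hsi, enabled=params.remove_sparse)
    logger.info(
        "sparsity filter: %d channels kept, %d removed",
        hsi.n_channels, len(hsi.removed_mz),
    )
    return hsi, peakset
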