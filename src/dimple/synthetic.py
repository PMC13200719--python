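"""Ground-truthed synthetic root MSI data.

Emulates the data regimes of DESI-MSI of a longitudinal root-tip section:
a tapering root-shaped foreground mask on a 2D pixel grid; per-pixel
centroided spectra whose m/z values carry Gaussian ppm-scale jitter and
whose intensities carry multiplicative lognormal noise (MSI intensities are
positive and right-skewed); planted channels with axial enrichment patterns
(tip-enriched, transition-zone, bimodal, mature-tissue, uniform, and a
lateral cell-layer stripe); background-only channels (stronger outside the
mask); sparse salt-and-pepper channels; broadband chemical noise; and
optional hot pixels.  Every generated entry traces to exactly one
ground-truth channel or to broadband noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from dimple.errors import ParameterError
from dimple.msi_io import Mask, MSIGrid, PixelSpectrum

__all__ = [
    "ChannelTruth",
    "GroundTruth",
    "PATTERNS",
    "generate_root_msi",
    "expected_linescan",
    "root_mask",
]


@dataclass(frozen=True)
class ChannelTruth:
    """Ground truth for one planted m/z channel."""

    true_mz: float
    pattern: str
    profile: np.ndarray  # per-row mean intensity inside the mask
    true_fold: float  # sample / background per-pixel mean ratio
    sparse: bool = False
    background_only: bool = False


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a pipeline run against the simulation."""

    mask: Mask
    channels: tuple[ChannelTruth, ...]
    hot_pixels: tuple[tuple[int, int], ...]
    seed: int

    @property
    def foreground_channels(self) -> tuple[ChannelTruth, ...]:
        """Planted channels the pipeline should recover (non-sparse, sample-enriched)."""
        return tuple(c for c in self.channels if not c.sparse and not c.background_only)

    def channel_by_mz(self, mz: float, ppm_tol: float = 25.0) -> ChannelTruth:
        best, best_ppm = None, np.inf
        for ch in self.channels:
            d = abs(mz - ch.true_mz) / ch.true_mz * 1e6
            if d < best_ppm:
                best, best_ppm = ch, d
        if best is None or best_ppm > ppm_tol:
            raise KeyError(f"no ground-truth channel within {ppm_tol} ppm of {mz}")
        return best


def root_mask(rows: int, cols: int) -> Mask:
    """Tapering band along the row axis: narrow at the tip (row 0), widening
    toward the mature end, mimicking a longitudinal root section."""
    center = (cols - 1) / 2.0
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    half_width = 1.5 + (0.42 * cols - 1.5) * (r / max(rows - 1, 1))
    return Mask(np.abs(c - center) <= half_width)


def _template(pattern: str, rows: int) -> np.ndarray:
    r = np.arange(rows, dtype=np.float64)
    R = float(rows)
    if pattern == "tip":
        return np.exp(-0.5 * ((r - 0.05 * R) / (0.10 * R)) ** 2)
    if pattern == "transition":
        return np.exp(-0.5 * ((r - 0.45 * R) / (0.10 * R)) ** 2)
    if pattern == "bimodal":
        return np.exp(-0.5 * ((r - 0.08 * R) / (0.06 * R)) ** 2) + np.exp(
            -0.5 * ((r - 0.80 * R) / (0.08 * R)) ** 2
        )
    if pattern == "mature":
        return 1.0 / (1.0 + np.exp(-(r - 0.70 * R) / (0.05 * R)))
    if pattern in ("uniform", "stripe"):
        return np.ones(rows)
    raise ParameterError(f"unknown pattern {pattern!r}; known: {sorted(PATTERNS)}")


PATTERNS = ("tip", "transition", "bimodal", "mature", "uniform", "stripe")

_BASE_AMPLITUDE = 100.0
_BG_ONLY_LEVEL = 50.0
_SPARSE_INTENSITY = 200.0
_HOT_PIXEL_FACTOR = 30.0


def generate_root_msi(
    rows: int = 100,
    cols: int = 24,
    n_per_pattern: int = 5,
    patterns: Sequence[str] = ("tip", "transition", "bimodal", "mature"),
    n_background_only: int = 5,
    n_sparse: int = 3,
    n_hot_pixels: int = 0,
    ppm_jitter: float = 1.0,
    noise_sigma: float = 0.25,
    noise_rate: float = 2.0,
    fold_range: tuple[float, float] = (3.0, 8.0),
    mz_values: Sequence[float] | None = None,
    seed: int | None = None,
) -> tuple[MSIGrid, GroundTruth]:
    """Simulate a root MSI acquisition with full ground truth.

    Parameters
    ----------
    rows, cols
        Raster size; the developmental axis runs along rows (row 0 = tip).
    n_per_pattern, patterns
        Number of planted sample-enriched channels per axial pattern class.
    n_background_only
        Channels stronger outside the mask (solvent/substrate signal); their
        in-mask level is a quarter of the outside level, so they fail any
        enrichment threshold above 1.
    n_sparse
        Channels present only at isolated, mutually non-adjacent pixels
        (salt-and-pepper artifacts), targets of the erosion sparsity filter.
    n_hot_pixels
        Pixels whose whole spectrum is scaled by a large factor.
    ppm_jitter
        Std. dev. of the per-entry Gaussian relative m/z error, in ppm.
    noise_sigma
        Sigma of the multiplicative lognormal intensity noise (0 = noiseless).
    noise_rate
        Mean count of broadband noise entries per pixel (Poisson), drawn
        uniformly over the mass range away from any planted channel.
    fold_range
        Range of true sample-over-background per-pixel mean enrichment folds
        for planted channels.
    mz_values
        Optional explicit channel m/z values (planted, then background-only,
        then sparse); defaults to an even spread over 105-595 Th.
    seed
        Mandatory RNG seed; identical seeds give bit-identical output.
    """
    if seed is None:
        raise ParameterError("seed is mandatory for reproducible simulation")
    if rows < 20 or cols < 8:
        raise ParameterError("simulation needs rows >= 20 and cols >= 8")
    if ppm_jitter < 0 or noise_sigma < 0 or noise_rate < 0:
        raise ParameterError("ppm_jitter, noise_sigma and noise_rate must be >= 0")
    for p in patterns:
        if p not in PATTERNS:
            raise ParameterError(f"unknown pattern {p!r}; known: {sorted(PATTERNS)}")
    rng = np.random.default_rng(seed)

    mask = root_mask(rows, cols)
    n_planted = n_per_pattern * len(patterns)
    n_total = n_planted + n_background_only + n_sparse
    if mz_values is None:
        mzs = np.linspace(105.0, 595.0, n_total) if n_total > 1 else np.array([150.0])
    else:
        mzs = np.asarray(mz_values, dtype=np.float64)
        if len(mzs) != n_total:
            raise ParameterError(f"mz_values must list {n_total} channel m/z values")
    fg_pixels = np.argwhere(mask.grid)
    n_fg = len(fg_pixels)

    channels: list[ChannelTruth] = []
    lateral_weight: list[np.ndarray | None] = []
    idx = 0
    center_col = (cols - 1) / 2.0
    for pattern in patterns:
        for _ in range(n_per_pattern):
            profile = _BASE_AMPLITUDE * _template(pattern, rows)
            fold = float(rng.uniform(*fold_range))
            channels.append(
                ChannelTruth(float(mzs[idx]), pattern, profile, fold)
            )
            if pattern == "stripe":
                w = np.zeros(cols)
                w[np.abs(np.arange(cols) - center_col) <= 1.0] = 1.0
                lateral_weight.append(w)
            else:
                lateral_weight.append(None)
            idx += 1
    for _ in range(n_background_only):
        profile = np.full(rows, _BG_ONLY_LEVEL / 4.0)
        channels.append(
            ChannelTruth(float(mzs[idx]), "background", profile, 0.25, background_only=True)
        )
        lateral_weight.append(None)
        idx += 1

    # isolated pixels for sparse channels: a coarse lattice guarantees that
    # no two chosen pixels are 8-adjacent
    lattice = [
        (r, c) for r, c in fg_pixels if r % 3 == 1 and c % 3 == 1
    ]
    sparse_sites: list[list[tuple[int, int]]] = []
    for _ in range(n_sparse):
        k = min(10, len(lattice))
        pick = rng.choice(len(lattice), size=k, replace=False)
        sparse_sites.append([lattice[i] for i in pick])
        profile = np.zeros(rows)
        channels.append(
            ChannelTruth(float(mzs[idx]), "sparse", profile, np.inf, sparse=True)
        )
        lateral_weight.append(None)
        idx += 1

    hot = []
    if n_hot_pixels > 0:
        pick = rng.choice(n_fg, size=min(n_hot_pixels, n_fg), replace=False)
        hot = [tuple(int(v) for v in fg_pixels[i]) for i in pick]

    # per-channel mean level outside the mask, from the true fold
    bg_level = np.zeros(len(channels))
    for i, ch in enumerate(channels):
        if ch.background_only:
            bg_level[i] = _BG_ONLY_LEVEL
        elif ch.sparse:
            bg_level[i] = 0.0
        else:
            fg_mean = float(np.mean([ch.profile[r] for r, _ in fg_pixels]))
            bg_level[i] = fg_mean / ch.true_fold

    sparse_lookup = {}
    si = 0
    for i, ch in enumerate(channels):
        if ch.sparse:
            sparse_lookup[i] = set(sparse_sites[si])
            si += 1

    def noisy(value: float) -> float:
        if noise_sigma == 0:
            return value
        return value * rng.lognormal(mean=-0.5 * noise_sigma**2, sigma=noise_sigma)

    def jittered(mz: float) -> float:
        if ppm_jitter == 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, ppm_jitter * 1e-6))

    grid = MSIGrid.empty(rows, cols)
    mz_sorted = np.sort(mzs)
    for r in range(rows):
        for c in range(cols):
            inside = bool(mask.grid[r, c])
            entry_mz: list[float] = []
            entry_int: list[float] = []
            for i, ch in enumerate(channels):
                if ch.sparse:
                    if inside and (r, c) in sparse_lookup[i]:
                        level = _SPARSE_INTENSITY
                    else:
                        continue
                elif inside:
                    level = ch.profile[r]
                    w = lateral_weight[i]
                    if w is not None:
                        level *= w[c]
                else:
                    level = bg_level[i]
                if level <= 0:
                    continue
                entry_mz.append(jittered(ch.true_mz))
                entry_int.append(noisy(level))
            if noise_rate > 0:
                for _ in range(rng.poisson(noise_rate)):
                    m = _draw_noise_mz(rng, mz_sorted)
                    entry_mz.append(m)
                    entry_int.append(5.0 * rng.exponential())
            if not entry_mz:
                continue
            mz_arr = np.array(entry_mz)
            int_arr = np.array(entry_int)
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, int_arr = mz_arr[order], int_arr[order]
            # merge the (vanishingly rare) exact m/z collisions
            uniq, inverse = np.unique(mz_arr, return_inverse=True)
            if len(uniq) != len(mz_arr):
                summed = np.zeros(len(uniq))
                np.add.at(summed, inverse, int_arr)
                mz_arr, int_arr = uniq, summed
            grid[r, c] = PixelSpectrum(mz_arr, int_arr)

    for r, c in hot:
        spec = grid[r, c]
        grid[r, c] = PixelSpectrum(spec.mz, spec.intensity * _HOT_PIXEL_FACTOR)

    gt = GroundTruth(
        mask=mask,
        channels=tuple(channels),
        hot_pixels=tuple(hot),
        seed=seed,
    )
    return grid, gt


def _draw_noise_mz(rng: np.random.Generator, planted: np.ndarray) -> float:
    """Uniform m/z in [100, 600] rejected within 25 ppm of any planted channel."""
    for _ in range(100):
        m = rng.uniform(100.0, 600.0)
        i = np.searchsorted(planted, m)
        ok = True
        for j in (i - 1, i):
            if 0 <= j < len(planted) and abs(m - planted[j]) / planted[j] * 1e6 < 25:
                ok = False
                break
        if ok:
            return m
    raise RuntimeError("could not place a noise entry away from planted channels")


def expected_linescan(gt: GroundTruth, channel: int | float) -> np.ndarray:
    """Noiseless normalized per-row profile of a planted channel.

    ``channel`` is a ground-truth index or a true m/z value.  The profile is
    what the pipeline's normalized (unsmoothed) linescan converges to as
    noise goes to zero.
    """
    if isinstance(channel, (int, np.integer)):
        if not 0 <= channel < len(gt.channels):
            raise KeyError(f"no ground-truth channel index {channel}")
        ch = gt.channels[channel]
    else:
        ch = gt.channel_by_mz(float(channel))
    peak = ch.profile.max()
    if peak == 0:
        return ch.profile.copy()
    return ch.profile / peak
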