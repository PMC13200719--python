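"""Linescan projection, normalization, Ward clustering, and channel exports.

A linescan is the maximum projection of one hyperspectral channel across the
lateral axis, leaving a 1D intensity profile along the developmental axis
(row 0 = root tip).  Each linescan is normalized to a maximum of 1, smoothed
with a running median (10 pixels by default), and the set of linescans is
clustered hierarchically with Ward's linkage on Euclidean distances.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.cluster.hierarchy import cut_tree, dendrogram, linkage

from dimple._smoothing import running_median
from dimple.errors import ChannelNotFoundError, ParameterError
from dimple.preprocess import HyperspectralImage

logger = logging.getLogger("dimple.linescan")

__all__ = [
    "Linescan",
    "LinescanSet",
    "ClusterResult",
    "project_linescan",
    "normalize_and_smooth",
    "cluster_linescans",
    "render_linescan_graph",
    "export_channel_image",
]


@dataclass(frozen=True)
class Linescan:
    """1D axial intensity profile for one channel; index 0 is the root tip."""

    values: np.ndarray
    channel_mz: float
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("linescan values must be 1D")
        if np.any(v < 0):
            raise ValueError("linescan values must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class LinescanSet:
    """Linescans for every kept channel, ascending in channel m/z."""

    linescans: list[Linescan]

    def __post_init__(self) -> None:
        if any(len(ls) != len(self.linescans[0]) for ls in self.linescans):
            raise ValueError("all linescans must share one length")

    @property
    def channel_mz(self) -> np.ndarray:
        return np.array([ls.channel_mz for ls in self.linescans])

    def matrix(self) -> np.ndarray:
        """Channels x positions matrix of linescan values."""
        return np.vstack([ls.values for ls in self.linescans])

    def __len__(self) -> int:
        return len(self.linescans)


@dataclass(frozen=True)
class ClusterResult:
    """Ward clustering of linescans cut to exactly ``k`` clusters.

    ``assignments[i]`` is the 1-based cluster id of channel i (clusters are
    numbered by the ascending m/z of their first member); ``ordering`` is the
    display order of channel indices, by cluster then by m/z.
    """

    assignments: np.ndarray
    linkage: np.ndarray
    k: int
    ordering: np.ndarray


def project_linescan(hsi: HyperspectralImage, axis: str = "rows") -> LinescanSet:
    """Maximum projection of every channel across the lateral axis.

    With ``axis='rows'`` (default) the developmental axis is the row axis and
    the maximum is taken over columns: ``values[r] = max_c cube[ch, r, c]``.
    ``axis='cols'`` projects the other way for sections mounted sideways.
    """
    if hsi.n_channels == 0:
        raise ParameterError("hyperspectral image has no kept channels to project")
    if axis == "rows":
        mat = hsi.cube.max(axis=2)
    elif axis == "cols":
        mat = hsi.cube.max(axis=1)
    else:
        raise ParameterError("axis must be 'rows' or 'cols'")
    return LinescanSet(
        [Linescan(mat[i], float(hsi.channel_mz[i])) for i in range(hsi.n_channels)]
    )


def normalize_and_smooth(ls: Linescan, filter_width: int = 10) -> Linescan:
    """Normalize to max 1, then median-smooth — in that order.

    An all-zero profile stays all-zero.  The running median uses truncated
    windows at the edges; even widths put the extra window element on the
    leading side and take the lower median.  No re-normalization happens
    after smoothing, so the smoothed maximum can fall below 1.
    """
    if filter_width < 1:
        raise ParameterError("filter_width must be >= 1")
    if np.any(ls.values < 0):
        raise ValueError("linescan values must be non-negative")
    peak = ls.values.max() if len(ls.values) else 0.0
    normed = ls.values / peak if peak > 0 else ls.values.copy()
    smoothed = running_median(normed, filter_width)
    return Linescan(smoothed, ls.channel_mz, normalized=True)


def cluster_linescans(lset: LinescanSet, k: int) -> ClusterResult:
    """Ward's hierarchical clustering of linescans, cut to exactly k clusters.

    Distances are Euclidean norms between linescans.  The merge tree is
    deterministic given input order; cluster ids are relabeled 1..k in the
    order clusters first appear along ascending channel m/z.
    """
    n = len(lset)
    if n < 2:
        raise ParameterError("clustering needs at least two linescans")
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    X = lset.matrix()
    Z = linkage(X, method="ward")
    raw = cut_tree(Z, n_clusters=k).ravel()
    # relabel so cluster 1 holds the smallest-m/z channel, etc.
    order = np.argsort(lset.channel_mz, kind="stable")
    relabel: dict[int, int] = {}
    for i in order:
        if raw[i] not in relabel:
            relabel[raw[i]] = len(relabel) + 1
    assignments = np.array([relabel[c] for c in raw])
    mz = lset.channel_mz
    ordering = np.array(
        sorted(range(n), key=lambda i: (assignments[i], mz[i]))
    )
    return ClusterResult(assignments=assignments, linkage=Z, k=k, ordering=ordering)


def merge_height_elbow(Z: np.ndarray) -> int:
    """Suggested cluster count from the largest gap in merge heights.

    Guidance only — the cluster count is always a user decision, made by
    inspecting the dendrogram.
    """
    heights = Z[:, 2]
    if len(heights) < 2:
        return 2
    gaps = np.diff(heights)
    return int(len(heights) - np.argmax(gaps))


def render_linescan_graph(
    lset: LinescanSet,
    result: ClusterResult,
    path: str | os.PathLike,
    order: str = "ascending",
) -> str:
    """Write the clustered linescan heatmap and its dendrogram.

    One column per channel, grouped by cluster and ordered by m/z within each
    cluster (``order='descending'`` reverses the within-cluster order); the
    y axis is the axial position with the root tip (index 0) at the top.
    Returns the dendrogram path (``<stem>_dendrogram.png``).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if order not in ("ascending", "descending"):
        raise ParameterError("order must be 'ascending' or 'descending'")
    path = os.fspath(path)
    col_order = list(result.ordering)
    if order == "descending":
        rev: list[int] = []
        for cid in sorted(set(result.assignments)):
            members = [i for i in col_order if result.assignments[i] == cid]
            rev.extend(members[::-1])
        col_order = rev
    mat = lset.matrix()[col_order].T  # positions x channels

    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(max(6, 0.12 * len(col_order)), 7),
        gridspec_kw={"height_ratios": [1, 24], "hspace": 0.02},
    )
    cluster_row = np.array([result.assignments[i] for i in col_order])[None, :]
    ax_bar.imshow(cluster_row, aspect="auto", cmap="tab10", vmin=1, vmax=max(10, result.k))
    ax_bar.set_yticks([])
    ax_bar.set_xticks([])
    for cid in sorted(set(result.assignments)):
        cols = np.nonzero(cluster_row[0] == cid)[0]
        ax_bar.text(cols.mean(), 0, str(cid), ha="center", va="center", fontsize=8)
    im = ax.imshow(mat, aspect="auto", origin="upper", cmap="viridis", vmin=0, vmax=1)
    ax.set_xlabel("m/z linescans (grouped by cluster)")
    ax.set_ylabel("Position along root axis (pixels; 0 = root tip)")
    cb = fig.colorbar(im, ax=ax, fraction=0.04)
    cb.set_label("Normalized Intensity")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    stem, _ = os.path.splitext(path)
    dendro_path = f"{stem}_dendrogram.png"
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(
        result.linkage,
        labels=[f"{m:.4f}" for m in lset.channel_mz],
        leaf_rotation=90,
        ax=ax,
    )
    ax.set_ylabel("Ward merge height")
    fig.savefig(dendro_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return dendro_path


def export_channel_image(
    hsi: HyperspectralImage,
    channel_mz: float,
    path: str | os.PathLike,
    ppm_tol: float = 5.0,
    tic_normalize: bool = False,
    include_removed: bool = True,
) -> float:
    """Write the 2D image of the channel nearest ``channel_mz``.

    Searches kept channels (and removed ones unless ``include_removed`` is
    False) for the nearest center within ``ppm_tol``; errors list the nearest
    candidates otherwise.  With ``tic_normalize``, every in-mask pixel is
    divided by that pixel's TIC (the sum of the cube over kept channels)
    before display scaling.  Writes float TIFF for .tif/.tiff paths, 8-bit
    PNG otherwise.  Returns the exported channel's m/z.
    """
    if ppm_tol <= 0:
        raise ParameterError("ppm_tol must be positive")
    mzs = np.concatenate([hsi.channel_mz, hsi.removed_mz if include_removed else []])
    cubes = (
        np.concatenate([hsi.cube, hsi.removed_cube], axis=0)
        if include_removed and len(hsi.removed_mz)
        else hsi.cube
    )
    if len(mzs) == 0:
        raise ChannelNotFoundError("hyperspectral image has no channels")
    dist_ppm = np.abs(mzs - channel_mz) / channel_mz * 1e6
    idx = int(np.argmin(dist_ppm))
    if dist_ppm[idx] > ppm_tol:
        nearest = mzs[np.argsort(dist_ppm)[:3]]
        raise ChannelNotFoundError(
            f"no channel within {ppm_tol} ppm of m/z {channel_mz}; nearest: "
            + ", ".join(f"{m:.4f}" for m in nearest)
        )
    img = cubes[idx].astype(np.float64)
    if tic_normalize:
        tic = hsi.cube.sum(axis=0)
        out = np.zeros_like(img)
        inside = hsi.mask.grid & (tic > 0)
        out[inside] = img[inside] / tic[inside]
        img = out
    logger.info(
        "exporting channel m/z %.4f (%.2f ppm from requested %.4f)",
        mzs[idx], dist_ppm[idx], channel_mz,
    )
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img.astype(np.float32), photometric="minisblack")
    else:
        from PIL import Image

        peak = img.max()
        scaled = (img / peak * 255).astype(np.uint8) if peak > 0 else img.astype(np.uint8)
        Image.fromarray(scaled, mode="L").save(path)
    return float(mzs[idx])
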