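"""Replicate pooling and cross-variety comparison of m/z peak lists.

Replicate peak lists are pooled into unique features within an absolute m/z
tolerance (0.001 Th by default), and pooled lists from two varieties are
matched one-to-one within the same tolerance to count shared and
variety-unique mass signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from dimple.errors import ParameterError

__all__ = ["PeakList", "pool_unique", "compare_lists", "ComparisonResult"]


@dataclass(frozen=True)
class PeakList:
    """Ascending, duplicate-free m/z values with a replicate/variety label."""

    mz: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        if mz.ndim != 1:
            raise ValueError("peak list m/z must be 1D")
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("peak list m/z must be strictly ascending without duplicates")
        object.__setattr__(self, "mz", mz)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class ComparisonResult:
    """Matched (shared) and unmatched features from a two-list comparison."""

    shared_a: np.ndarray  # m/z of matched features, from list a
    shared_b: np.ndarray  # their partners in list b, same order
    unique_a: np.ndarray
    unique_b: np.ndarray

    @property
    def n_shared(self) -> int:
        return len(self.shared_a)


def pool_unique(
    lists: Sequence[PeakList],
    tol: float = 0.001,
    mode: str = "greedy",
    label: str = "pooled",
) -> PeakList:
    """Pool peak lists into unique features within an absolute m/z tolerance.

    ``mode='greedy'`` (default) anchors a group at the smallest unassigned
    value v and absorbs every value <= v + tol, so a chain like
    100.0000/100.0005/100.0011 with tol 0.001 splits after the anchor window.
    ``mode='transitive'`` instead merges any chain of values whose successive
    gaps are <= tol (single-linkage closure).  Group representatives are the
    member means.
    """
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    if mode not in ("greedy", "transitive"):
        raise ParameterError("mode must be 'greedy' or 'transitive'")
    if len(lists) == 0:
        raise ParameterError("at least one peak list is required")
    values = np.sort(np.concatenate([pl.mz for pl in lists]))
    if len(values) == 0:
        return PeakList(values, label)
    reps: list[float] = []
    if mode == "greedy":
        i = 0
        while i < len(values):
            anchor = values[i]
            j = i
            while j < len(values) and values[j] <= anchor + tol:
                j += 1
            reps.append(float(values[i:j].mean()))
            i = j
    else:
        start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] - values[i - 1] > tol:
                reps.append(float(values[start:i].mean()))
                start = i
    return PeakList(np.array(reps), label)


def compare_lists(a: PeakList, b: PeakList, tol: float = 0.001) -> ComparisonResult:
    """Match two pooled lists one-to-one within tolerance.

    All cross pairs with |delta m/z| <= tol are matched greedily in order of
    ascending |delta| (ties by list position), each feature matching at most
    once; matched pairs are shared, leftovers are unique to their list.
    """
    if tol <= 0:
        raise ParameterError("tolerance must be positive")
    pairs: list[tuple[float, int, int]] = []
    for i, va in enumerate(a.mz):
        lo = np.searchsorted(b.mz, va - tol, side="left")
        hi = np.searchsorted(b.mz, va + tol, side="right")
        for j in range(lo, hi):
            pairs.append((abs(va - b.mz[j]), i, j))
    pairs.sort()
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    matched: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            matched.append((i, j))
    matched.sort()
    return ComparisonResult(
        shared_a=np.array([a.mz[i] for i, _ in matched]),
        shared_b=np.array([b.mz[j] for _, j in matched]),
        unique_a=a.mz[~used_a],
        unique_b=b.mz[~used_b],
    )
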