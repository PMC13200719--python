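"""Independent brute-force reference implementations used only by tests.

Each oracle restates the operation's definition as directly as possible
(nested loops, exhaustive scans) without sharing code with the package.
"""

from __future__ import annotations

import numpy as np


def brute_consensus_peaks(mz, intensity, window_ppm):
    """All entries strictly maximal within +/- (mz_i * ppm / 1e6), ties to lower m/z."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    centers = []
    for i in range(len(mz)):
        half = mz[i] * window_ppm / 1e6
        is_center = True
        for j in range(len(mz)):
            if j == i or abs(mz[j] - mz[i]) > half:
                continue
            if intensity[j] > intensity[i] or (intensity[j] == intensity[i] and mz[j] < mz[i]):
                is_center = False
                break
        if is_center:
            centers.append((mz[i], intensity[i]))
    return centers


def brute_running_median(values, width):
    """Truncated windows; even widths lead-heavy; lower median."""
    values = list(map(float, values))
    n = len(values)
    before = width // 2 if width % 2 == 0 else (width - 1) // 2
    after = (width - 1) // 2
    out = []
    for i in range(n):
        window = sorted(values[max(0, i - before):min(n, i + after + 1)])
        out.append(window[(len(window) - 1) // 2])
    return out


def brute_sparse_channel_removed(channel_image):
    """True iff no nonzero pixel has a fully nonzero 3x3 neighbourhood
    (borders count as zero)."""
    img = np.asarray(channel_image)
    rows, cols = img.shape
    for r in range(rows):
        for c in range(cols):
            if img[r, c] <= 0:
                continue
            full = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols) or img[rr, cc] <= 0:
                        full = False
            if full:
                return False
    return True


def brute_pool_greedy(values, tol):
    """Anchor at the smallest unassigned value; absorb everything <= anchor + tol."""
    values = sorted(values)
    reps = []
    i = 0
    while i < len(values):
        group = [values[i]]
        j = i + 1
        while j < len(values) and values[j] <= values[i] + tol:
            group.append(values[j])
            j += 1
        reps.append(sum(group) / len(group))
        i = j
    return reps


def brute_ward_partition(X, k):
    """Naive agglomerative Ward: merge the pair with the smallest increase in
    within-cluster sum of squares until k clusters remain."""
    X = np.asarray(X, dtype=float)
    clusters = [[i] for i in range(len(X))]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = X[clusters[a]].mean(axis=0)
                cb = X[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                d = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def partition_from_labels(labels):
    out = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, set()).add(i)
    return {frozenset(s) for s in out.values()}


def brute_hot_pixel_rescale(tic, k):
    """Expected TIC image after hot-pixel suppression (scan of 8-neighbourhoods)."""
    tic = np.asarray(tic, dtype=float)
    rows, cols = tic.shape
    out = tic.copy()
    for r in range(rows):
        for c in range(cols):
            neigh = [
                tic[rr, cc]
                for rr in range(max(0, r - 1), min(rows, r + 2))
                for cc in range(max(0, c - 1), min(cols, c + 2))
                if (rr, cc) != (r, c)
            ]
            med = float(np.median(neigh))
            mad = float(np.median(np.abs(np.array(neigh) - med)))
            if tic[r, c] > med + k * mad and tic[r, c] > 0:
                out[r, c] = med
    return out
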