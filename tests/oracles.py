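"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: exterior air is found
by hand-rolled BFS, distances by exhaustive pairwise scans, ANOVA sums of
squares by explicit loops, and silhouette overlap by rotating full binary
masks and counting pixels.
"""

from collections import deque

import numpy as np
from scipy import ndimage

from rdtsim.volume import BACKGROUND, CANAL, DENTIN, REMOVED, ToothVolume


def bfs_exterior(labels: np.ndarray) -> np.ndarray:
    """Background voxels 6-connected to the grid boundary, by explicit BFS."""
    bg = labels == BACKGROUND
    ext = np.zeros_like(bg)
    nx, ny, nz = labels.shape
    queue: deque = deque()
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if (i in (0, nx - 1) or j in (0, ny - 1) or k in (0, nz - 1)) and bg[
                    i, j, k
                ]:
                    if not ext[i, j, k]:
                        ext[i, j, k] = True
                        queue.append((i, j, k))
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in (
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ):
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                if bg[a, b, c] and not ext[a, b, c]:
                    ext[a, b, c] = True
                    queue.append((a, b, c))
    return ext


def brute_force_thickness(volume: ToothVolume, roi):
    """All-pairs surface-to-exterior distance scan (tiny grids only).

    Returns (surface voxel indices, thickness μm) in the same C order the
    implementation uses.
    """
    labels = volume.labels
    ext = bfs_exterior(labels)
    ext_pts = np.argwhere(ext).astype(float)
    cavity = (labels == CANAL) | (labels == REMOVED)
    k0, k1 = roi
    surface = []
    nx, ny, nz = labels.shape
    for i, j, k in np.argwhere(cavity):
        if not (k0 <= k < k1):
            continue
        for di, dj, dk in (
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ):
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz and labels[a, b, c] == DENTIN:
                surface.append((i, j, k))
                break
    surface = np.asarray(surface)
    dists = np.empty(len(surface))
    for n, p in enumerate(surface):
        d2 = np.sum((ext_pts - p.astype(float)) ** 2, axis=1)
        dists[n] = np.sqrt(d2.min()) * volume.voxel_size_um
    return surface, dists


def icc_oracle(table: np.ndarray, model: str) -> float:
    """Single-measure ICC from explicitly looped sums of squares."""
    t = np.asarray(table, float)
    n, k = t.shape
    grand = t.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (t[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (t[:, j].mean() - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (t[i, j] - grand) ** 2
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def brute_force_parallax(
    volume: ToothVolume, tag_a: str, tag_b: str, step_deg: float, max_deg: float = 60.0
) -> float:
    """First angle with zero silhouette pixel overlap, by rotating the full
    binary masks (nearest-neighbour) and counting overlapping pixels."""
    a = volume.structures[tag_a].astype(np.float32)
    b = volume.structures[tag_b].astype(np.float32)
    n = int(np.ceil(np.hypot(*a.shape[:2]))) + 2
    pads = []
    for dim in a.shape[:2]:
        s = n if (n - dim) % 2 == 0 else n + 1
        p = (s - dim) // 2
        pads.append((p, p))
    a = np.pad(a, (*pads, (0, 0)))
    b = np.pad(b, (*pads, (0, 0)))
    for ang in np.arange(0.0, max_deg + step_deg / 2, step_deg):
        # ndimage.rotate's positive angle turns content the opposite way to
        # the package's x' = x cos + y sin convention; negate to scan the
        # same physical rotation.
        ra = ndimage.rotate(a, -ang, axes=(0, 1), order=0, reshape=False) > 0.5
        rb = ndimage.rotate(b, -ang, axes=(0, 1), order=0, reshape=False) > 0.5
        sa = ra.any(axis=1)
        sb = rb.any(axis=1)
        if not np.any(sa & sb):
            return float(ang)
    raise AssertionError("no separation found by brute force")
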