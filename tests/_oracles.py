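"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: distances come from
exhaustive nearest-neighbour queries over explicit coordinate lists
(cKDTree), the chi-square statistic is accumulated cell by cell from its
definition, and footprint fractions are counted directly.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2 as chi2_dist


def nn_distance_to(points_from: np.ndarray, points_to: np.ndarray) -> np.ndarray:
    """Exact Euclidean nearest-neighbour distances (brute enumeration via
    KD-tree, independent of any distance-transform code)."""
    if len(points_to) == 0:
        return np.full(len(points_from), np.inf)
    tree = cKDTree(points_to)
    d, _ = tree.query(points_from, k=1)
    return d


def erode_oracle(mask: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Keep foreground voxels whose spacing-aware distance to the nearest
    background voxel exceeds margin."""
    sp = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * sp
    bg = np.argwhere(~mask) * sp
    out = np.zeros_like(mask)
    if len(fg) == 0:
        return out
    if len(bg) == 0:
        return mask.copy()
    d = nn_distance_to(fg, bg)
    keep = np.argwhere(mask)[d > margin]
    out[tuple(keep.T)] = True
    return out


def dilate_oracle(mask: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Add background voxels within spacing-aware distance margin of the mask."""
    sp = np.asarray(spacing, dtype=float)
    fg = np.argwhere(mask) * sp
    bg_idx = np.argwhere(~mask)
    out = mask.copy()
    if len(fg) == 0 or len(bg_idx) == 0:
        return out
    d = nn_distance_to(bg_idx * sp, fg)
    add = bg_idx[d <= margin]
    out[tuple(add.T)] = True
    return out


def shell_oracle(cluster: np.ndarray, wm: np.ndarray, k: int,
                 thickness: float) -> np.ndarray:
    """Distance-band shell k by explicit nearest-cluster-voxel distances."""
    src = np.argwhere(cluster).astype(float)
    rest = np.argwhere(~cluster)
    d = nn_distance_to(rest.astype(float), src)
    band = rest[(d > thickness * (k - 1)) & (d <= thickness * k)]
    out = np.zeros_like(cluster)
    out[tuple(band.T)] = True
    return out & wm & ~cluster


def chi2_oracle(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square accumulated cell by cell from first principles."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    dof = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, dof))


def footprint_fraction_oracle(mask: np.ndarray, factor: int) -> np.ndarray:
    """Coverage fraction of each coarse voxel's footprint, by direct count."""
    nx, ny, nz = (s // factor for s in mask.shape)
    out = np.zeros((nx, ny, nz))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                blk = mask[i * factor:(i + 1) * factor,
                           j * factor:(j + 1) * factor,
                           k * factor:(k + 1) * factor]
                out[i, j, k] = blk.mean()
    return out
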