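"""Construction of the five texture matrices from a discretized ROI.

All neighborhoods are at Chebyshev distance 1: GLCM and GLRLM use the 13
unique 3D direction vectors (26 neighbors, symmetric halves), GLSZM uses
26-connected zones, GLDM counts 26-neighborhood dependences at zero
gray-level tolerance, and NGTDM averages over the 26-neighborhood.
Matrices are stored as raw counts; normalization happens in the feature
formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedROI

__all__ = ["TextureMatrices", "build_matrices", "ANGLES_13", "OFFSETS_26"]

# 13 unique direction vectors at Chebyshev distance 1 (one of each +/-
# pair of the 26 neighbor offsets), oriented so the first nonzero
# component is +1.
_all = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
ANGLES_13 = tuple(sorted(o for o in _all if o > tuple(-c for c in o)))
OFFSETS_26 = tuple(sorted(_all))
del _all

assert len(ANGLES_13) == 13 and len(OFFSETS_26) == 26


@dataclass
class TextureMatrices:
    """Raw-count texture matrices of one discretized ROI.

    glcm : (13, Ng, Ng) symmetric pair counts per direction
    glrlm : (13, Ng, Lmax) run counts per direction
    glszm : (Ng, Smax) 26-connected zone counts
    gldm : (Ng, Dmax) dependence counts; column c holds voxels with c
        dependent neighbors, i.e. dependence size j = c + 1 including
        the center voxel
    ngtdm_n, ngtdm_s : per-level voxel counts and summed absolute
        neighborhood differences
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm_n: np.ndarray
    ngtdm_s: np.ndarray
    n_levels: int
    n_voxels: int


def _crop_to_mask(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    return levels[slices], mask[slices]


def _pad(levels: np.ndarray) -> np.ndarray:
    return np.pad(levels, 1, mode="constant", constant_values=0)


def _shifted(padded: np.ndarray, offset: tuple[int, int, int], shape) -> np.ndarray:
    dx, dy, dz = offset
    return padded[
        1 + dx : 1 + dx + shape[0],
        1 + dy : 1 + dy + shape[1],
        1 + dz : 1 + dz + shape[2],
    ]


def _glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    padded = _pad(levels)
    out = np.zeros((len(ANGLES_13), n_levels, n_levels), dtype=np.float64)
    for a, offset in enumerate(ANGLES_13):
        nb = _shifted(padded, offset, levels.shape)
        valid = (levels > 0) & (nb > 0)
        if not valid.any():
            continue
        idx = (levels[valid] - 1) * n_levels + (nb[valid] - 1)
        counts = np.bincount(idx, minlength=n_levels * n_levels)
        mat = counts.reshape(n_levels, n_levels).astype(np.float64)
        out[a] = mat + mat.T  # symmetric: count each pair in both orders
    return out


def _glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    coords = np.argwhere(levels > 0)
    lv = levels[levels > 0]
    n = coords.shape[0]
    per_dir: list[dict[tuple[int, int], float]] = []
    max_len = 1
    for offset in ANGLES_13:
        d = np.asarray(offset)
        axis = int(np.nonzero(d)[0][0])  # d[axis] == +1 by orientation
        t = coords[:, axis]
        key = coords - t[:, None] * d
        order = np.lexsort((t, lv, key[:, 2], key[:, 1], key[:, 0]))
        # A new run starts when the line key or level changes, or when t
        # is not consecutive along the line.
        k_s, t_s, lv_s = key[order], t[order], lv[order]
        new_run = np.ones(n, dtype=bool)
        if n > 1:
            same_line = (k_s[1:] == k_s[:-1]).all(axis=1)
            contiguous = t_s[1:] == t_s[:-1] + 1
            same_level = lv_s[1:] == lv_s[:-1]
            new_run[1:] = ~(same_line & contiguous & same_level)
        starts = np.flatnonzero(new_run)
        run_lengths = np.diff(np.append(starts, n))
        run_levels = lv_s[starts]
        max_len = max(max_len, int(run_lengths.max()))
        counts: dict[tuple[int, int], float] = {}
        for g, length in zip(run_levels, run_lengths):
            key2 = (int(g) - 1, int(length) - 1)
            counts[key2] = counts.get(key2, 0.0) + 1.0
        per_dir.append(counts)
    out = np.zeros((len(ANGLES_13), n_levels, max_len), dtype=np.float64)
    for a, counts in enumerate(per_dir):
        for (gi, li), c in counts.items():
            out[a, gi, li] = c
    return out


def _glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    structure = np.ones((3, 3, 3), dtype=np.int8)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        labeled, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((g - 1, int(s) - 1))
            max_size = max(max_size, int(s))
    out = np.zeros((n_levels, max_size), dtype=np.float64)
    for gi, si in zones:
        out[gi, si] += 1.0
    return out


def _gldm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    padded = _pad(levels)
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        nb = _shifted(padded, offset, levels.shape)
        dep += ((nb == levels) & (nb > 0) & mask).astype(np.int64)
    max_dep = int(dep[mask].max()) if mask.any() else 0
    out = np.zeros((n_levels, max_dep + 1), dtype=np.float64)
    idx = (levels[mask] - 1) * (max_dep + 1) + dep[mask]
    counts = np.bincount(idx, minlength=n_levels * (max_dep + 1))
    out[:] = counts.reshape(n_levels, max_dep + 1)
    return out


def _ngtdm(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    padded = _pad(levels)
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for offset in OFFSETS_26:
        nb = _shifted(padded, offset, levels.shape)
        inmask = nb > 0
        nb_sum += np.where(inmask, nb, 0)
        nb_cnt += inmask.astype(np.int64)
    n_i = np.zeros(n_levels, dtype=np.float64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    valid = mask & (nb_cnt > 0)
    if valid.any():
        avg = nb_sum[valid] / nb_cnt[valid]
        lv = levels[valid]
        diffs = np.abs(lv - avg)
        n_i = np.bincount(lv - 1, minlength=n_levels).astype(np.float64)
        s_i = np.bincount(lv - 1, weights=diffs, minlength=n_levels)
    else:  # isolated voxels only (e.g. single-voxel ROI)
        lv = levels[mask]
        n_i = np.bincount(lv - 1, minlength=n_levels).astype(np.float64)
    return n_i, s_i


def build_matrices(disc: DiscretizedROI) -> TextureMatrices:
    """Compute all five texture matrices of a discretized ROI."""
    mask = np.asarray(disc.mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    levels = np.where(mask, disc.levels, 0)
    levels, mask = _crop_to_mask(levels, mask)
    ng = disc.n_levels
    n_i, s_i = _ngtdm(levels, ng)
    return TextureMatrices(
        glcm=_glcm(levels, ng),
        glrlm=_glrlm(levels, ng),
        glszm=_glszm(levels, ng),
        gldm=_gldm(levels, ng),
        ngtdm_n=n_i,
        ngtdm_s=s_i,
        n_levels=ng,
        n_voxels=int(mask.sum()),
    )
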