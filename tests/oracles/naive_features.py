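"""Brute-force oracle for the feature engine.

Everything here is written as direct loop-based transcriptions of the
feature definitions, independent of the package's vectorized code paths:
matrices are accumulated pair by pair, zones grow by breadth-first
search, and every feature is an explicit double sum.  Slow by design;
only for small ROIs in tests.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

EPS = np.spacing(1.0)

# one representative of each +/- offset pair, first nonzero component +1
DIRECTIONS = []
for dx in (-1, 0, 1):
    for dy in (-1, 0, 1):
        for dz in (-1, 0, 1):
            if (dx, dy, dz) == (0, 0, 0):
                continue
            if (dx, dy, dz) > (-dx, -dy, -dz):
                DIRECTIONS.append((dx, dy, dz))
DIRECTIONS.sort()
NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(levels, x, y, z):
    return (
        0 <= x < levels.shape[0]
        and 0 <= y < levels.shape[1]
        and 0 <= z < levels.shape[2]
        and levels[x, y, z] > 0
    )


def naive_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric pair counts, (13, ng, ng)."""
    out = np.zeros((len(DIRECTIONS), ng, ng))
    for a, (dx, dy, dz) in enumerate(DIRECTIONS):
        for x in range(levels.shape[0]):
            for y in range(levels.shape[1]):
                for z in range(levels.shape[2]):
                    if levels[x, y, z] <= 0:
                        continue
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if _inside(levels, nx, ny, nz):
                        i, j = levels[x, y, z] - 1, levels[nx, ny, nz] - 1
                        out[a, i, j] += 1
                        out[a, j, i] += 1
    return out


def naive_glrlm(levels: np.ndarray, ng: int) -> list[dict[tuple[int, int], int]]:
    """Per-direction {(level, run length): count} dictionaries."""
    result = []
    for dx, dy, dz in DIRECTIONS:
        counts: dict[tuple[int, int], int] = {}
        seen = np.zeros(levels.shape, dtype=bool)
        for x in range(levels.shape[0]):
            for y in range(levels.shape[1]):
                for z in range(levels.shape[2]):
                    if levels[x, y, z] <= 0 or seen[x, y, z]:
                        continue
                    # only start runs at voxels with no same-run predecessor
                    px, py, pz = x - dx, y - dy, z - dz
                    if _inside(levels, px, py, pz) and levels[px, py, pz] == levels[x, y, z]:
                        continue
                    g = int(levels[x, y, z])
                    length = 0
                    cx, cy, cz = x, y, z
                    while _inside(levels, cx, cy, cz) and levels[cx, cy, cz] == g:
                        seen[cx, cy, cz] = True
                        length += 1
                        cx, cy, cz = cx + dx, cy + dy, cz + dz
                    counts[(g, length)] = counts.get((g, length), 0) + 1
        seen[:] = False
        result.append(counts)
    return result


def naive_glszm(levels: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """{(level, zone size): count} by 26-connected flood fill."""
    seen = np.zeros(levels.shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for x in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for z in range(levels.shape[2]):
                if levels[x, y, z] <= 0 or seen[x, y, z]:
                    continue
                g = int(levels[x, y, z])
                size = 0
                queue = deque([(x, y, z)])
                seen[x, y, z] = True
                while queue:
                    cx, cy, cz = queue.popleft()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            _inside(levels, nx, ny, nz)
                            and not seen[nx, ny, nz]
                            and levels[nx, ny, nz] == g
                        ):
                            seen[nx, ny, nz] = True
                            queue.append((nx, ny, nz))
                counts[(g, size)] = counts.get((g, size), 0) + 1
    return counts


def naive_gldm(levels: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """{(level, dependence size): count}; size counts the center voxel."""
    counts: dict[tuple[int, int], int] = {}
    for x in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for z in range(levels.shape[2]):
                if levels[x, y, z] <= 0:
                    continue
                g = int(levels[x, y, z])
                dep = 1
                for dx, dy, dz in NEIGHBORS_26:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if _inside(levels, nx, ny, nz) and levels[nx, ny, nz] == g:
                        dep += 1
                counts[(g, dep)] = counts.get((g, dep), 0) + 1
    return counts


def naive_ngtdm(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for x in range(levels.shape[0]):
        for y in range(levels.shape[1]):
            for z in range(levels.shape[2]):
                g = int(levels[x, y, z])
                if g <= 0:
                    continue
                nb = [
                    int(levels[x + dx, y + dy, z + dz])
                    for dx, dy, dz in NEIGHBORS_26
                    if _inside(levels, x + dx, y + dy, z + dz)
                ]
                if nb:
                    n_i[g - 1] += 1
                    s_i[g - 1] += abs(g - sum(nb) / len(nb))
    return n_i, s_i


# ---------------------------------------------------------------------------
# feature formulas as explicit sums


def glcm_features_from_counts(counts: np.ndarray) -> dict[str, float]:
    per_dir = []
    for mat in counts:
        ng = mat.shape[0]
        total = mat.sum()
        if total == 0:
            per_dir.append(None)
            continue
        p = mat / total
        px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
        mu = sum((i + 1) * px[i] for i in range(ng))
        sig2 = sum(px[i] * ((i + 1) - mu) ** 2 for i in range(ng))
        sig = math.sqrt(sig2)

        p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
        p_diff = {k: 0.0 for k in range(ng)}
        for i in range(ng):
            for j in range(ng):
                p_sum[i + j + 2] += p[i][j]
                p_diff[abs(i - j)] += p[i][j]

        f: dict[str, float] = {}
        f["Autocorrelation"] = sum(
            p[i][j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
        )
        f["JointAverage"] = mu
        for name, power in (("ClusterProminence", 4), ("ClusterShade", 3), ("ClusterTendency", 2)):
            f[name] = sum(
                p[i][j] * ((i + 1) + (j + 1) - 2 * mu) ** power
                for i in range(ng)
                for j in range(ng)
            )
        f["Contrast"] = sum(
            p[i][j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
        )
        f["Correlation"] = (
            (f["Autocorrelation"] - mu * mu) / sig2 if sig2 > 0 else 1.0
        )
        da = sum(k * v for k, v in p_diff.items())
        f["DifferenceAverage"] = da
        f["DifferenceEntropy"] = -sum(v * math.log2(v + EPS) for v in p_diff.values())
        f["DifferenceVariance"] = sum(v * (k - da) ** 2 for k, v in p_diff.items())
        f["JointEnergy"] = sum(p[i][j] ** 2 for i in range(ng) for j in range(ng))
        hxy = -sum(
            p[i][j] * math.log2(p[i][j] + EPS) for i in range(ng) for j in range(ng)
        )
        f["JointEntropy"] = hxy
        hx = -sum(px[i] * math.log2(px[i] + EPS) for i in range(ng))
        hxy1 = -sum(
            p[i][j] * math.log2(px[i] * px[j] + EPS)
            for i in range(ng)
            for j in range(ng)
        )
        hxy2 = -sum(
            px[i] * px[j] * math.log2(px[i] * px[j] + EPS)
            for i in range(ng)
            for j in range(ng)
        )
        f["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
        f["Imc2"] = (
            math.sqrt(1 - math.exp(-2 * (hxy2 - hxy))) if hxy2 >= hxy else 0.0
        )
        f["Idm"] = sum(
            p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)
        )
        f["Idmn"] = sum(
            p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)
        )
        f["Id"] = sum(
            p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)
        )
        f["Idn"] = sum(
            p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
        )
        f["InverseVariance"] = sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        )
        f["MaximumProbability"] = max(
            p[i][j] for i in range(ng) for j in range(ng)
        )
        f["SumAverage"] = sum(k * v for k, v in p_sum.items())
        f["SumEntropy"] = -sum(v * math.log2(v + EPS) for v in p_sum.values())
        f["SumSquares"] = sum(
            p[i][j] * ((i + 1) - mu) ** 2 for i in range(ng) for j in range(ng)
        )
        present = [i for i in range(ng) if px[i] > 0]
        if len(present) < 2:
            f["MCC"] = 1.0
        else:
            q = np.zeros((len(present), len(present)))
            for a, i in enumerate(present):
                for b, j in enumerate(present):
                    q[a, b] = sum(
                        p[i][k] * p[j][k] / (px[i] * px[k])
                        for k in present
                    )
            eig = sorted(np.real(np.linalg.eigvals(q)))
            f["MCC"] = math.sqrt(max(eig[-2], 0.0))
        per_dir.append(f)
    names = per_dir[next(i for i, d in enumerate(per_dir) if d is not None)].keys()
    return {
        name: float(np.mean([d[name] for d in per_dir if d is not None]))
        for name in names
    }


def _sdm_features(entries: dict[tuple[int, int], float], n_voxels: int, prefix: str) -> dict[str, float]:
    """Shared small/large-times-gray-level formula block for RLM-style
    matrices given sparse {(level, size): count} entries."""
    nz = sum(entries.values())
    pg: dict[int, float] = {}
    ps: dict[int, float] = {}
    for (g, s), c in entries.items():
        pg[g] = pg.get(g, 0) + c
        ps[s] = ps.get(s, 0) + c
    mu_g = sum(g * c for (g, s), c in entries.items()) / nz
    mu_s = sum(s * c for (g, s), c in entries.items()) / nz
    f = {
        "small": sum(c / s**2 for (g, s), c in entries.items()) / nz,
        "large": sum(c * s**2 for (g, s), c in entries.items()) / nz,
        "gln": sum(v**2 for v in pg.values()) / nz,
        "glnn": sum(v**2 for v in pg.values()) / nz**2,
        "sn": sum(v**2 for v in ps.values()) / nz,
        "snn": sum(v**2 for v in ps.values()) / nz**2,
        "pct": nz / n_voxels,
        "glv": sum(c * (g - mu_g) ** 2 for (g, s), c in entries.items()) / nz,
        "sv": sum(c * (s - mu_s) ** 2 for (g, s), c in entries.items()) / nz,
        "entropy": -sum(
            (c / nz) * math.log2(c / nz + EPS) for c in entries.values()
        ),
        "lgl": sum(c / g**2 for (g, s), c in entries.items()) / nz,
        "hgl": sum(c * g**2 for (g, s), c in entries.items()) / nz,
        "slgl": sum(c / (g**2 * s**2) for (g, s), c in entries.items()) / nz,
        "shgl": sum(c * g**2 / s**2 for (g, s), c in entries.items()) / nz,
        "llgl": sum(c * s**2 / g**2 for (g, s), c in entries.items()) / nz,
        "lhgl": sum(c * g**2 * s**2 for (g, s), c in entries.items()) / nz,
    }
    return f


def glrlm_features_from_counts(per_dir, n_voxels: int) -> dict[str, float]:
    keymap = {
        "ShortRunEmphasis": "small",
        "LongRunEmphasis": "large",
        "GrayLevelNonUniformity": "gln",
        "GrayLevelNonUniformityNormalized": "glnn",
        "RunLengthNonUniformity": "sn",
        "RunLengthNonUniformityNormalized": "snn",
        "RunPercentage": "pct",
        "GrayLevelVariance": "glv",
        "RunVariance": "sv",
        "RunEntropy": "entropy",
        "LowGrayLevelRunEmphasis": "lgl",
        "HighGrayLevelRunEmphasis": "hgl",
        "ShortRunLowGrayLevelEmphasis": "slgl",
        "ShortRunHighGrayLevelEmphasis": "shgl",
        "LongRunLowGrayLevelEmphasis": "llgl",
        "LongRunHighGrayLevelEmphasis": "lhgl",
    }
    dir_feats = [
        _sdm_features({k: float(v) for k, v in counts.items()}, n_voxels, "r")
        for counts in per_dir
        if counts
    ]
    return {
        name: float(np.mean([d[key] for d in dir_feats]))
        for name, key in keymap.items()
    }


def glszm_features_from_counts(counts, n_voxels: int) -> dict[str, float]:
    keymap = {
        "SmallAreaEmphasis": "small",
        "LargeAreaEmphasis": "large",
        "GrayLevelNonUniformity": "gln",
        "GrayLevelNonUniformityNormalized": "glnn",
        "SizeZoneNonUniformity": "sn",
        "SizeZoneNonUniformityNormalized": "snn",
        "ZonePercentage": "pct",
        "GrayLevelVariance": "glv",
        "ZoneVariance": "sv",
        "ZoneEntropy": "entropy",
        "LowGrayLevelZoneEmphasis": "lgl",
        "HighGrayLevelZoneEmphasis": "hgl",
        "SmallAreaLowGrayLevelEmphasis": "slgl",
        "SmallAreaHighGrayLevelEmphasis": "shgl",
        "LargeAreaLowGrayLevelEmphasis": "llgl",
        "LargeAreaHighGrayLevelEmphasis": "lhgl",
    }
    f = _sdm_features({k: float(v) for k, v in counts.items()}, n_voxels, "z")
    return {name: f[key] for name, key in keymap.items()}


def gldm_features_from_counts(counts, n_voxels: int) -> dict[str, float]:
    keymap = {
        "SmallDependenceEmphasis": "small",
        "LargeDependenceEmphasis": "large",
        "GrayLevelNonUniformity": "gln",
        "DependenceNonUniformity": "sn",
        "DependenceNonUniformityNormalized": "snn",
        "GrayLevelVariance": "glv",
        "DependenceVariance": "sv",
        "DependenceEntropy": "entropy",
        "LowGrayLevelEmphasis": "lgl",
        "HighGrayLevelEmphasis": "hgl",
        "SmallDependenceLowGrayLevelEmphasis": "slgl",
        "SmallDependenceHighGrayLevelEmphasis": "shgl",
        "LargeDependenceLowGrayLevelEmphasis": "llgl",
        "LargeDependenceHighGrayLevelEmphasis": "lhgl",
    }
    f = _sdm_features({k: float(v) for k, v in counts.items()}, n_voxels, "d")
    return {name: f[key] for name, key in keymap.items()}


def ngtdm_features_from_counts(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    nvp = n_i.sum()
    ng = len(n_i)
    p = n_i / nvp
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    f: dict[str, float] = {}
    denom = sum(p[i] * s_i[i] for i in present)
    f["Coarseness"] = 1.0 / denom if denom != 0 else 1e6
    if ngp <= 1:
        f["Contrast"] = 0.0
    else:
        f["Contrast"] = (
            sum(
                p[i] * p[j] * ((i + 1) - (j + 1)) ** 2
                for i in present
                for j in present
            )
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
    busy = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    f["Busyness"] = denom / busy if busy != 0 else 0.0
    f["Complexity"] = (
        sum(
            abs((i + 1) - (j + 1))
            * (p[i] * s_i[i] + p[j] * s_i[j])
            / (p[i] + p[j])
            for i in present
            for j in present
        )
        / nvp
    )
    stot = s_i.sum()
    f["Strength"] = (
        sum(
            (p[i] + p[j]) * ((i + 1) - (j + 1)) ** 2
            for i in present
            for j in present
        )
        / stot
        if stot != 0
        else 0.0
    )
    return f


def naive_first_order(x: np.ndarray, levels_hist: np.ndarray, voxel_volume: float) -> dict[str, float]:
    """First-order features by direct formula; x = in-mask intensities,
    levels_hist = per-level counts of the discretized ROI."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    mean = x.sum() / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p10 = float(np.percentile(x, 10))
    p90 = float(np.percentile(x, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    p = levels_hist[levels_hist > 0] / levels_hist.sum()
    energy = sum(v**2 for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(q * math.log2(q + EPS) for q in p),
        "Minimum": float(x[0]),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x[-1]),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Range": float(x[-1] - x[0]),
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / sd**3 if sd > 0 else 0.0,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / var**2 if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": sum(q**2 for q in p),
    }


def naive_all_texture(levels: np.ndarray, ng: int, n_voxels: int) -> dict[str, float]:
    """All 75 texture features of a (0-padded) level array."""
    out = {}
    for name, val in glcm_features_from_counts(naive_glcm(levels, ng)).items():
        out[f"glcm_{name}"] = val
    for name, val in gldm_features_from_counts(naive_gldm(levels, ng), n_voxels).items():
        out[f"gldm_{name}"] = val
    for name, val in glrlm_features_from_counts(naive_glrlm(levels, ng), n_voxels).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features_from_counts(naive_glszm(levels, ng), n_voxels).items():
        out[f"glszm_{name}"] = val
    n_i, s_i = naive_ngtdm(levels, ng)
    for name, val in ngtdm_features_from_counts(n_i, s_i).items():
        out[f"ngtdm_{name}"] = val
    return out
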