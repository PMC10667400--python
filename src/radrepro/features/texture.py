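"""Texture feature formulas over the five matrix families.

GLCM and GLRLM features are computed per direction and then averaged
over the 13 directions (feature-level averaging, not matrix averaging).
Degenerate cases follow documented conventions: a single-gray-level ROI
gives zero entropies, Imc1 = Imc2 = 0 and Correlation = MCC = 1; NGTDM
Coarseness with a zero denominator emits 1e6, Busyness and Strength
emit 0.
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrices

__all__ = [
    "GLCM_FEATURES",
    "GLDM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "texture_features",
]

_EPS = np.spacing(1.0)

GLCM_FEATURES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)
GLDM_FEATURES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
GLRLM_FEATURES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage",
    "GrayLevelVariance", "RunVariance", "RunEntropy",
    "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis",
)
GLSZM_FEATURES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage",
    "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
    "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis",
)
NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def _glcm_one_direction(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    total = counts.sum()
    out: dict[str, float] = {}
    if total == 0:  # no co-occurring pairs in this direction
        return {name: np.nan for name in GLCM_FEATURES}
    p = counts / total
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((px * i).sum())
    mu_y = mu_x  # symmetric matrix
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))

    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    out["Autocorrelation"] = float((p * ii * jj).sum())
    out["JointAverage"] = mu_x
    out["ClusterProminence"] = float((p * (ii + jj - mu_x - mu_y) ** 4).sum())
    out["ClusterShade"] = float((p * (ii + jj - mu_x - mu_y) ** 3).sum())
    out["ClusterTendency"] = float((p * (ii + jj - mu_x - mu_y) ** 2).sum())
    out["Contrast"] = float((p * (ii - jj) ** 2).sum())
    if sig_x > 0:
        out["Correlation"] = float(
            ((p * ii * jj).sum() - mu_x * mu_y) / (sig_x * sig_x)
        )
    else:
        out["Correlation"] = 1.0
    da = float((p_diff * k_diff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + _EPS)).sum())
    out["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    out["JointEnergy"] = float((p**2).sum())
    hxy = float(-(p * np.log2(p + _EPS)).sum())
    out["JointEntropy"] = hxy

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hxy1 = float(-(p * np.log2(np.outer(px, px) + _EPS)).sum())
    hxy2 = float(-(np.outer(px, px) * np.log2(np.outer(px, px) + _EPS)).sum())
    if hx > 0:
        out["Imc1"] = (hxy - hxy1) / hx
    else:
        out["Imc1"] = 0.0
    if hxy2 >= hxy:
        out["Imc2"] = float(np.sqrt(1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    else:  # numerical jitter can push hxy2 slightly below hxy
        out["Imc2"] = 0.0

    out["Idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["Idmn"] = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    out["Id"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["Idn"] = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off = ii != jj
    out["InverseVariance"] = float((p[off] / (ii[off] - jj[off]) ** 2).sum()) if ng > 1 else 0.0
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((p_sum * k_sum).sum())
    out["SumEntropy"] = float(-(p_sum * np.log2(p_sum + _EPS)).sum())
    out["SumSquares"] = float((p * (ii - mu_x) ** 2).sum())

    # MCC: sqrt of the second-largest eigenvalue of Q
    if ng == 1:
        out["MCC"] = 1.0
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.zeros((ng, ng))
            nz = px > 0
            # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
            denom = np.outer(px, px)
            w = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)
            q = w @ p.T
        eig = np.linalg.eigvals(q[np.ix_(nz, nz)])
        eig = np.sort(np.real(eig))
        if eig.size < 2:
            out["MCC"] = 1.0
        else:
            out["MCC"] = float(np.sqrt(max(eig[-2], 0.0)))
    return out


def glcm_features(mats: TextureMatrices) -> dict[str, float]:
    per_dir = [_glcm_one_direction(mats.glcm[a]) for a in range(mats.glcm.shape[0])]
    return {
        name: float(np.nanmean([d[name] for d in per_dir]))
        for name in GLCM_FEATURES
    }


def _rlm_one_direction(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, lmax = mat.shape
    nr = mat.sum()
    if nr == 0:
        return {name: np.nan for name in GLRLM_FEATURES}
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    p = mat / nr
    pg = mat.sum(axis=1)  # per gray level
    pr = mat.sum(axis=0)  # per run length
    ivec = i.ravel()
    jvec = j.ravel()
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    out = {
        "ShortRunEmphasis": float((mat / j**2).sum() / nr),
        "LongRunEmphasis": float((mat * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "RunLengthNonUniformity": float((pr**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((mat / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((mat * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nr),
    }
    return out


def glrlm_features(mats: TextureMatrices) -> dict[str, float]:
    per_dir = [
        _rlm_one_direction(mats.glrlm[a], mats.n_voxels)
        for a in range(mats.glrlm.shape[0])
    ]
    return {
        name: float(np.nanmean([d[name] for d in per_dir]))
        for name in GLRLM_FEATURES
    }


def glszm_features(mats: TextureMatrices) -> dict[str, float]:
    mat = mats.glszm
    ng, smax = mat.shape
    nz = mat.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, smax + 1, dtype=float)[None, :]
    p = mat / nz
    pg = mat.sum(axis=1)
    ps = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "SmallAreaEmphasis": float((mat / j**2).sum() / nz),
        "LargeAreaEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "ZonePercentage": float(nz / mats.n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((mat * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def gldm_features(mats: TextureMatrices) -> dict[str, float]:
    mat = mats.gldm
    ng, dmax = mat.shape
    nz = mat.sum()
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    # dependence size j counts the center voxel: column c -> j = c + 1
    j = np.arange(1, dmax + 1, dtype=float)[None, :]
    p = mat / nz
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "SmallDependenceEmphasis": float((mat / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def ngtdm_features(mats: TextureMatrices) -> dict[str, float]:
    n_i, s_i = mats.ngtdm_n, mats.ngtdm_s
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, mats.n_levels + 1, dtype=float)
    ip, pp, sp = i[present], p_i[present], s_i[present]

    out: dict[str, float] = {}
    denom = float((pp * sp).sum())
    out["Coarseness"] = 1.0 / denom if denom != 0 else 1e6

    if ngp <= 1:
        out["Contrast"] = 0.0
    else:
        pairs = float(
            sum(
                pp[a] * pp[b] * (ip[a] - ip[b]) ** 2
                for a in range(ngp)
                for b in range(ngp)
            )
        )
        out["Contrast"] = pairs / (ngp * (ngp - 1)) * (s_i.sum() / nvp)

    busy_denom = float(
        sum(abs(ip[a] * pp[a] - ip[b] * pp[b]) for a in range(ngp) for b in range(ngp))
    )
    out["Busyness"] = denom / busy_denom if busy_denom != 0 else 0.0

    complexity = 0.0
    for a in range(ngp):
        for b in range(ngp):
            complexity += (
                abs(ip[a] - ip[b])
                * (pp[a] * sp[a] + pp[b] * sp[b])
                / (pp[a] + pp[b])
            )
    out["Complexity"] = complexity / nvp

    s_total = float(s_i.sum())
    if s_total == 0:
        out["Strength"] = 0.0
    else:
        strength = float(
            sum(
                (pp[a] + pp[b]) * (ip[a] - ip[b]) ** 2
                for a in range(ngp)
                for b in range(ngp)
            )
        )
        out["Strength"] = strength / s_total
    return out


def texture_features(mats: TextureMatrices) -> dict[str, float]:
    """All 75 texture features, keyed ``<group>_<FeatureName>``."""
    out: dict[str, float] = {}
    for group, func in (
        ("glcm", glcm_features),
        ("gldm", gldm_features),
        ("glrlm", glrlm_features),
        ("glszm", glszm_features),
        ("ngtdm", ngtdm_features),
    ):
        for name, value in func(mats).items():
            out[f"{group}_{name}"] = value
    return out
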