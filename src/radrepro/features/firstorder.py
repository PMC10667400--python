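"""First-order intensity statistics (18 features).

All statistics except Entropy and Uniformity are computed from the
continuous post-filter intensities; Entropy and Uniformity come from the
discretized gray-level histogram.  TotalEnergy scales Energy by the
voxel volume in mm^3.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedROI

__all__ = ["FO_FEATURES", "first_order_features"]

_EPS = np.spacing(1.0)

FO_FEATURES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def first_order_features(
    volume: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizedROI,
    spacing: tuple[float, float, float],
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(volume, dtype=float)[mask]
    n = x.size
    voxel_volume = float(np.prod(spacing))

    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = float(np.sqrt(var))
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]

    if sd > 0:
        m2 = var
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # not excess-corrected
    else:
        skew, kurt = 0.0, 0.0

    lv = disc.levels[mask]
    counts = np.bincount(lv, minlength=disc.n_levels + 1)[1:]
    p = counts / counts.sum()

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-(p * np.log2(p + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
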