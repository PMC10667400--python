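"""Pre-processing parameter grid and its three stages.

Three parameters are varied: gray-level discretization (relative/FBN or
absolute/FBS, four binning values each), signal-intensity normalization
(AR = dual-reference affine normalization, NAR = none), and intensity
outlier filtering (NoF = none, IN = clip to the mean +/- 3 sigma range,
OUT = drop voxels outside that range from the mask).  The full Cartesian
grid has 2*4*2*3 = 48 settings.

Pipeline order for a single setting is normalization -> outlier
filtering -> discretization, so that the outlier bounds reflect the
intensities that are actually discretized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FBN_BINNINGS",
    "FBS_BINNINGS",
    "PreprocessSetting",
    "OutlierFilterResult",
    "DiscretizedROI",
    "enumerate_settings",
    "normalize_dual_reference",
    "filter_outliers",
    "discretize_fbn",
    "discretize_fbs",
    "apply_setting",
]

FBN_BINNINGS = (16, 32, 64, 128)
FBS_BINNINGS = (5, 10, 20, 40)
NORMALIZATIONS = ("AR", "NAR")
OUTLIER_MODES = ("NoF", "IN", "OUT")

#: Default affine anchors for dual-reference normalization:
#: muscle mean -> 0, fat mean -> 1000 (arbitrary units).
DEFAULT_ANCHORS = (0.0, 1000.0)


@dataclass(frozen=True)
class PreprocessSetting:
    """One point of the 48-setting pre-processing grid."""

    setting_index: int
    discretization: Literal["FBN", "FBS"]
    binning: int
    normalization: Literal["AR", "NAR"]
    outlier_mode: Literal["NoF", "IN", "OUT"]

    def __post_init__(self) -> None:
        legal = FBN_BINNINGS if self.discretization == "FBN" else FBS_BINNINGS
        if self.binning not in legal:
            raise ValueError(
                f"binning {self.binning} not legal for {self.discretization}; "
                f"expected one of {legal}"
            )

    @property
    def label(self) -> str:
        return (
            f"{self.discretization}{self.binning}/"
            f"{self.normalization}/{self.outlier_mode}"
        )

    def to_dict(self) -> dict:
        return {
            "setting_index": self.setting_index,
            "discretization": self.discretization,
            "binning": self.binning,
            "normalization": self.normalization,
            "outlier_mode": self.outlier_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSetting":
        return cls(
            setting_index=int(d["setting_index"]),
            discretization=d["discretization"],
            binning=int(d["binning"]),
            normalization=d["normalization"],
            outlier_mode=d["outlier_mode"],
        )


def enumerate_settings() -> list[PreprocessSetting]:
    """Return all 48 settings in a stable, deterministic order.

    Order is discretization-major (FBN before FBS), then binning
    ascending, then normalization (AR, NAR), then outlier mode
    (NoF, IN, OUT); indices run 1..48.  Under this order setting 18 is
    FBN64/NAR/OUT and setting 37 is FBS20/AR/NoF.
    """
    settings = []
    idx = 1
    for disc, binnings in (("FBN", FBN_BINNINGS), ("FBS", FBS_BINNINGS)):
        for binning, norm, outlier in product(binnings, NORMALIZATIONS, OUTLIER_MODES):
            settings.append(
                PreprocessSetting(
                    setting_index=idx,
                    discretization=disc,
                    binning=binning,
                    normalization=norm,
                    outlier_mode=outlier,
                )
            )
            idx += 1
    return settings


def normalize_dual_reference(
    volume: np.ndarray,
    fat_mask: np.ndarray,
    muscle_mask: np.ndarray,
    anchors: tuple[float, float] = DEFAULT_ANCHORS,
) -> np.ndarray:
    """Affinely map intensities so reference-tissue means hit fixed anchors.

    The mean over the muscle mask is mapped to ``anchors[0]`` (low) and
    the mean over the fat mask to ``anchors[1]`` (high); all voxels are
    transformed with the same monotone increasing affine map.  This is a
    simplified stand-in for automated dual-reference normalization that
    requires the reference masks to be supplied.

    Parameters
    ----------
    volume : 3D float array
    fat_mask, muscle_mask : 3D boolean arrays, nonempty
    anchors : (low, high) target values for (muscle, fat) means

    Returns
    -------
    Normalized volume (new array).
    """
    fat_mask = np.asarray(fat_mask, dtype=bool)
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if not fat_mask.any():
        raise ValueError("fat reference mask is empty")
    if not muscle_mask.any():
        raise ValueError("muscle reference mask is empty")
    fat_mean = float(np.mean(volume[fat_mask]))
    muscle_mean = float(np.mean(volume[muscle_mask]))
    if fat_mean == muscle_mean:
        raise ValueError(
            f"degenerate reference tissues: fat mean == muscle mean == {fat_mean}"
        )
    low, high = anchors
    gain = (high - low) / (fat_mean - muscle_mean)
    if gain <= 0:
        raise ValueError(
            "normalization map is not monotone increasing "
            f"(fat mean {fat_mean} vs muscle mean {muscle_mean}, anchors {anchors})"
        )
    return low + gain * (np.asarray(volume, dtype=float) - muscle_mean)


@dataclass
class OutlierFilterResult:
    """Result of the [mu - 3 sigma, mu + 3 sigma] re-segmentation stage."""

    volume: np.ndarray
    mask: np.ndarray
    mode: str
    mu: float
    sigma: float
    n_affected: int


def filter_outliers(
    volume: np.ndarray,
    mask: np.ndarray,
    mode: str,
    n_sigma: float = 3.0,
    ddof: int = 1,
) -> OutlierFilterResult:
    """Apply intensity outlier filtering to in-mask voxels.

    mu and sigma are computed once from the input in-mask intensities
    (not iterated).  ``IN`` clips out-of-range voxels to the nearest
    bound, keeping the mask; ``OUT`` removes them from the mask; ``NoF``
    is the identity.  sigma uses the sample standard deviation
    (``ddof=1``) by default.
    """
    if mode not in OUTLIER_MODES:
        raise ValueError(f"unknown outlier mode {mode!r}; expected one of {OUTLIER_MODES}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = np.asarray(volume, dtype=float)
    vals = volume[mask]
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0

    if mode == "NoF":
        return OutlierFilterResult(volume, mask, mode, mu, sigma, 0)
    if sigma == 0.0:
        warnings.warn(
            "outlier filter is a no-op: zero in-mask standard deviation",
            stacklevel=2,
        )
        return OutlierFilterResult(volume, mask, mode, mu, sigma, 0)

    lo, hi = mu - n_sigma * sigma, mu + n_sigma * sigma
    outside = mask & ((volume < lo) | (volume > hi))
    n_affected = int(outside.sum())
    if mode == "IN":
        out_vol = volume.copy()
        out_vol[outside] = np.clip(out_vol[outside], lo, hi)
        return OutlierFilterResult(out_vol, mask, mode, mu, sigma, n_affected)
    # OUT
    out_mask = mask & ~outside
    return OutlierFilterResult(volume, out_mask, mode, mu, sigma, n_affected)


@dataclass
class DiscretizedROI:
    """Integer gray levels 1..Ng on in-mask voxels.

    ``levels`` has the volume's shape with 0 outside the mask and values
    in 1..Ng inside.  ``n_levels`` (Ng) is the number of gray levels of
    the occupied range: exactly the bin number for FBN, the number of
    width-W bins spanning the anchored intensity range for FBS.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    x_min: float
    x_max: float
    discretization: str
    binning: float


def discretize_fbn(volume: np.ndarray, mask: np.ndarray, n_bins: int) -> DiscretizedROI:
    """Relative (fixed bin number) discretization of in-mask intensities.

    level(x) = floor(Nb * (x - Xmin) / (Xmax - Xmin)) + 1, with x = Xmax
    clamped into bin Nb.  A constant ROI maps to a single level 1.
    Invariant under any positive affine intensity map.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = np.asarray(volume, dtype=float)
    vals = volume[mask]
    x_min, x_max = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if x_max == x_min:
        levels[mask] = 1
        return DiscretizedROI(levels, mask, 1, x_min, x_max, "FBN", n_bins)
    binned = np.floor(n_bins * (vals - x_min) / (x_max - x_min)).astype(np.int64) + 1
    np.clip(binned, 1, n_bins, out=binned)
    levels[mask] = binned
    return DiscretizedROI(levels, mask, n_bins, x_min, x_max, "FBN", n_bins)


def discretize_fbs(
    volume: np.ndarray,
    mask: np.ndarray,
    bin_width: float,
    anchor: str = "multiple_of_width",
) -> DiscretizedROI:
    """Absolute (fixed bin size) discretization of in-mask intensities.

    Bin edges are anchored at integer multiples of the bin width at or
    below the in-mask minimum (``anchor='multiple_of_width'``, the
    reference-tool convention), so level(x) = floor(x/W) - floor(Xmin/W)
    + 1.  With ``anchor='roi_minimum'`` edges start at Xmin instead.
    Sensitive to intensity scale by construction.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = np.asarray(volume, dtype=float)
    vals = volume[mask]
    x_min, x_max = float(vals.min()), float(vals.max())
    if anchor == "multiple_of_width":
        base = np.floor(x_min / bin_width)
        binned = (np.floor(vals / bin_width) - base).astype(np.int64) + 1
    elif anchor == "roi_minimum":
        binned = np.floor((vals - x_min) / bin_width).astype(np.int64) + 1
    else:
        raise ValueError(f"unknown FBS anchor {anchor!r}")
    n_levels = int(binned.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[mask] = binned
    return DiscretizedROI(levels, mask, n_levels, x_min, x_max, "FBS", bin_width)


def apply_setting(
    case,
    scan: int,
    setting: PreprocessSetting,
    anchors: tuple[float, float] = DEFAULT_ANCHORS,
    n_sigma: float = 3.0,
    sigma_ddof: int = 1,
    fbs_anchor: str = "multiple_of_width",
) -> tuple[np.ndarray, np.ndarray, DiscretizedROI]:
    """Run the full pre-processing pipeline of one setting on one scan.

    Stages in order: (1) dual-reference normalization if AR, (2) outlier
    filtering on the (possibly normalized) volume, (3) discretization on
    the filtered ROI.  Returns the post-filter continuous volume and
    final mask (consumed by first-order intensity features) and the
    DiscretizedROI (consumed by texture features).

    ``case`` is any object with ``scan{1,2}_volume``, ``scan{1,2}_mask``,
    ``fat_mask`` and ``muscle_mask`` array attributes.
    """
    if scan not in (1, 2):
        raise ValueError("scan must be 1 or 2")
    volume = getattr(case, f"scan{scan}_volume")
    mask = np.asarray(getattr(case, f"scan{scan}_mask"), dtype=bool)

    if setting.normalization == "AR":
        volume = normalize_dual_reference(volume, case.fat_mask, case.muscle_mask, anchors)

    result = filter_outliers(volume, mask, setting.outlier_mode, n_sigma, sigma_ddof)
    if not result.mask.any():
        lesion = getattr(case, "lesion_id", "<unknown>")
        raise ValueError(
            f"outlier filtering emptied the ROI of lesion {lesion} "
            f"under setting {setting.setting_index} ({setting.label})"
        )

    if setting.discretization == "FBN":
        disc = discretize_fbn(result.volume, result.mask, setting.binning)
    else:
        disc = discretize_fbs(result.volume, result.mask, setting.binning, fbs_anchor)
    return result.volume, result.mask, disc
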