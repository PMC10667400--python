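"""Inter-scan reproducibility scoring with ICC(2,1) and setting selection.

The intra-class correlation is the two-way random-effects, absolute
agreement, single-measurement form:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

with MSR/MSC/MSE the subject, rater (scan) and residual mean squares of
the two-way crossed ANOVA, n subjects and k = 2 scans.  Features with
ICC strictly greater than 0.75 count as having good reproducibility;
the winning setting has the highest good count, ties broken by lowest
binning value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PreprocessSetting

__all__ = [
    "ICCResult",
    "ReproducibilityGrid",
    "icc_2_1",
    "icc_2_1_many",
    "build_grid",
    "count_good",
    "select_setting",
    "consistently_good",
    "GOOD_THRESHOLD",
]

GOOD_THRESHOLD = 0.75


@dataclass
class ICCResult:
    feature_name: str
    setting_index: int
    icc: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int = 2
    degenerate: bool = False

    def is_good(self, threshold: float = GOOD_THRESHOLD) -> bool:
        return (not self.degenerate) and self.icc > threshold


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """MSR, MSC, MSE of the two-way crossed decomposition of an n x k table."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_2_1(
    paired: np.ndarray,
    feature_name: str = "",
    setting_index: int = 0,
) -> ICCResult:
    """ICC(2,1) of an n x k matrix of paired measurements (k = 2 scans).

    A zero denominator (all values identical) reports ICC 1 with the
    degenerate flag set; degenerate results never count as good.
    """
    data = np.asarray(paired, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"expected an n x k matrix, got shape {data.shape}")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"ICC requires n >= 3 subjects, got {n}")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")
    msr, msc, mse = _anova_mean_squares(data)
    if np.ptp(data) == 0.0:
        # all values identical: zero denominator, report 1 but flag it
        return ICCResult(feature_name, setting_index, 1.0, msr, msc, mse, n, k, True)
    if (data == data[:, :1]).all():
        # perfect inter-scan agreement with subject variation: exact 1
        # (avoids returning 1 - eps from round-off in the mean squares)
        return ICCResult(feature_name, setting_index, 1.0, msr, msc, 0.0, n, k, False)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or not np.isfinite(denom):
        return ICCResult(feature_name, setting_index, 1.0, msr, msc, mse, n, k, True)
    icc = (msr - mse) / denom
    return ICCResult(feature_name, setting_index, float(icc), msr, msc, mse, n, k, False)


def icc_2_1_many(data: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over a batch of m tables shaped (m, n, k).

    Degenerate (all-identical) tables yield 1.0.  Used for Monte-Carlo
    work where constructing m ICCResult objects would dominate runtime.
    """
    data = np.asarray(data, dtype=float)
    m, n, k = data.shape
    if n < 3:
        raise ValueError(f"ICC requires n >= 3 subjects, got {n}")
    grand = data.mean(axis=(1, 2), keepdims=True)
    row_means = data.mean(axis=2, keepdims=True)
    col_means = data.mean(axis=1, keepdims=True)
    ssr = k * ((row_means - grand) ** 2).sum(axis=(1, 2))
    ssc = n * ((col_means - grand) ** 2).sum(axis=(1, 2))
    sst = ((data - grand) ** 2).sum(axis=(1, 2))
    sse = np.clip(sst - ssr - ssc, 0.0, None)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / np.where(denom > 0, denom, 1.0), 1.0)
    return icc


@dataclass
class ReproducibilityGrid:
    """107 x 48 matrix of ICC results plus bookkeeping."""

    results: dict[tuple[str, int], ICCResult]
    feature_names: tuple[str, ...]
    setting_indices: tuple[int, ...]

    @property
    def n_cells(self) -> int:
        return len(self.results)

    def icc(self, feature: str, setting: int) -> float:
        return self.results[(feature, setting)].icc

    def to_frame(self) -> pd.DataFrame:
        """Wide frame: rows = features, columns = setting indices."""
        mat = np.full((len(self.feature_names), len(self.setting_indices)), np.nan)
        for (feat, setting), res in self.results.items():
            i = self.feature_names.index(feat)
            j = self.setting_indices.index(setting)
            mat[i, j] = res.icc
        return pd.DataFrame(mat, index=list(self.feature_names), columns=list(self.setting_indices))


def build_grid(features: pd.DataFrame, lesion_set: str = "all") -> ReproducibilityGrid:
    """Score every (feature, setting) cell of a long-format feature table.

    ``features`` columns: lesion_id, scan, setting_index, feature_name,
    value (and optionally is_index when ``lesion_set='index'``).
    Every lesion must have both scans for every setting.
    """
    if lesion_set == "index":
        if "is_index" not in features.columns:
            raise ValueError("lesion_set='index' requires an is_index column")
        features = features[features["is_index"].astype(bool)]
    elif lesion_set != "all":
        raise ValueError(f"unknown lesion_set {lesion_set!r}")

    wide = features.pivot_table(
        index="lesion_id",
        columns=["feature_name", "setting_index", "scan"],
        values="value",
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()][0]
        bad = wide.index[wide[missing].isna()][0]
        raise ValueError(f"lesion {bad!r} is missing scan data for {missing}")

    feature_names = tuple(sorted(features["feature_name"].unique()))
    setting_indices = tuple(sorted(features["setting_index"].unique()))
    results: dict[tuple[str, int], ICCResult] = {}
    for feat in feature_names:
        for setting in setting_indices:
            block = wide[feat][setting]  # n x scans
            data = block[[1, 2]].to_numpy()
            results[(feat, int(setting))] = icc_2_1(data, feat, int(setting))
    return ReproducibilityGrid(results, feature_names, setting_indices)


def count_good(grid: ReproducibilityGrid, threshold: float = GOOD_THRESHOLD) -> dict[int, int]:
    """Per-setting count of features with ICC strictly above threshold."""
    counts = {s: 0 for s in grid.setting_indices}
    for (_, setting), res in grid.results.items():
        if res.is_good(threshold):
            counts[setting] += 1
    return counts


def select_setting(
    counts: dict[int, int], settings: list[PreprocessSetting]
) -> PreprocessSetting:
    """Pick the setting with the most good features.

    Ties are broken by the lowest binning value among the tied settings.
    Binning values of FBN (a bin count) and FBS (a bin width) are not
    comparable, so a tie spanning both discretization types — or one
    left unresolved by equal binning values — falls back to the lowest
    setting index with a warning.
    """
    by_index = {s.setting_index: s for s in settings}
    missing = [s for s in by_index if s not in counts]
    if missing:
        raise ValueError(f"counts missing for settings {missing}")
    best_count = max(counts.values())
    tied = [by_index[i] for i, c in counts.items() if c == best_count]
    if len(tied) == 1:
        return tied[0]
    if len({s.discretization for s in tied}) == 1:
        min_binning = min(s.binning for s in tied)
        tied = [s for s in tied if s.binning == min_binning]
        if len(tied) == 1:
            return tied[0]
    warnings.warn(
        "tie-break by lowest binning value is ambiguous between "
        + ", ".join(s.label for s in tied)
        + "; falling back to lowest setting index",
        stacklevel=2,
    )
    return min(tied, key=lambda s: s.setting_index)


def consistently_good(
    grid: ReproducibilityGrid, threshold: float = GOOD_THRESHOLD
) -> list[str]:
    """Features with ICC above threshold in every setting of the grid."""
    if not grid.results:
        raise ValueError("empty grid")
    out = []
    for feat in grid.feature_names:
        if all(
            grid.results[(feat, s)].is_good(threshold) for s in grid.setting_indices
        ):
            out.append(feat)
    return out
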