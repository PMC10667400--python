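"""Nonparametric category comparisons with FDR correction.

Two-category clinical variables (PSAD low/high at 0.15 ng/mL^2, prostate
volume small/enlarged at 40 mL) use the two-tailed Mann-Whitney U test;
three-category variables (PI-RADS 3/4/5, ISUP <1 / 1 / >1) use
Kruskal-Wallis.  P values are Benjamini-Hochberg adjusted within each
test family, and adjusted p < 0.05 counts as significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reproducibility import icc_2_1

__all__ = [
    "CATEGORY_SCHEMES",
    "ComparisonResult",
    "categorize",
    "mann_whitney_u",
    "kruskal_wallis",
    "benjamini_hochberg",
    "compare_icc_by_category",
    "compare_values_by_category",
    "results_to_frame",
]

ALPHA = 0.05
#: Largest combined sample size at which the exact MWU null distribution
#: is enumerated (ties force the corrected normal approximation).
EXACT_MWU_MAX_N = 12


def _psad_category(v: float) -> str:
    return "low" if v <= 0.15 else "high"


def _volume_category(v: float) -> str:
    return "small" if v < 40.0 else "enlarged"


def _pirads_category(v: int) -> str:
    return str(int(v))


def _isup_category(v: int) -> str:
    v = int(v)
    if v < 1:
        return "<1"
    return "1" if v == 1 else ">1"


#: variable -> (clinical column, category function); two-level schemes
#: get MWU, multi-level schemes get Kruskal-Wallis.
CATEGORY_SCHEMES: dict[str, tuple[str, Callable]] = {
    "PSAD": ("psad", _psad_category),
    "prostate_volume": ("prostate_volume", _volume_category),
    "PIRADS": ("pirads", _pirads_category),
    "ISUP": ("isup", _isup_category),
}


def categorize(clinical: pd.DataFrame, variable: str) -> pd.Series:
    """Category label per row of the clinical table for one variable."""
    column, rule = CATEGORY_SCHEMES[variable]
    return clinical[column].map(rule)


@dataclass
class ComparisonResult:
    variable: str
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float = np.nan
    group_sizes: dict[str, int] = field(default_factory=dict)
    feature: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < ALPHA)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U (U statistic of x, exact p for small
    tie-free samples, tie- and continuity-corrected normal approximation
    otherwise)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square, g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    if sum(g.size for g in groups) < 5:
        raise ValueError("need total n >= 5")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    adj_i = min over j >= i (in the ascending sort) of m * p_j / j,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.clip(adjusted_sorted, 0.0, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


def _test_by_category(values: pd.Series, cats: pd.Series, variable: str) -> ComparisonResult:
    levels = sorted(cats.unique())
    groups = {lv: values[cats == lv].to_numpy() for lv in levels}
    sizes = {lv: int(g.size) for lv, g in groups.items()}
    if len(levels) == 2:
        u, p = mann_whitney_u(groups[levels[0]], groups[levels[1]])
        return ComparisonResult(variable, "MannWhitneyU", u, p, group_sizes=sizes)
    h, p = kruskal_wallis([groups[lv] for lv in levels])
    return ComparisonResult(variable, "KruskalWallis", h, p, group_sizes=sizes)


def _per_category_iccs(
    features: pd.DataFrame, lesion_cats: pd.Series, category: str
) -> np.ndarray | None:
    """107-vector of per-feature ICCs within one category subgroup."""
    lesions = lesion_cats.index[lesion_cats == category]
    lesions = lesions.intersection(pd.Index(features["lesion_id"].unique()))
    if len(lesions) < 3:
        return None
    sub = features[features["lesion_id"].isin(lesions)]
    wide = sub.pivot_table(index="lesion_id", columns=["feature_name", "scan"], values="value")
    feats = sorted(sub["feature_name"].unique())
    iccs = np.empty(len(feats))
    for i, feat in enumerate(feats):
        iccs[i] = icc_2_1(wide[feat][[1, 2]].to_numpy()).icc
    return iccs


def compare_icc_by_category(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    variables: Sequence[str] = tuple(CATEGORY_SCHEMES),
) -> list[ComparisonResult]:
    """Test whether per-feature ICC distributions differ between the
    categories of each clinical variable.

    ``features`` is a long table (lesion_id, scan, feature_name, value)
    already restricted to the index lesions and the selected setting;
    ``clinical`` is indexed or keyed by lesion_id.  Per category the 107
    per-feature ICCs are recomputed within that subgroup, and the
    resulting ICC distributions are compared with MWU / Kruskal-Wallis.
    BH correction is applied across the family of testable variables.
    Variables with a category of fewer than 3 lesions are dropped from
    the family (ICC is not computable there).
    """
    clin = clinical.set_index("lesion_id") if "lesion_id" in clinical.columns else clinical
    results: list[ComparisonResult] = []
    for variable in variables:
        cats = categorize(clin, variable)
        per_cat = {c: _per_category_iccs(features, cats, c) for c in sorted(cats.unique())}
        if any(v is None for v in per_cat.values()) or len(per_cat) < 2:
            continue  # flagged: category too small for ICC
        icc_values = pd.Series(np.concatenate(list(per_cat.values())))
        labels = pd.Series(
            np.concatenate([[c] * len(v) for c, v in per_cat.items()])
        )
        results.append(_test_by_category(icc_values, labels, variable))
    if results:
        adjusted = benjamini_hochberg([r.p_raw for r in results])
        for r, adj in zip(results, adjusted):
            r.p_adjusted = float(adj)
    return results


def compare_values_by_category(
    baseline: pd.DataFrame,
    clinical: pd.DataFrame,
    variables: Sequence[str] = tuple(CATEGORY_SCHEMES),
    family: str = "per_variable",
) -> list[ComparisonResult]:
    """Test each feature's baseline values across clinical categories.

    ``baseline`` is a long table (lesion_id, feature_name, value) of
    scan-1 index-lesion values at the selected setting.  One test per
    (feature, variable); BH per variable family across the 107 features
    by default (``family='per_variable'``) or over the whole table with
    ``family='global'``.
    """
    if family not in ("per_variable", "global"):
        raise ValueError(f"unknown BH family scheme {family!r}")
    clin = clinical.set_index("lesion_id") if "lesion_id" in clinical.columns else clinical
    wide = baseline.pivot_table(index="lesion_id", columns="feature_name", values="value")
    results: list[ComparisonResult] = []
    for variable in variables:
        cats = categorize(clin, variable).reindex(wide.index)
        if cats.nunique() < 2 or cats.value_counts().min() < 1:
            continue
        if cats.nunique() > 2 and len(cats) < 5:
            continue  # Kruskal-Wallis needs total n >= 5
        var_results = []
        for feat in wide.columns:
            values = wide[feat]
            if values.nunique() <= 1:
                res = ComparisonResult(
                    variable,
                    "MannWhitneyU" if cats.nunique() == 2 else "KruskalWallis",
                    np.nan,
                    1.0,
                    group_sizes=cats.value_counts().to_dict(),
                )
            else:
                res = _test_by_category(values, cats, variable)
            res.feature = feat
            var_results.append(res)
        if family == "per_variable" and var_results:
            adjusted = benjamini_hochberg([r.p_raw for r in var_results])
            for r, adj in zip(var_results, adjusted):
                r.p_adjusted = float(adj)
        results.extend(var_results)
    if family == "global" and results:
        adjusted = benjamini_hochberg([r.p_raw for r in results])
        for r, adj in zip(results, adjusted):
            r.p_adjusted = float(adj)
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = [
        {
            "variable": r.variable,
            "feature": r.feature or "ICC-distribution",
            "test": r.test,
            "statistic": r.statistic,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
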