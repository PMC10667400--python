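"""Stage orchestration: extract -> icc -> select -> compare."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from .features import extract_all
from .group_stats import (
    compare_icc_by_category,
    compare_values_by_category,
    results_to_frame,
)
from .io import write_settings_grid
from .preprocess import PreprocessSetting, enumerate_settings
from .reproducibility import build_grid, count_good, select_setting
from .synthetic import PairedLesionCase

__all__ = ["extract_cohort", "run_pipeline"]


def extract_cohort(
    cases: list[PairedLesionCase],
    settings: list[PreprocessSetting] | None = None,
    on_error: str = "record",
) -> tuple[pd.DataFrame, list[str]]:
    """Long-format feature table over lesions x scans x settings.

    Failures (e.g. a setting emptying an ROI) are recorded and the run
    continues over the remaining cells unless ``on_error='raise'``.
    """
    settings = settings if settings is not None else enumerate_settings()
    rows = []
    failures: list[str] = []
    for case in cases:
        for setting in settings:
            for scan in (1, 2):
                try:
                    values = extract_all(case, scan, setting)
                except ValueError as exc:
                    if on_error == "raise":
                        raise
                    failures.append(str(exc))
                    continue
                rows.extend(
                    {
                        "lesion_id": case.lesion_id,
                        "scan": scan,
                        "setting_index": setting.setting_index,
                        "feature_name": name,
                        "value": value,
                        "is_index": case.clinical.is_index,
                    }
                    for name, value in values.items()
                )
    return pd.DataFrame(rows), failures


def run_pipeline(
    cases: list[PairedLesionCase],
    clinical: pd.DataFrame,
    out_dir,
    settings: list[PreprocessSetting] | None = None,
) -> dict:
    """Full workflow on an in-memory cohort; writes all stage outputs.

    Returns a summary dict with the feature table, grid, selected
    setting and comparison results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = settings if settings is not None else enumerate_settings()
    write_settings_grid(out / "grid_settings.json", settings)

    caught: list[str] = []
    features, failures = extract_cohort(cases, settings)
    caught.extend(failures)
    features.to_csv(out / "features.csv", index=False)

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        grid = build_grid(features, lesion_set="all")
        counts = count_good(grid)
        selected = select_setting(counts, settings)
        caught.extend(str(w.message) for w in wlist)

    grid.to_frame().to_csv(out / "grid.csv")
    (out / "selected_setting.json").write_text(json.dumps(selected.to_dict(), indent=2))

    index_features = features[
        features["is_index"] & (features["setting_index"] == selected.setting_index)
    ]
    icc_comparisons = compare_icc_by_category(
        index_features[["lesion_id", "scan", "feature_name", "value"]], clinical
    )
    baseline = index_features[index_features["scan"] == 1][
        ["lesion_id", "feature_name", "value"]
    ]
    value_comparisons = compare_values_by_category(baseline, clinical)
    comparisons = results_to_frame(icc_comparisons + value_comparisons)
    comparisons.to_csv(out / "comparisons.csv", index=False)

    return {
        "features": features,
        "grid": grid,
        "counts": counts,
        "selected": selected,
        "comparisons": comparisons,
        "warnings": caught,
    }
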