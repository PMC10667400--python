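"""Radiomics feature engine: 107 features in 7 groups.

Feature keys are ``<group>_<FeatureName>`` with groups fo (18),
glcm (24), gldm (14), glrlm (16), glszm (16), ngtdm (5) and shape (14).
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedROI, PreprocessSetting, apply_setting
from .firstorder import FO_FEATURES, first_order_features
from .matrices import TextureMatrices, build_matrices
from .shape import SHAPE_FEATURES, shape_features
from .texture import (
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    texture_features,
)

__all__ = [
    "FEATURE_GROUPS",
    "ALL_FEATURE_NAMES",
    "build_matrices",
    "TextureMatrices",
    "first_order_features",
    "texture_features",
    "shape_features",
    "extract_all",
]

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "fo": FO_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "shape": SHAPE_FEATURES,
}

ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{group}_{name}" for group, names in FEATURE_GROUPS.items() for name in names
)

assert len(ALL_FEATURE_NAMES) == 107


def extract_all(case, scan: int, setting: PreprocessSetting, **preprocess_kwargs) -> dict[str, float]:
    """Pre-process one scan under one setting and extract all 107 features.

    Shape features depend only on the final mask, so they are identical
    across settings sharing an outlier mode.  Raises if the setting
    empties the ROI.
    """
    volume, mask, disc = apply_setting(case, scan, setting, **preprocess_kwargs)
    spacing = tuple(case.spacing)

    out: dict[str, float] = {}
    for name, value in first_order_features(volume, mask, disc, spacing).items():
        out[f"fo_{name}"] = value
    mats = build_matrices(disc)
    out.update(texture_features(mats))
    for name, value in shape_features(mask, spacing).items():
        out[f"shape_{name}"] = value

    assert len(out) == 107
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(f"non-finite feature values: {bad}")
    return out
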