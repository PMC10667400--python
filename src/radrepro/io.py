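"""File formats and cohort (de)serialization.

Volumes and masks are NIfTI; the clinical table, feature table,
reproducibility grid and comparison results are CSV; the setting grid,
selected setting and run manifest are JSON; configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .preprocess import PreprocessSetting, enumerate_settings
from .synthetic import ClinicalVariables, PairedLesionCase, SimulationConfig

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_cohort",
    "read_cohort",
    "write_settings_grid",
    "read_settings_grid",
    "load_config",
    "write_manifest",
]


def _check_3d(data: np.ndarray, path) -> None:
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got {data.ndim} axes with shape {data.shape}"
        )


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI scalar volume; returns (values, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    _check_3d(data, path)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_mask(path, volume_shape=None) -> np.ndarray:
    """Read a binary NIfTI mask (values must be 0/1 after 0.5 threshold)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    _check_3d(data, path)
    values = np.unique(data)
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise ValueError(f"{path}: mask is not binary, found values {values[:10]}")
    mask = data > 0.5
    if volume_shape is not None and mask.shape != tuple(volume_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match volume shape {tuple(volume_shape)}"
        )
    return mask


def write_volume(path, data: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_cohort(cases: list[PairedLesionCase], out_dir) -> Path:
    """Write volumes/masks as NIfTI plus clinical.csv and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    clinical_rows = []
    for case in cases:
        entry = {}
        for name in (
            "scan1_volume",
            "scan2_volume",
            "scan1_mask",
            "scan2_mask",
            "fat_mask",
            "muscle_mask",
        ):
            fname = f"{case.lesion_id}_{name}.nii"
            arr = getattr(case, name)
            write_volume(out / fname, arr.astype(np.float64), case.spacing)
            entry[name] = fname
        entry["spacing"] = list(case.spacing)
        manifest[case.lesion_id] = entry
        clinical_rows.append(
            {
                "lesion_id": case.lesion_id,
                "patient_id": case.patient_id,
                **asdict(case.clinical),
            }
        )
    pd.DataFrame(clinical_rows).to_csv(out / "clinical.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_cohort(cohort_dir) -> list[PairedLesionCase]:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    clinical = pd.read_csv(cohort_dir / "clinical.csv").set_index("lesion_id")
    cases = []
    for lesion_id in sorted(manifest):
        entry = manifest[lesion_id]
        vol1, spacing = read_volume(cohort_dir / entry["scan1_volume"])
        vol2, _ = read_volume(cohort_dir / entry["scan2_volume"])
        masks = {
            name: read_mask(cohort_dir / entry[name], vol1.shape)
            for name in ("scan1_mask", "scan2_mask", "fat_mask", "muscle_mask")
        }
        row = clinical.loc[lesion_id]
        cases.append(
            PairedLesionCase(
                lesion_id=lesion_id,
                patient_id=str(row["patient_id"]),
                scan1_volume=vol1,
                scan2_volume=vol2,
                spacing=spacing,
                clinical=ClinicalVariables(
                    psad=float(row["psad"]),
                    prostate_volume=float(row["prostate_volume"]),
                    pirads=int(row["pirads"]),
                    isup=int(row["isup"]),
                    is_index=bool(row["is_index"]),
                ),
                **masks,
            )
        )
    return cases


def write_settings_grid(path, settings: list[PreprocessSetting] | None = None) -> None:
    settings = settings if settings is not None else enumerate_settings()
    Path(path).write_text(json.dumps([s.to_dict() for s in settings], indent=2))


def read_settings_grid(path) -> list[PreprocessSetting]:
    return [PreprocessSetting.from_dict(d) for d in json.loads(Path(path).read_text())]


def load_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file (missing keys default)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tuple_keys = {
        "grid_shape",
        "voxel_spacing",
        "gain_range",
        "offset_range",
        "lesion_radius_range",
    }
    kwargs = {
        k: tuple(v) if k in tuple_keys and isinstance(v, list) else v
        for k, v in raw.items()
    }
    return SimulationConfig(**kwargs)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, config: dict, seed, inputs: dict, outputs: dict, warnings_list) -> None:
    from . import __version__

    manifest = {
        "software_version": __version__,
        "seed": seed,
        "config": config,
        "input_hashes": {k: file_sha256(v) for k, v in inputs.items()},
        "output_hashes": {k: file_sha256(v) for k, v in outputs.items()},
        "warnings": list(warnings_list),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
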