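"""File formats: TAC CSV, dynamic NIfTI + frame-timing sidecar, YAML config.

TAC CSV dialect (UTF-8, header required):
    frame_index, t_start_min, t_end_min, value, units

NIfTI-1 has no per-frame timing field, so 4D dynamic volumes travel with a
JSON (or CSV) sidecar carrying ``frame_start_min``/``frame_end_min``
arrays.  Region masks are integer-labelled NIfTI volumes.

Scenario YAML blocks: input_function, rate_constants (per region),
ph (per region, optional), ph_response, schedule, noise, seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    FrameSchedule,
    InputFunction,
    RateConstants,
    TimeActivityCurve,
    ValidationError,
)
from .ph_response import PHResponseModel
from .synthetic import ScenarioSpec, RegionSpec, make_scenario

__all__ = [
    "read_tac_csv", "write_tac_csv",
    "read_frame_sidecar", "write_frame_sidecar",
    "read_dynamic_nifti", "write_dynamic_nifti",
    "read_mask_nifti", "write_mask_nifti",
    "load_scenario_yaml", "dump_scenario_yaml",
]

TAC_COLUMNS = ["frame_index", "t_start_min", "t_end_min", "value", "units"]


def write_tac_csv(tac: TimeActivityCurve, path) -> None:
    df = pd.DataFrame({
        "frame_index": np.arange(1, len(tac.schedule) + 1),
        "t_start_min": tac.schedule.start,
        "t_end_min": tac.schedule.end,
        "value": tac.values,
        "units": tac.units,
    })
    df.to_csv(path, index=False)


def read_tac_csv(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"TAC CSV {path} is missing column(s): {', '.join(missing)}")
    df = df.sort_values("frame_index")
    schedule = FrameSchedule(df["t_start_min"].to_numpy(), df["t_end_min"].to_numpy())
    units = str(df["units"].iloc[0])
    return TimeActivityCurve(schedule, df["value"].to_numpy(dtype=float), units=units)


def write_frame_sidecar(schedule: FrameSchedule, path) -> None:
    path = Path(path)
    payload = {"frame_start_min": schedule.start.tolist(),
               "frame_end_min": schedule.end.tolist()}
    if path.suffix.lower() == ".csv":
        pd.DataFrame(payload).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(payload, indent=1))


def read_frame_sidecar(path) -> FrameSchedule:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        start, end = df["frame_start_min"], df["frame_end_min"]
    else:
        payload = json.loads(path.read_text())
        start, end = payload["frame_start_min"], payload["frame_end_min"]
    return FrameSchedule(np.asarray(start, float), np.asarray(end, float))


def write_dynamic_nifti(img, img_path, sidecar_path=None) -> None:
    """Write a DynamicImage as 4D NIfTI plus (optionally) its sidecar."""
    affine = img.affine if img.affine is not None else np.diag(
        list(img.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(img.data.astype(np.float64), affine), str(img_path))
    if sidecar_path is not None:
        write_frame_sidecar(img.schedule, sidecar_path)


def read_dynamic_nifti(img_path, sidecar_path):
    """Load a 4D NIfTI and its frame-timing sidecar as a DynamicImage."""
    from .mapping import DynamicImage

    nii = nib.load(str(img_path))
    schedule = read_frame_sidecar(sidecar_path)
    data = np.asarray(nii.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"{img_path} is not a 4D volume")
    if data.shape[3] != len(schedule):
        raise ValidationError(
            f"sidecar has {len(schedule)} frames but image has {data.shape[3]}")
    voxels = tuple(float(v) for v in nii.header.get_zooms()[:3])
    return DynamicImage(data, schedule, voxels, np.asarray(nii.affine))


def write_mask_nifti(mask: np.ndarray, path, affine=None) -> None:
    affine = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.int16)


def _rates_to_dict(rc: RateConstants) -> dict:
    return {"K1": rc.K1, "k2": rc.k2, "k3": rc.k3, "kh_per_h": rc.kh,
            "k4": rc.k4, "k5": rc.k5}


def _rates_from_dict(d: dict) -> RateConstants:
    return RateConstants(K1=d["K1"], k2=d["k2"], k3=d["k3"], kh=d["kh_per_h"],
                         k4=d.get("k4", 0.0), k5=d.get("k5", 1.74))


def dump_scenario_yaml(spec: ScenarioSpec, path) -> None:
    regions = {}
    for name, rspec in spec.regions.items():
        if isinstance(rspec.rates, RateConstants):
            entry = {"rates": _rates_to_dict(rspec.rates)}
        else:
            entry = {"rates": [{"switch_time": t, **_rates_to_dict(rc)}
                               for t, rc in rspec.rates]}
        if rspec.ph is not None:
            entry["ph"] = rspec.ph
        regions[name] = entry
    doc = {
        "scenario": spec.name,
        "input_function": {"A1": spec.input_function.A1, "A2": spec.input_function.A2,
                           "lam1": spec.input_function.lam1,
                           "lam2": spec.input_function.lam2,
                           "delay": spec.input_function.delay},
        "rate_constants": regions,
        "ph_response": {"ph50": spec.ph_model.ph50, "hill": spec.ph_model.hill,
                        "floor": spec.ph_model.floor, "ceiling": spec.ph_model.ceiling},
        "schedule": {"frame_start_min": spec.schedule.start.tolist(),
                     "frame_end_min": spec.schedule.end.tolist()},
        "noise": spec.noise,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario_yaml(path) -> ScenarioSpec:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        regions = {}
        for name, entry in doc["rate_constants"].items():
            raw = entry["rates"]
            if isinstance(raw, dict):
                rates = _rates_from_dict(raw)
            else:
                rates = tuple((float(seg["switch_time"]), _rates_from_dict(seg))
                              for seg in raw)
            regions[name] = RegionSpec(rates=rates, ph=entry.get("ph"))
        spec = ScenarioSpec(
            name=doc.get("scenario", "custom"),
            regions=regions,
            input_function=InputFunction(**doc["input_function"]),
            ph_model=PHResponseModel(**doc.get("ph_response", {})),
            schedule=FrameSchedule(
                np.asarray(doc["schedule"]["frame_start_min"], float),
                np.asarray(doc["schedule"]["frame_end_min"], float)),
            noise=float(doc.get("noise", 0.0)),
            seed=doc.get("seed"),
        )
    except KeyError as e:
        raise ValidationError(f"scenario config is missing required field {e}") from e
    return spec
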