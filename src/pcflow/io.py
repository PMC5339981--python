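"""File interchange: NIfTI and compressed plain-array bundles for image-like
arrays, JSON for reports and truth records, CSV for tables.

Array layout on disk follows scanner export conventions: NIfTI volumes are
stored as (row, col, frame) with the pixel size in the affine, one file per
velocity component; encoded series go out as paired magnitude/phase stacks
(phase in (-pi, pi]) with a JSON sidecar carrying venc, seed and noise
parameters.  ``.npz`` bundles keep everything in one self-describing file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .encoding import EncodedSeries, VelocityMaps, wrap_phase
from .phantom import PlaneSpec, SubjectTruth, TTEMeasurement, VelocityField
from .quantify import HemodynamicReport

__all__ = [
    "save_field_npz", "load_field_npz",
    "save_maps_npz", "load_maps_npz",
    "save_field_nifti", "load_maps_nifti",
    "save_encoded_series", "load_encoded_series",
    "save_json", "load_json",
    "truth_to_dict", "tte_to_dict", "report_to_dict",
]


def _plane_meta(plane: PlaneSpec) -> dict:
    return dataclasses.asdict(plane)


def _plane_from_meta(meta: Mapping) -> PlaneSpec:
    return PlaneSpec(**{k: meta[k] for k in (
        "grid_nx", "grid_ny", "pixel_size", "n_frames", "frame_dt",
        "plane_index", "plane_offset")})


def _affine(plane: PlaneSpec) -> np.ndarray:
    return np.diag([plane.pixel_size, plane.pixel_size, plane.frame_dt, 1.0])


def _to_nifti_order(a: np.ndarray) -> np.ndarray:
    # [frame, y, x] -> (y, x, frame)
    return np.ascontiguousarray(np.moveaxis(a, 0, -1))


def _from_nifti_order(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.moveaxis(a, -1, 0))


# ---------------------------------------------------------------- npz bundles

def save_field_npz(field: VelocityField, path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path, vx=field.vx, vy=field.vy, vz=field.vz,
        lumen_mask=field.lumen_mask, signal_magnitude=field.signal_magnitude,
        plane_json=np.bytes_(json.dumps(_plane_meta(field.plane)).encode()),
    )
    return path


def load_field_npz(path) -> VelocityField:
    with np.load(path) as z:
        plane = _plane_from_meta(json.loads(bytes(z["plane_json"]).decode()))
        return VelocityField(
            vx=z["vx"], vy=z["vy"], vz=z["vz"], lumen_mask=z["lumen_mask"],
            signal_magnitude=z["signal_magnitude"], plane=plane,
        )


def save_maps_npz(maps: VelocityMaps, path) -> Path:
    path = Path(path)
    np.savez_compressed(
        path, vx=maps.vx, vy=maps.vy, vz=maps.vz, magnitude=maps.magnitude,
        venc=np.float64(maps.venc),
        plane_json=np.bytes_(json.dumps(_plane_meta(maps.plane)).encode()),
    )
    return path


def load_maps_npz(path) -> VelocityMaps:
    with np.load(path) as z:
        plane = _plane_from_meta(json.loads(bytes(z["plane_json"]).decode()))
        return VelocityMaps(
            vx=z["vx"], vy=z["vy"], vz=z["vz"], magnitude=z["magnitude"],
            venc=float(z["venc"]), plane=plane,
        )


# -------------------------------------------------------------------- NIfTI

def save_field_nifti(field: VelocityField, directory, stem: str = "field") -> dict:
    """One NIfTI per velocity component (frame as 3rd dim) plus masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(field.plane)
    paths = {}
    for name, arr in (("vx", field.vx), ("vy", field.vy), ("vz", field.vz)):
        p = directory / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(_to_nifti_order(arr), aff), p)
        paths[name] = p
    for name, arr in (
        ("lumen_mask", field.lumen_mask.astype(np.uint8)),
        ("magnitude", field.signal_magnitude),
    ):
        p = directory / f"{stem}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.ascontiguousarray(arr), aff), p)
        paths[name] = p
    save_json(_plane_meta(field.plane), directory / f"{stem}_plane.json")
    paths["plane"] = directory / f"{stem}_plane.json"
    return paths


def load_maps_nifti(vx_path, vy_path, vz_path, *, venc: float,
                    plane_json=None, pixel_size: float = 1.95,
                    frame_dt: float = 40.0, plane_index: int = 0) -> VelocityMaps:
    """Assemble decoded maps from per-component NIfTI files.

    Plane metadata comes from a sidecar JSON when available, otherwise from
    the keyword arguments.
    """
    arrs = [
        _from_nifti_order(np.asanyarray(nib.load(p).dataobj, dtype=float))
        for p in (vx_path, vy_path, vz_path)
    ]
    nf, ny, nx = arrs[0].shape
    if plane_json is not None:
        plane = _plane_from_meta(load_json(plane_json))
    else:
        plane = PlaneSpec(grid_nx=nx, grid_ny=ny, pixel_size=pixel_size,
                          n_frames=nf, frame_dt=frame_dt, plane_index=plane_index)
    return VelocityMaps(
        vx=arrs[0], vy=arrs[1], vz=arrs[2], magnitude=np.ones_like(arrs[0]),
        venc=venc, plane=plane,
    )


def save_encoded_series(series: EncodedSeries, directory, stem: str = "encoded") -> dict:
    """Paired magnitude/phase stacks (4D: y, x, frame, encoding) + sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    z = series.complex_images  # [4, f, y, x]
    mag = np.moveaxis(np.abs(z), (0, 1), (-1, -2))  # (y, x, f, 4)
    phs = np.moveaxis(wrap_phase(np.angle(z)), (0, 1), (-1, -2))
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = series.plane.pixel_size
    p_mag = directory / f"{stem}_mag.nii.gz"
    p_phs = directory / f"{stem}_phase.nii.gz"
    nib.save(nib.Nifti1Image(np.ascontiguousarray(mag), aff), p_mag)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(phs), aff), p_phs)
    sidecar = {
        "venc": series.venc, "noise_sigma": series.noise_sigma,
        "seed": series.seed, "plane": _plane_meta(series.plane),
        "background_phase": (
            series.background_phase
            if np.isscalar(series.background_phase)
            else "map"
        ),
    }
    p_json = directory / f"{stem}.json"
    save_json(sidecar, p_json)
    return {"magnitude": p_mag, "phase": p_phs, "sidecar": p_json}


def load_encoded_series(mag_path, phase_path, sidecar_path) -> EncodedSeries:
    meta = load_json(sidecar_path)
    mag = np.asanyarray(nib.load(mag_path).dataobj, dtype=float)
    phs = np.asanyarray(nib.load(phase_path).dataobj, dtype=float)
    z = mag * np.exp(1j * phs)  # (y, x, f, 4)
    z = np.moveaxis(z, (-1, -2), (0, 1))
    bg = meta["background_phase"]
    return EncodedSeries(
        complex_images=np.ascontiguousarray(z),
        venc=meta["venc"], noise_sigma=meta["noise_sigma"],
        background_phase=0.0 if bg == "map" else bg,
        seed=meta["seed"], plane=_plane_from_meta(meta["plane"]),
    )


# --------------------------------------------------------------------- JSON

class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def save_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path


def load_json(path):
    return json.loads(Path(path).read_text())


def truth_to_dict(truth: SubjectTruth) -> dict:
    d = dataclasses.asdict(truth)
    d["true_peak_speed_per_plane"] = {
        str(k): v for k, v in truth.true_peak_speed_per_plane.items()
    }
    d["true_sv_per_plane"] = {str(k): v for k, v in truth.true_sv_per_plane.items()}
    return d


def tte_to_dict(tte: TTEMeasurement) -> dict:
    return dataclasses.asdict(tte)


def report_to_dict(report: HemodynamicReport) -> dict:
    return report.to_dict()
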