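"""Hemodynamic quantification from decoded velocity maps.

Implements the post-processing chain used clinically to grade aortic
stenosis from phase-contrast velocity maps:

* pixel rejection by joint magnitude and temporal-average-flow thresholds,
* the pixel-wise speed map  V = sqrt(Vx^2 + Vy^2 + Vz^2),
* per-frame peak-velocity curves in 1Dir (|Vz| only) or 3Dir (speed) mode,
* selection of the acquisition plane with the highest peak,
* peak/mean velocity, modified-Bernoulli pressure gradients
  (PG = 4 Vpeak^2 mmHg, MG = time-average of 4 v(t)^2),
* the velocity-time integral (trapezoidal, full cycle),
* through-plane stroke volume over a vessel ROI, and
* continuity-equation valve areas: AVA = A_LVOT * VTI_LVOT / VTI_AV with
  A_LVOT = pi (D/2)^2, plus the CMR variants AVA_Cine = SV_cine / VTI_AV and
  AVA_Flow = SV_PC / VTI_AV.

Stroke volume always uses the through-plane component Vz — volumetric flux
through a plane is the normal component by definition — in both 1Dir and
3Dir modes.  No background phase-offset correction is applied anywhere in
the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .encoding import VelocityMaps, detect_aliasing
from .unwrap import unwrap_velocity

__all__ = [
    "ThresholdConfig",
    "PeakCurve",
    "HemodynamicReport",
    "SalvageFailedError",
    "threshold_mask",
    "speed_map",
    "peak_velocity_curve",
    "select_plane",
    "v_mean",
    "bernoulli_gradient",
    "mean_gradient",
    "vti",
    "stroke_volume_pc",
    "lvot_area",
    "ava_continuity",
    "ava_cine",
    "ava_flow",
    "quantify_subject",
    "REPORT_COLUMNS",
]

MODES = ("1Dir", "3Dir")

REPORT_COLUMNS = [
    "vpeak_ms", "vmean_ms", "mg_mmhg", "pg_mmhg", "vti_cm", "sv_ml",
    "ava_cine_cm2", "ava_flow_cm2", "selected_plane", "method",
]


class SalvageFailedError(RuntimeError):
    """A plane shows velocity aliasing that phase unwrapping cannot fix."""

    def __init__(self, plane_index: int, directions: Sequence[str]):
        self.plane_index = plane_index
        self.directions = list(directions)
        super().__init__(
            f"salvage failed at plane {plane_index}, directions {self.directions}"
        )


def _norm_mode(mode: str) -> str:
    m = mode.lower()
    if m in ("1dir", "1d"):
        return "1Dir"
    if m in ("3dir", "3d"):
        return "3Dir"
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Pixel-rejection thresholds.

    ``mag_frac``: fraction of the maximum time-minimum magnitude a pixel must
    retain in every frame.  ``flow_floor_frac``: the temporal mean per-pixel
    flow speed must exceed this fraction of venc (or the absolute
    ``flow_floor_cms`` when given).  Both criteria must hold; the surviving
    mask is static across frames.
    """

    mag_frac: float = 0.15
    flow_floor_frac: float = 0.05
    flow_floor_cms: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mag_frac < 1.0):
            raise ValueError("mag_frac must be in [0, 1)")
        if self.flow_floor_frac < 0:
            raise ValueError("flow_floor_frac must be >= 0")
        if self.flow_floor_cms is not None and self.flow_floor_cms < 0:
            raise ValueError("flow_floor_cms must be >= 0")

    def flow_floor(self, venc: float) -> float:
        return self.flow_floor_cms if self.flow_floor_cms is not None \
            else self.flow_floor_frac * venc


@dataclass
class PeakCurve:
    """Per-frame maximum velocity over retained pixels."""

    t: np.ndarray  # ms
    v: np.ndarray  # cm/s
    plane_index: int | None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if np.any(self.v < 0):
            raise ValueError("peak-curve velocities must be >= 0")


@dataclass
class HemodynamicReport:
    """All stenosis parameters for one subject and one method."""

    vpeak: float  # m/s
    vmean: float  # m/s
    mg: float  # mmHg
    pg: float  # mmHg
    vti_av: float  # cm
    sv_pc: float | None  # mL
    sv_cine: float | None  # mL
    ava_cine: float | None  # cm^2
    ava_flow: float | None  # cm^2
    ava_tte_style: float | None  # cm^2
    selected_plane: int | None
    method: str  # 1Dir | 3Dir | TTE

    def __post_init__(self) -> None:
        if abs(self.pg - 4.0 * self.vpeak**2) > 1e-9 * max(1.0, self.pg):
            raise ValueError("pg must equal 4*vpeak^2")
        if self.vpeak + 1e-12 < self.vmean:
            raise ValueError("vpeak must be >= vmean")

    def to_row(self) -> dict:
        return {
            "vpeak_ms": self.vpeak, "vmean_ms": self.vmean,
            "mg_mmhg": self.mg, "pg_mmhg": self.pg, "vti_cm": self.vti_av,
            "sv_ml": self.sv_pc, "ava_cine_cm2": self.ava_cine,
            "ava_flow_cm2": self.ava_flow, "selected_plane": self.selected_plane,
            "method": self.method,
        }

    def to_dict(self) -> dict:
        d = self.to_row()
        d.update(sv_cine_ml=self.sv_cine, ava_tte_style_cm2=self.ava_tte_style)
        return d


def speed_map(maps: VelocityMaps) -> np.ndarray:
    """Pixel-wise speed sqrt(vx^2 + vy^2 + vz^2), per frame."""
    return maps.speed()


def threshold_mask(
    maps: VelocityMaps,
    mode: str,
    cfg: ThresholdConfig | None = None,
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Static retained-pixel mask: magnitude AND temporal-mean-flow criteria.

    The flow criterion uses |vz| in 1Dir mode and the speed map in 3Dir mode.
    """
    cfg = cfg or ThresholdConfig()
    mode = _norm_mode(mode)
    tmin = maps.magnitude.min(axis=0)
    ref = tmin[roi].max() if roi is not None else tmin.max()
    mag_ok = tmin >= cfg.mag_frac * ref
    flow = np.abs(maps.vz) if mode == "1Dir" else maps.speed()
    flow_ok = flow.mean(axis=0) >= cfg.flow_floor(maps.venc)
    mask = mag_ok & flow_ok
    if roi is not None:
        mask &= roi
    if not mask.any():
        raise ValueError("no pixels survive thresholds")
    return mask


def peak_velocity_curve(maps: VelocityMaps, mask: np.ndarray, mode: str) -> PeakCurve:
    """Per-frame maximum of |vz| (1Dir) or speed (3Dir) over masked pixels."""
    if not mask.any():
        raise ValueError("mask must be non-empty")
    mode = _norm_mode(mode)
    v = np.abs(maps.vz) if mode == "1Dir" else maps.speed()
    return PeakCurve(
        t=maps.plane.frame_times, v=v[:, mask].max(axis=1),
        plane_index=maps.plane.plane_index,
    )


def select_plane(curves: Sequence[PeakCurve]) -> int:
    """Index (into ``curves``) of the highest-peak curve; ties -> lowest."""
    if len(curves) == 0:
        raise ValueError("at least one curve is required")
    peaks = np.array([c.v.max() for c in curves])
    return int(np.argmax(peaks))


def _ejection_sel(curve: PeakCurve, window: str, floor_frac: float) -> np.ndarray:
    if window == "full_cycle":
        return np.ones_like(curve.v, dtype=bool)
    if window != "ejection":
        raise ValueError("window must be 'ejection' or 'full_cycle'")
    vmax = curve.v.max()
    if vmax == 0:
        return np.ones_like(curve.v, dtype=bool)
    return curve.v > floor_frac * vmax


def v_mean(curve: PeakCurve, window: str = "ejection",
           floor_frac: float = 0.01) -> float:
    """Mean of the peak-velocity curve in m/s.

    ``ejection`` (default) averages frames above ``floor_frac`` of the curve
    maximum — the Doppler convention of averaging over the ejection envelope;
    ``full_cycle`` averages every frame.
    """
    sel = _ejection_sel(curve, window, floor_frac)
    return float(curve.v[sel].mean()) / 100.0


def bernoulli_gradient(v: float) -> float:
    """Modified Bernoulli pressure gradient 4*v^2 (v in m/s -> mmHg)."""
    if v < 0:
        raise ValueError("velocity must be >= 0")
    return 4.0 * v * v


def mean_gradient(curve: PeakCurve, window: str = "ejection",
                  floor_frac: float = 0.01) -> float:
    """Time-average of 4*v(t)^2 over the same window as v_mean (mmHg).

    Note MG != 4*Vmean^2: the square is averaged, not the mean squared.
    """
    sel = _ejection_sel(curve, window, floor_frac)
    v_ms = curve.v[sel] / 100.0
    return float(np.mean(4.0 * v_ms**2))


def vti(curve: PeakCurve) -> float:
    """Velocity-time integral over the full cycle (trapezoidal), in cm."""
    return float(np.trapezoid(curve.v, curve.t / 1000.0))


def stroke_volume_pc(maps: VelocityMaps, roi: np.ndarray) -> float:
    """Through-plane stroke volume over the ROI, in mL (rectangle rule).

    Uses vz only, in both modes: flux through a plane is inherently the
    normal velocity component times area.
    """
    if roi is None or not roi.any():
        raise ValueError("roi must be non-empty")
    dt_s = maps.plane.frame_dt / 1000.0
    return float(maps.vz[:, roi].sum() * maps.plane.pixel_area_cm2 * dt_s)


def lvot_area(d: float) -> float:
    """Circular LVOT area pi*(D/2)^2, D in cm -> cm^2."""
    if d < 0:
        raise ValueError("diameter must be >= 0")
    return math.pi * (d / 2.0) ** 2


def ava_continuity(a_lvot: float, vti_lvot: float, vti_av: float) -> float:
    """Continuity-equation valve area A_LVOT * VTI_LVOT / VTI_AV (cm^2)."""
    if vti_av <= 0:
        raise ValueError("vti_av must be > 0")
    return a_lvot * vti_lvot / vti_av


def ava_cine(sv_cine: float, vti_av: float) -> float:
    """Valve area from cine stroke volume: SV_cine / VTI_AV (mL/cm = cm^2)."""
    if vti_av <= 0:
        raise ValueError("vti_av must be > 0")
    return sv_cine / vti_av


def ava_flow(sv_pc: float, vti_av: float) -> float:
    """Valve area from PC stroke volume: SV_PC / VTI_AV (mL/cm = cm^2)."""
    if vti_av <= 0:
        raise ValueError("vti_av must be > 0")
    return sv_pc / vti_av


def quantify_subject(
    maps_by_plane: Mapping[int, VelocityMaps],
    rois: Mapping[int, np.ndarray],
    mode: str,
    *,
    sv_cine: float | None = None,
    lvot_diameter: float | None = None,
    vti_lvot: float | None = None,
    cfg: ThresholdConfig | None = None,
    vmean_window: str = "ejection",
    ejection_floor_frac: float = 0.01,
    unwrap_method: str = "temporal",
) -> HemodynamicReport:
    """Run threshold -> (unwrap if flagged) -> curves -> plane selection ->
    all hemodynamic parameters for one subject and one velocity-measurement
    mode.

    Raises :class:`SalvageFailedError` when a plane is aliased beyond repair;
    cohort drivers exclude such subjects with a logged reason.
    """
    mode = _norm_mode(mode)
    cfg = cfg or ThresholdConfig()
    keys = sorted(maps_by_plane)
    curves: list[PeakCurve] = []
    cleaned: dict[int, VelocityMaps] = {}
    for k in keys:
        maps = maps_by_plane[k]
        roi = rois[k]
        rep = detect_aliasing(maps, lumen_mask=roi)
        if rep.any:
            maps, urep = unwrap_velocity(maps, method=unwrap_method, lumen_mask=roi)
            if urep.failed:
                raise SalvageFailedError(
                    k, [d for d, bad in urep.salvage_failed.items() if bad]
                )
        cleaned[k] = maps
        mask = threshold_mask(maps, mode, cfg, roi=roi)
        curves.append(peak_velocity_curve(maps, mask, mode))

    i = select_plane(curves)
    sel_key = keys[i]
    curve = curves[i]
    vpeak = float(curve.v.max()) / 100.0
    vm = v_mean(curve, window=vmean_window, floor_frac=ejection_floor_frac)
    mg = mean_gradient(curve, window=vmean_window, floor_frac=ejection_floor_frac)
    pg = bernoulli_gradient(vpeak)
    vti_av = vti(curve)
    sv_pc = stroke_volume_pc(cleaned[sel_key], rois[sel_key])

    a_cine = ava_cine(sv_cine, vti_av) if sv_cine is not None and vti_av > 0 else None
    a_flow = ava_flow(sv_pc, vti_av) if vti_av > 0 else None
    a_tte = None
    if lvot_diameter is not None and vti_lvot is not None and vti_av > 0:
        a_tte = ava_continuity(lvot_area(lvot_diameter), vti_lvot, vti_av)

    return HemodynamicReport(
        vpeak=vpeak, vmean=vm, mg=mg, pg=pg, vti_av=vti_av,
        sv_pc=sv_pc, sv_cine=sv_cine, ava_cine=a_cine, ava_flow=a_flow,
        ava_tte_style=a_tte, selected_plane=sel_key, method=mode,
    )
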