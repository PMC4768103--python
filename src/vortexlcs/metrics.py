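"""Vortex and chamber quantification.

Volumes use short-axis slice summation (union of delineated areas times slice
thickness, summed over slices). The vortex-wall distance is the difference of
sphere-equivalent radii of the chamber and the vortex. Valve and vortex sizes
are expressed as effective (equal-area circle) diameters; the vortex
formation ratio is the length of the ejected fluid column divided by the
inlet diameter, VFR = L/D = 4 V / (pi D^3).

Unit regime: volumes ml, areas mm^2, lengths mm, velocities cm/s, flow rates
ml/s, times ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy

from . import geometry
from .exceptions import DomainError, MeasurementError
from .flow_io import ContourSet, VelocityField4D

__all__ = [
    "slice_summation_volume",
    "vortex_wall_distance",
    "vortex_volume_fraction",
    "through_plane_flow_profile",
    "EWaveTiming",
    "detect_e_wave",
    "mitral_effective_diameter",
    "max_lcs_diameter",
    "diameter_ratio",
    "vortex_formation_ratio",
    "peak_filling_rate",
    "MetricsTable",
]


# ---------------------------------------------------------------------------
# volumetrics
# ---------------------------------------------------------------------------


def slice_summation_volume(contours: ContourSet) -> pd.Series:
    """Chamber/vortex volume per timeframe (ml) by short-axis slice summation.

    Per slice the *union* of the delineated polygon areas is multiplied by
    the slice thickness; overlapping polygons within a slice are never double
    counted. Slice volumes are summed per timeframe; 1 ml = 1000 mm^3.
    """
    if contours.slice_thickness <= 0:
        raise DomainError("slice thickness must be positive")
    volumes: dict[int, float] = {}
    for (tf, _sl), polys in contours.contours.items():
        area = geometry.union_area(polys)
        volumes[tf] = volumes.get(tf, 0.0) + area * contours.slice_thickness / 1000.0
    series = pd.Series(volumes, dtype=float).sort_index()
    series.index.name = "timeframe"
    series.name = "volume_ml"
    return series


def vortex_wall_distance(lv_volume_ml, vortex_volume_ml):
    """Sphere-equivalent radius difference (mm) between chamber and vortex.

    Radius of the sphere matching the LV volume minus the radius of the
    sphere matching the vortex volume: (3V/4pi)^(1/3) with V in mm^3.
    """
    lv = np.asarray(lv_volume_ml, dtype=float)
    vv = np.asarray(vortex_volume_ml, dtype=float)
    if np.any(lv < 0) or np.any(vv < 0):
        raise DomainError("volumes must be non-negative")
    if np.any(vv > lv + 1e-12):
        raise DomainError("vortex volume cannot exceed LV volume after cropping")
    r = lambda v_ml: np.cbrt(3.0 * v_ml * 1000.0 / (4.0 * np.pi))
    out = r(lv) - r(vv)
    return float(out) if out.ndim == 0 else out


def vortex_volume_fraction(vortex_volume_ml, lv_volume_ml):
    """Vortex volume as a percentage of LV volume (VV%)."""
    lv = np.asarray(lv_volume_ml, dtype=float)
    vv = np.asarray(vortex_volume_ml, dtype=float)
    if np.any(lv <= 0):
        raise DomainError("LV volume must be positive")
    out = 100.0 * vv / lv
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# flow profiles
# ---------------------------------------------------------------------------


def through_plane_flow_profile(
    field: VelocityField4D,
    slice_index: int,
    roi: ContourSet | np.ndarray,
    normal_sign: int = 1,
    timeframes: list[int] | None = None,
) -> pd.DataFrame:
    """Signed through-plane flow rate (ml/s) and peak speed per timeframe.

    The through-plane component on a short-axis slice is vz. Flow is summed
    over voxel centers inside the ROI: 1 cm/s over 1 mm^2 equals 0.01 ml/s.
    ``normal_sign`` flips the positive flow direction (+1 keeps +z positive).
    The ROI is either a polygon array or a ContourSet keyed on the slice (the
    polygon of its first timeframe entry for the slice is used).
    """
    if isinstance(roi, ContourSet):
        polys = None
        for (tf, sl), p in sorted(roi.contours.items()):
            if sl == slice_index and p:
                polys = p
                break
        if polys is None:
            raise DomainError(f"ROI contour set has no polygon for slice {slice_index}")
    else:
        polys = [np.asarray(roi, dtype=float)]
    geom = geometry.to_shapely(polys)
    if geom.is_empty:
        raise DomainError("empty ROI")

    x = field.axis_coordinates(0)
    y = field.axis_coordinates(1)
    Y, X = np.meshgrid(y, x, indexing="ij")
    inside = contains_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)
    if not np.any(inside):
        raise DomainError("ROI contains no voxel centers")
    voxel_area = float(field.grid_spacing[0] * field.grid_spacing[1])

    tfs = range(field.n_timeframes) if timeframes is None else timeframes
    rows = []
    for tf in tfs:
        vz = field.velocity[tf, slice_index, :, :, 2]
        sel = vz[inside]
        flow = normal_sign * float(sel.sum()) * voxel_area * 0.01
        peak = float(np.max(np.abs(sel)))
        rows.append((int(tf), float(field.time_points[tf]), flow, peak))
    return pd.DataFrame(rows, columns=["timeframe", "time_ms", "flow_ml_s", "peak_velocity_cm_s"])


@dataclass
class EWaveTiming:
    """Detected early-filling (E-wave) landmarks from a transmitral flow profile."""

    onset_timeframe: int
    onset_time_ms: float
    peak_timeframe: int
    peak_time_ms: float
    peak_flow_ml_s: float
    peak_velocity_cm_s: float


def detect_e_wave(profile: pd.DataFrame, onset_fraction: float = 0.05) -> EWaveTiming:
    """Locate E-wave onset and peak from a through-plane flow profile.

    The peak is the maximum positive flow rate; the onset is the earliest
    timeframe of the contiguous run before the peak in which the flow exceeds
    ``onset_fraction`` (default 5%) of the peak. This operationalizes the
    "beginning of vortex ring formation" used as the backward-integration
    origin.
    """
    flow = profile["flow_ml_s"].to_numpy()
    if np.all(flow <= 0):
        raise MeasurementError("no positive inflow in the profile")
    ipeak = int(np.argmax(flow))
    peak = flow[ipeak]
    onset = ipeak
    while onset > 0 and flow[onset - 1] > onset_fraction * peak:
        onset -= 1
    return EWaveTiming(
        onset_timeframe=int(profile["timeframe"].iloc[onset]),
        onset_time_ms=float(profile["time_ms"].iloc[onset]),
        peak_timeframe=int(profile["timeframe"].iloc[ipeak]),
        peak_time_ms=float(profile["time_ms"].iloc[ipeak]),
        peak_flow_ml_s=float(peak),
        peak_velocity_cm_s=float(profile["peak_velocity_cm_s"].iloc[ipeak]),
    )


# ---------------------------------------------------------------------------
# valve and vortex diameters
# ---------------------------------------------------------------------------


def mitral_effective_diameter(
    field: VelocityField4D,
    candidate_slices: list[int],
    rois: dict[int, np.ndarray],
    speed_threshold_cm_s: float = 10.0,
    normal_sign: int = 1,
) -> tuple[float, float, int, int]:
    """Mitral annular area and effective diameter from through-plane flow.

    At the timeframe of peak total flow, the flow-profile area of each
    candidate slice is the summed in-plane area of ROI voxels whose
    through-plane speed exceeds the threshold; the smallest area across
    slices is taken as the annular area, and the diameter is that of the
    equal-area circle. Returns (area mm^2, diameter mm, slice, timeframe).
    """
    if not candidate_slices:
        raise DomainError("at least one candidate slice is required")
    profiles = {
        sl: through_plane_flow_profile(field, sl, rois[sl], normal_sign=normal_sign)
        for sl in candidate_slices
    }
    total = sum(p["flow_ml_s"].to_numpy() for p in profiles.values())
    peak_tf = int(np.argmax(total))

    voxel_area = float(field.grid_spacing[0] * field.grid_spacing[1])
    x = field.axis_coordinates(0)
    y = field.axis_coordinates(1)
    Y, X = np.meshgrid(y, x, indexing="ij")

    best: tuple[float, int] | None = None
    for sl in candidate_slices:
        geom = geometry.to_shapely([np.asarray(rois[sl], dtype=float)])
        inside = contains_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)
        speed = np.abs(field.velocity[peak_tf, sl, :, :, 2])
        n_above = int(np.count_nonzero(inside & (speed > speed_threshold_cm_s)))
        if n_above == 0:
            continue
        area = n_above * voxel_area
        if best is None or area < best[0]:
            best = (area, sl)
    if best is None:
        raise MeasurementError(
            f"no ROI voxel exceeds {speed_threshold_cm_s} cm/s at the peak-flow timeframe"
        )
    area, sl = best
    return area, geometry.effective_diameter(area), sl, peak_tf


def max_lcs_diameter(lcs: ContourSet) -> float:
    """Largest per-slice effective diameter (mm) over all slices and timeframes.

    Mirrors the mitral measurement: per (timeframe, slice) the union area of
    the LCS delineations is converted to an equal-area-circle diameter and
    the maximum is taken.
    """
    if not lcs.contours:
        raise DomainError("empty contour set")
    best = 0.0
    for polys in lcs.contours.values():
        best = max(best, geometry.effective_diameter(geometry.union_area(polys)))
    return best


def diameter_ratio(max_lcs_diameter_mm: float, mitral_diameter_mm: float) -> float:
    """Ratio of the largest LCS diameter to the mitral effective diameter."""
    if mitral_diameter_mm <= 0:
        raise DomainError("mitral diameter must be positive")
    return float(max_lcs_diameter_mm) / float(mitral_diameter_mm)


def vortex_formation_ratio(inflow_volume_ml: float, inlet_diameter_mm: float) -> float:
    """VFR = L/D with L the inflow column length: VFR = 4 V / (pi D^3)."""
    if inlet_diameter_mm <= 0:
        raise DomainError("inlet diameter must be positive")
    if inflow_volume_ml < 0:
        raise DomainError("inflow volume must be non-negative")
    return float(4.0 * inflow_volume_ml * 1000.0 / (np.pi * inlet_diameter_mm**3))


def peak_filling_rate(volume_ml: pd.Series, time_ms: np.ndarray | None = None) -> float:
    """Peak of dV/dt (ml/s) by central differences over the volume-time curve."""
    v = volume_ml.to_numpy(dtype=float)
    if len(v) < 3:
        raise DomainError("need at least 3 samples to differentiate")
    if time_ms is None:
        time_ms = volume_ml.index.to_numpy(dtype=float)
    dvdt = np.gradient(v, np.asarray(time_ms, dtype=float) / 1000.0)
    return float(np.max(dvdt))


# ---------------------------------------------------------------------------
# assembled per-subject table
# ---------------------------------------------------------------------------


@dataclass
class MetricsTable:
    """Tidy per-timeframe metrics plus per-subject scalars.

    ``per_timeframe`` columns: subject_id, timeframe, time_ms, lv_volume_ml,
    vortex_volume_ml, vv_percent, wall_distance_mm. ``per_subject`` columns:
    subject_id, group, mitral_area_mm2, mitral_diameter_mm,
    max_lcs_diameter_mm, diameter_ratio, vfr, e_peak_velocity_cm_s,
    peak_filling_rate_ml_s.
    """

    per_timeframe: pd.DataFrame
    per_subject: pd.DataFrame

    def validate(self) -> None:
        pt = self.per_timeframe
        if len(pt):
            vvp = pt["vv_percent"].to_numpy()
            if np.any((vvp < 0) | (vvp > 100 + 1e-9)):
                raise DomainError("vv_percent outside [0, 100]")
            if np.any(pt["vortex_volume_ml"].to_numpy() > pt["lv_volume_ml"].to_numpy() + 1e-9):
                raise DomainError("vortex volume exceeds LV volume")
            if np.any(pt["lv_volume_ml"].to_numpy() < 0):
                raise DomainError("negative volume")

    def write(self, per_timeframe_path, per_subject_path) -> None:
        self.per_timeframe.to_csv(per_timeframe_path, index=False)
        self.per_subject.to_csv(per_subject_path, index=False)


def build_metrics_table(
    subject_id: str,
    group: str,
    lv_volume_ml: pd.Series,
    vortex_volume_ml: pd.Series,
    time_ms: dict[int, float],
    mitral_area_mm2: float | None = None,
    mitral_diameter_mm: float | None = None,
    lcs: ContourSet | None = None,
    inflow_volume_ml: float | None = None,
    e_peak_velocity_cm_s: float | None = None,
) -> MetricsTable:
    """Assemble the per-subject MetricsTable from stage outputs.

    Vortex volume defaults to 0 on timeframes that have an LV volume but no
    delineated vortex; the vortex is clipped to the LV volume (post-cropping
    numerical slack only).
    """
    rows = []
    for tf, lv in lv_volume_ml.items():
        vv = float(min(vortex_volume_ml.get(tf, 0.0), lv))
        rows.append(
            (
                subject_id,
                int(tf),
                float(time_ms.get(int(tf), np.nan)),
                float(lv),
                vv,
                vortex_volume_fraction(vv, lv),
                vortex_wall_distance(lv, vv),
            )
        )
    per_tf = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "timeframe",
            "time_ms",
            "lv_volume_ml",
            "vortex_volume_ml",
            "vv_percent",
            "wall_distance_mm",
        ],
    )

    max_d = max_lcs_diameter(lcs) if lcs is not None and lcs.contours else np.nan
    ratio = (
        diameter_ratio(max_d, mitral_diameter_mm)
        if np.isfinite(max_d) and mitral_diameter_mm
        else np.nan
    )
    vfr = (
        vortex_formation_ratio(inflow_volume_ml, mitral_diameter_mm)
        if inflow_volume_ml is not None and mitral_diameter_mm
        else np.nan
    )
    pfr = peak_filling_rate(per_tf.set_index("timeframe")["lv_volume_ml"],
                            per_tf["time_ms"].to_numpy()) if len(per_tf) >= 3 else np.nan
    per_subject = pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "group": group,
                "mitral_area_mm2": mitral_area_mm2,
                "mitral_diameter_mm": mitral_diameter_mm,
                "max_lcs_diameter_mm": max_d,
                "diameter_ratio": ratio,
                "vfr": vfr,
                "e_peak_velocity_cm_s": e_peak_velocity_cm_s,
                "peak_filling_rate_ml_s": pfr,
            }
        ]
    )
    table = MetricsTable(per_timeframe=per_tf, per_subject=per_subject)
    table.validate()
    return table
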