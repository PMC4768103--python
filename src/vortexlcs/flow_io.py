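"""Data model and on-disk formats for 4D phase-contrast velocity data.

Unit regime (fixed across the whole package, conversion happens only here):
velocities cm/s, positions/spacings mm, times ms. Velocity arrays are indexed
``[timeframe, z, y, x, component]`` with components ordered ``(vx, vy, vz)``;
voxel ``(ix, iy, iz)`` has its center at ``grid_origin + index * grid_spacing``.

Two on-disk dialects are supported:

* NIfTI: one ``.nii.gz`` per velocity component (RAS+, diagonal affine) plus a
  JSON sidecar holding timing, VENC and the velocity unit of the stored data.
* A single-file HDF5 archive holding the 5-D array and all metadata as
  attributes; this dialect round-trips bit exactly.

Contours (endocardium, LCS delineations, flow ROIs) are CSV with one row per
vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError, MetadataError, ParseError, ValidationError
from .geometry import polygon_area, strip_closing_vertex

GROUP_LABELS = ("control", "patient")
CONTOUR_LABELS = ("lcs", "endocardium", "roi")

_UNIT_TO_CM_S = {"cm/s": 1.0, "m/s": 100.0, "mm/s": 0.1}

_CONTOUR_COLUMNS = [
    "label",
    "timeframe",
    "slice_index",
    "polygon_id",
    "vertex_index",
    "x_mm",
    "y_mm",
    "z_mm",
    "slice_thickness_mm",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class VelocityField4D:
    """Gridded, time-resolved, three-component velocity field.

    Attributes
    ----------
    velocity : ndarray, shape (nt, nz, ny, nx, 3)
        Velocity in cm/s, components (vx, vy, vz).
    grid_spacing : ndarray, shape (3,)
        Voxel spacing (sx, sy, sz) in mm; the grid is regular by construction.
    grid_origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    time_points : ndarray, shape (nt,)
        Timeframe times in ms from the R-wave, strictly increasing.
    venc : float or None
        Velocity-encoding limit of the acquisition, cm/s.
    cycle_length : float or None
        Cardiac cycle length, ms.
    """

    velocity: np.ndarray
    grid_spacing: np.ndarray
    grid_origin: np.ndarray
    time_points: np.ndarray
    venc: float | None = None
    cycle_length: float | None = None

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.grid_spacing = np.asarray(self.grid_spacing, dtype=float).reshape(3)
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        self.time_points = np.asarray(self.time_points, dtype=float).reshape(-1)
        self.validate()

    # -- introspection ----------------------------------------------------
    @property
    def n_timeframes(self) -> int:
        return self.velocity.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.shape_zyx
        return nx, ny, nz

    @property
    def world_max(self) -> np.ndarray:
        """World coordinate of the last voxel center along each axis."""
        n = np.array(self.shape_xyz, dtype=float)
        return self.grid_origin + (n - 1) * self.grid_spacing

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along a world axis (0=x, 1=y, 2=z)."""
        n = self.shape_xyz[axis]
        return self.grid_origin[axis] + np.arange(n) * self.grid_spacing[axis]

    def copy_with(self, velocity: np.ndarray) -> "VelocityField4D":
        return VelocityField4D(
            velocity=velocity,
            grid_spacing=self.grid_spacing.copy(),
            grid_origin=self.grid_origin.copy(),
            time_points=self.time_points.copy(),
            venc=self.venc,
            cycle_length=self.cycle_length,
        )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError(
                f"velocity must have shape (nt, nz, ny, nx, 3), got {self.velocity.shape}"
            )
        if len(self.time_points) != self.velocity.shape[0]:
            raise ValidationError("time_points length must match number of timeframes")
        if len(self.time_points) < 2:
            raise ValidationError("at least 2 timeframes are required")
        if np.any(np.diff(self.time_points) <= 0):
            raise ValidationError("time_points must be strictly increasing")
        if np.any(self.grid_spacing <= 0):
            raise ValidationError("grid spacing must be positive on every axis")
        if not np.all(np.isfinite(self.velocity)):
            raise ValidationError("velocity contains non-finite values")
        if self.venc is not None:
            if self.venc <= 0:
                raise ValidationError("venc must be positive")
            vmax = float(np.max(np.abs(self.velocity)))
            if vmax > 10.0 * self.venc:
                raise ValidationError(
                    f"|v| up to {vmax:.1f} cm/s exceeds 10*venc={10 * self.venc:.1f} cm/s"
                )


@dataclass
class StationaryTissueMask:
    """Boolean voxel mask of stationary tissue, on the same grid as the field."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("stationary mask must be a 3-D (nz, ny, nx) array")
        if int(self.mask.sum()) < 10:
            raise ValidationError(
                "stationary mask needs at least 10 voxels to overdetermine the 4-coefficient fit"
            )

    def validate_against(self, field: VelocityField4D) -> None:
        if self.mask.shape != field.shape_zyx:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match field grid {field.shape_zyx}"
            )


@dataclass
class ContourSet:
    """Closed planar polygons per (timeframe, slice_index), in world mm.

    Polygons are stored open; the closing edge is implicit. Slices are
    short-axis planes of constant z; ``slice_index`` orders them along the
    slice normal.
    """

    label: str = "lcs"
    slice_thickness: float = 8.0
    contours: dict[tuple[int, int], list[np.ndarray]] = dataclass_field(default_factory=dict)

    def __post_init__(self):
        if self.label not in CONTOUR_LABELS:
            raise ValidationError(f"label must be one of {CONTOUR_LABELS}, got {self.label!r}")
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be positive")
        clean: dict[tuple[int, int], list[np.ndarray]] = {}
        for key, polys in self.contours.items():
            tf, sl = int(key[0]), int(key[1])
            clean[(tf, sl)] = [strip_closing_vertex(p) for p in polys]
        self.contours = clean

    def add(self, timeframe: int, slice_index: int, polygon: np.ndarray) -> None:
        poly = strip_closing_vertex(polygon)
        if len(poly) < 3:
            raise ValidationError("a contour needs at least 3 distinct vertices")
        self.contours.setdefault((int(timeframe), int(slice_index)), []).append(poly)

    def polygons(self, timeframe: int, slice_index: int) -> list[np.ndarray]:
        return self.contours.get((int(timeframe), int(slice_index)), [])

    @property
    def timeframes(self) -> list[int]:
        return sorted({tf for tf, _ in self.contours})

    def slices(self, timeframe: int) -> list[int]:
        return sorted({sl for tf, sl in self.contours if tf == timeframe})

    @property
    def n_polygons(self) -> int:
        return sum(len(p) for p in self.contours.values())

    def total_area(self, timeframe: int) -> float:
        return sum(
            polygon_area(p) for (tf, _), polys in self.contours.items() if tf == timeframe
            for p in polys
        )


@dataclass
class AcquisitionMeta:
    """Per-subject covariates carried alongside the flow data into the statistics."""

    subject_id: str
    group: str
    heart_rate_bpm: float
    slice_thickness_mm: float = 8.0

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise ValidationError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")
        if self.heart_rate_bpm <= 0:
            raise ValidationError("heart rate must be positive")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "heart_rate_bpm": self.heart_rate_bpm,
            "slice_thickness_mm": self.slice_thickness_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        return cls(**{k: d[k] for k in ("subject_id", "group", "heart_rate_bpm", "slice_thickness_mm") if k in d})


# ---------------------------------------------------------------------------
# velocity field I/O
# ---------------------------------------------------------------------------

_COMPONENT_SUFFIXES = ("vx", "vy", "vz")


def write_velocity_field(field: VelocityField4D, path: str | Path) -> Path:
    """Write a velocity field; dialect chosen by extension.

    ``.h5``/``.hdf5`` selects the single-file archive; anything else is taken
    as a basename for the NIfTI-per-component dialect and the sidecar path is
    returned.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return write_velocity_field_hdf5(field, path)
    return write_velocity_field_nifti(field, path)


def read_velocity_field(path: str | Path) -> VelocityField4D:
    """Read a velocity field from an HDF5 archive or a NIfTI JSON sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_velocity_field_hdf5(path)
    if path.suffix == ".json":
        return read_velocity_field_nifti(path)
    raise FormatError(f"cannot infer velocity-field dialect from {path.name!r}")


def write_velocity_field_hdf5(field: VelocityField4D, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("velocity", data=field.velocity)
        ds.attrs["axis_order"] = "t,z,y,x,component"
        ds.attrs["units"] = "cm/s"
        f.attrs["grid_spacing_mm"] = field.grid_spacing
        f.attrs["grid_origin_mm"] = field.grid_origin
        f.attrs["time_points_ms"] = field.time_points
        if field.venc is not None:
            f.attrs["venc_cm_s"] = float(field.venc)
        if field.cycle_length is not None:
            f.attrs["cycle_length_ms"] = float(field.cycle_length)
    return path


def read_velocity_field_hdf5(path: str | Path) -> VelocityField4D:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "velocity" not in f:
            raise FormatError(f"{path.name}: no 'velocity' dataset")
        velocity = f["velocity"][...]
        attrs = dict(f.attrs)
    for key in ("grid_spacing_mm", "grid_origin_mm", "time_points_ms"):
        if key not in attrs:
            raise MetadataError(f"{path.name}: missing attribute {key!r}")
    return VelocityField4D(
        velocity=velocity,
        grid_spacing=attrs["grid_spacing_mm"],
        grid_origin=attrs["grid_origin_mm"],
        time_points=attrs["time_points_ms"],
        venc=float(attrs["venc_cm_s"]) if "venc_cm_s" in attrs else None,
        cycle_length=float(attrs["cycle_length_ms"]) if "cycle_length_ms" in attrs else None,
    )


def write_velocity_field_nifti(field: VelocityField4D, basename: str | Path) -> Path:
    """Write one RAS+ NIfTI volume per component plus a JSON sidecar.

    Returns the sidecar path, which is the handle ``read_velocity_field`` takes.
    """
    basename = Path(basename)
    basename.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(np.append(field.grid_spacing, 1.0))
    affine[:3, 3] = field.grid_origin
    components = []
    for ci, suffix in enumerate(_COMPONENT_SUFFIXES):
        # nibabel indexes [x, y, z, t]; internal layout is [t, z, y, x, c]
        data = np.transpose(field.velocity[..., ci], (3, 2, 1, 0))
        img = nib.Nifti1Image(data, affine)
        img.header.set_xyzt_units("mm", "msec")
        comp_path = basename.parent / f"{basename.name}_{suffix}.nii.gz"
        nib.save(img, comp_path)
        components.append(comp_path.name)
    sidecar = {
        "components": components,
        "velocity_units": "cm/s",
        "grid_spacing_mm": field.grid_spacing.tolist(),
        "grid_origin_mm": field.grid_origin.tolist(),
        "time_points_ms": field.time_points.tolist(),
        "venc_cm_s": field.venc,
        "cycle_length_ms": field.cycle_length,
    }
    sidecar_path = basename.parent / f"{basename.name}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar_path


def read_velocity_field_nifti(sidecar_path: str | Path) -> VelocityField4D:
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"sidecar {sidecar_path.name}: {e}", line=e.lineno) from e
    for key in ("components", "time_points_ms"):
        if key not in meta or meta[key] is None:
            raise MetadataError(f"sidecar {sidecar_path.name}: missing {key!r}")
    unit = meta.get("velocity_units", "cm/s")
    if unit not in _UNIT_TO_CM_S:
        raise MetadataError(f"unsupported velocity unit {unit!r}")
    scale = _UNIT_TO_CM_S[unit]

    volumes = []
    spacing = None
    origin = None
    for name in meta["components"]:
        img = nib.load(sidecar_path.parent / name)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            data = data[..., np.newaxis]
        if data.ndim != 4:
            raise FormatError(f"{name}: expected a 4-D volume, got shape {data.shape}")
        aff = img.affine
        if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
            raise FormatError(f"{name}: only diagonal RAS+ affines are supported")
        sp = np.diag(aff[:3, :3])
        if np.any(sp <= 0):
            raise FormatError(f"{name}: affine is not RAS+ (non-positive spacing)")
        if spacing is None:
            spacing, origin = sp, aff[:3, 3]
        elif not (np.allclose(sp, spacing) and np.allclose(aff[:3, 3], origin)):
            raise FormatError(f"{name}: component grids are not congruent")
        volumes.append(data)
    if len(volumes) != 3:
        raise FormatError("expected exactly three velocity components")
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise FormatError(f"component volumes have mismatched shapes: {sorted(shapes)}")

    # [x, y, z, t] per component -> [t, z, y, x, 3]
    velocity = np.stack([np.transpose(v, (3, 2, 1, 0)) for v in volumes], axis=-1) * scale
    # sidecar-declared spacing/origin take precedence only if consistent
    if "grid_spacing_mm" in meta and meta["grid_spacing_mm"] is not None:
        if not np.allclose(meta["grid_spacing_mm"], spacing):
            raise MetadataError("sidecar grid_spacing_mm disagrees with NIfTI affine")
    return VelocityField4D(
        velocity=velocity,
        grid_spacing=spacing,
        grid_origin=origin,
        time_points=np.asarray(meta["time_points_ms"], dtype=float),
        venc=meta.get("venc_cm_s"),
        cycle_length=meta.get("cycle_length_ms"),
    )


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def write_mask(mask: StationaryTissueMask, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("mask", data=mask.mask.astype(np.uint8))
        ds.attrs["axis_order"] = "z,y,x"
    return path


def read_mask(path: str | Path) -> StationaryTissueMask:
    with h5py.File(Path(path), "r") as f:
        if "mask" not in f:
            raise FormatError(f"{Path(path).name}: no 'mask' dataset")
        return StationaryTissueMask(f["mask"][...].astype(bool))


# ---------------------------------------------------------------------------
# contour I/O
# ---------------------------------------------------------------------------


def write_contours(contours: ContourSet, path: str | Path) -> Path:
    """Write a ContourSet as tidy CSV, one row per vertex, full float precision."""
    path = Path(path)
    rows = []
    for (tf, sl), polys in sorted(contours.contours.items()):
        for pid, poly in enumerate(polys):
            for vi, (x, y, z) in enumerate(poly):
                rows.append((contours.label, tf, sl, pid, vi, x, y, z, contours.slice_thickness))
    df = pd.DataFrame(rows, columns=_CONTOUR_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_contours(path: str | Path) -> ContourSet:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(f"{path.name}: {e}") from e
    missing = [c for c in _CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}", line=1)
    if df.empty:
        return ContourSet(label="lcs", slice_thickness=8.0)

    for col in ("timeframe", "slice_index", "polygon_id", "vertex_index",
                "x_mm", "y_mm", "z_mm", "slice_thickness_mm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(f"non-numeric value in column {col!r}", line=int(bad.idxmax()) + 2)
        df[col] = coerced

    labels = df["label"].unique()
    if len(labels) != 1:
        raise ParseError(f"{path.name}: expected a single contour label, got {list(labels)}")
    thickness = float(df["slice_thickness_mm"].iloc[0])
    cs = ContourSet(label=str(labels[0]), slice_thickness=thickness)
    for (tf, sl, _pid), g in df.groupby(["timeframe", "slice_index", "polygon_id"], sort=True):
        g = g.sort_values("vertex_index")
        cs.add(int(tf), int(sl), g[["x_mm", "y_mm", "z_mm"]].to_numpy())
    return cs
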