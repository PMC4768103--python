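"""Synthetic 4D flow generators with exact ground truth.

Every pipeline stage is testable without any acquisition: analytic benchmark
flows (uniform translation, solid-body rotation, planar strain, the
time-periodic double gyre, Hill's spherical vortex) and a kinematic left
ventricle phantom are sampled onto MRI-like velocity grids (default 3 mm
isotropic, 40 timephases per 1000 ms cycle) with optional Gaussian velocity
noise and VENC wrap injection.

Analytic velocity callables take world points (N, 3) in mm and a time in ms
and return velocities in cm/s, so they plug directly into the same advection
machinery as gridded fields and serve as oracles.

The ventricle phantom is kinematic, not a Navier-Stokes solution: the cavity
is a time-varying ellipsoid whose volume follows a prescribed biphasic (E/A)
filling curve, fed by a plug-flow transmitral jet above the base. The vortex
is a growing sphere whose boundary is *exactly material*: the interior moves
with a radial growth flow r * (da/dt)/a plus a rigid swirl, and the exterior
is at rest. Rigid rotation and conformal scaling carry no relative
deformation, so the backward FTLE is non-positive inside and zero outside,
while the velocity jump at the sphere makes the boundary a sharp ridge — the
ground truth a Lagrangian method must recover is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np
import pandas as pd

from . import geometry
from .exceptions import ConfigurationError, GenerationError
from .flow_io import ContourSet, StationaryTissueMask, VelocityField4D

__all__ = [
    "GridSpec",
    "SyntheticFlowSpec",
    "GroundTruth",
    "generate_field",
    "synthetic_ventricle",
    "VentricleParams",
    "inject_noise",
    "inject_wraps",
    "uniform_velocity",
    "solid_rotation_velocity",
    "planar_strain_velocity",
    "double_gyre_velocity",
    "hill_vortex_velocity",
    "sample_to_field",
]

MODELS = (
    "uniform",
    "solid_rotation",
    "planar_strain",
    "double_gyre",
    "hill_vortex",
    "synthetic_ventricle",
)


# ---------------------------------------------------------------------------
# grids and specs
# ---------------------------------------------------------------------------


@dataclass
class GridSpec:
    """Sampling grid: shape (nx, ny, nz), spacing/origin in mm, times in ms."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    time_points: np.ndarray

    def __post_init__(self):
        self.time_points = np.asarray(self.time_points, dtype=float)

    @classmethod
    def cardiac_default(cls) -> "GridSpec":
        """MRI-like default: 3 mm isotropic, 40 timephases over a 1000 ms cycle."""
        return cls(
            shape=(25, 25, 42),
            spacing=(3.0, 3.0, 3.0),
            origin=(-36.0, -36.0, -54.0),
            time_points=np.arange(40) * 25.0,
        )

    def points(self) -> np.ndarray:
        """All voxel-center world coordinates, shape (nz*ny*nx, 3), z fastest last."""
        nx, ny, nz = self.shape
        x = self.origin[0] + np.arange(nx) * self.spacing[0]
        y = self.origin[1] + np.arange(ny) * self.spacing[1]
        z = self.origin[2] + np.arange(nz) * self.spacing[2]
        Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass
class SyntheticFlowSpec:
    """Declarative description of a synthetic dataset (model + grid + noise)."""

    model: str
    grid: GridSpec
    params: dict = dataclass_field(default_factory=dict)
    noise_sigma: float = 0.0
    venc: float | None = None
    wrap_inject: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        if self.wrap_inject and not self.venc:
            raise ConfigurationError("wrap injection requires a venc")


@dataclass
class GroundTruth:
    """Exact reference quantities carried alongside a generated field."""

    velocity_fn: Callable[[np.ndarray, float], np.ndarray] | None = None
    params: dict = dataclass_field(default_factory=dict)
    endo_contours: ContourSet | None = None
    vortex_contours: ContourSet | None = None
    lv_volume_ml: pd.Series | None = None
    vortex_volume_ml: pd.Series | None = None
    vv_percent: pd.Series | None = None
    wall_distance_mm: pd.Series | None = None
    inflow_rate: pd.DataFrame | None = None
    inflow_volume_ml: float | None = None
    mitral_diameter_mm: float | None = None
    e_onset_ms: float | None = None
    boundary_radius_mm: Callable[[float], float] | None = None
    stationary_mask: StationaryTissueMask | None = None
    wrapped_voxels: np.ndarray | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# analytic velocity models (points mm, time ms -> cm/s)
# ---------------------------------------------------------------------------


def uniform_velocity(points: np.ndarray, t_ms: float, c=(10.0, 0.0, 0.0)) -> np.ndarray:
    """Spatially uniform translation at ``c`` cm/s."""
    return np.broadcast_to(np.asarray(c, dtype=float), np.atleast_2d(points).shape).copy()


def solid_rotation_velocity(
    points: np.ndarray,
    t_ms: float,
    omega_rad_s: float = 10.0,
    center=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
) -> np.ndarray:
    """Rigid rotation omega x r about ``axis`` through ``center``.

    r in mm and omega in rad/s give v = omega x r in mm/s = 0.1 cm/s.
    """
    pts = np.atleast_2d(points) - np.asarray(center, dtype=float)
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    return 0.1 * omega_rad_s * np.cross(ax, pts)


def planar_strain_velocity(
    points: np.ndarray, t_ms: float, k_per_s: float = 3.0, center=(0.0, 0.0, 0.0)
) -> np.ndarray:
    """Incompressible planar strain u = (k x, -k y, 0), k in 1/s."""
    pts = np.atleast_2d(points) - np.asarray(center, dtype=float)
    out = np.zeros_like(pts)
    out[:, 0] = 0.1 * k_per_s * pts[:, 0]
    out[:, 1] = -0.1 * k_per_s * pts[:, 1]
    return out


def double_gyre_velocity(
    points: np.ndarray,
    t_ms: float,
    A: float = 0.1,
    eps: float = 0.25,
    omega: float = np.pi / 5.0,
    length_scale_mm: float = 100.0,
    time_scale_ms: float = 1000.0,
) -> np.ndarray:
    """Standard time-periodic double gyre on [0, 2] x [0, 1], scaled to mm/ms.

    The dimensionless stream function is psi = A sin(pi f(x, t)) sin(pi y)
    with f = eps sin(omega t) x^2 + (1 - 2 eps sin(omega t)) x; the unit
    square maps to ``length_scale_mm`` and unit time to ``time_scale_ms``.
    """
    pts = np.atleast_2d(points)
    L, Ts = length_scale_mm, time_scale_ms
    x = pts[:, 0] / L
    y = pts[:, 1] / L
    tau = t_ms / Ts
    a = eps * np.sin(omega * tau)
    b = 1.0 - 2.0 * eps * np.sin(omega * tau)
    f = a * x**2 + b * x
    dfdx = 2.0 * a * x + b
    u = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * y)
    v = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
    out = np.zeros_like(pts)
    scale = 100.0 * L / Ts  # dimensionless -> cm/s
    out[:, 0] = scale * u
    out[:, 1] = scale * v
    return out


def hill_vortex_velocity(
    points: np.ndarray,
    t_ms: float,
    a_mm: float = 20.0,
    U_cm_s: float = 15.0,
    center0=(0.0, 0.0, 0.0),
    translating: bool = True,
) -> np.ndarray:
    """Hill's spherical vortex of radius ``a_mm`` translating along +z at U.

    Interior (co-moving frame): u_z = (3U/2a^2)(a^2 - 2 s^2 - z^2),
    u_s = (3U/2a^2) s z, from the Stokes stream function
    psi = (3U/4a^2) s^2 (a^2 - R^2); exterior is the uniform stream plus a
    doublet, psi = -(U/2) s^2 (1 - a^3/R^3). Velocity is continuous at R = a
    and the sphere is a material surface. With ``translating`` the lab-frame
    field is returned (+U z added, center advected at U).
    """
    pts = np.atleast_2d(points).astype(float)
    center = np.asarray(center0, dtype=float).copy()
    if translating:
        center[2] += U_cm_s * 0.01 * t_ms  # cm/s -> mm/ms
    d = pts - center
    s2 = d[:, 0] ** 2 + d[:, 1] ** 2
    z = d[:, 2]
    R2 = s2 + z**2
    a2 = a_mm**2
    out = np.zeros_like(pts)

    inside = R2 <= a2
    coef = 1.5 * U_cm_s / a2
    # u_s / s is finite everywhere; multiply through by the cylindrical offsets
    us_over_s_in = coef * z[inside]
    out[inside, 0] = us_over_s_in * d[inside, 0]
    out[inside, 1] = us_over_s_in * d[inside, 1]
    out[inside, 2] = coef * (a2 - 2.0 * s2[inside] - z[inside] ** 2)

    outside = ~inside
    R2o = R2[outside]
    R5 = R2o**2.5
    us_over_s_out = 1.5 * U_cm_s * a_mm**3 * z[outside] / R5
    out[outside, 0] = us_over_s_out * d[outside, 0]
    out[outside, 1] = us_over_s_out * d[outside, 1]
    out[outside, 2] = U_cm_s * (
        -1.0 + a_mm**3 / R2o**1.5 - 1.5 * s2[outside] * a_mm**3 / R5
    )
    if translating:
        out[:, 2] += U_cm_s
    return out


_ANALYTIC_MODELS: dict[str, Callable] = {
    "uniform": uniform_velocity,
    "solid_rotation": solid_rotation_velocity,
    "planar_strain": planar_strain_velocity,
    "double_gyre": double_gyre_velocity,
    "hill_vortex": hill_vortex_velocity,
}


def sample_to_field(
    velocity_fn: Callable[[np.ndarray, float], np.ndarray],
    grid: GridSpec,
    venc: float | None = None,
    cycle_length: float | None = None,
) -> VelocityField4D:
    """Sample an analytic velocity callable onto a grid as a VelocityField4D."""
    nx, ny, nz = grid.shape
    pts = grid.points()
    nt = len(grid.time_points)
    velocity = np.empty((nt, nz, ny, nx, 3))
    for ti, t in enumerate(grid.time_points):
        velocity[ti] = velocity_fn(pts, float(t)).reshape(nz, ny, nx, 3)
    return VelocityField4D(
        velocity=velocity,
        grid_spacing=np.asarray(grid.spacing, dtype=float),
        grid_origin=np.asarray(grid.origin, dtype=float),
        time_points=grid.time_points,
        venc=venc,
        cycle_length=cycle_length,
    )


# ---------------------------------------------------------------------------
# noise and wrap injection
# ---------------------------------------------------------------------------


def inject_noise(
    field: VelocityField4D, sigma_cm_s: float, seed: int | np.random.Generator = 0
) -> VelocityField4D:
    """Add i.i.d. Gaussian noise (per component) from a seeded stream."""
    if sigma_cm_s < 0:
        raise ConfigurationError("noise sigma must be non-negative")
    if sigma_cm_s == 0:
        return field.copy_with(field.velocity.copy())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = field.velocity + rng.normal(0.0, sigma_cm_s, size=field.velocity.shape)
    return field.copy_with(noisy)


def inject_wraps(
    field: VelocityField4D, venc_cm_s: float
) -> tuple[VelocityField4D, np.ndarray]:
    """Apply a single phase wrap: any |v| > venc maps to v - 2 venc sign(v).

    Returns the wrapped field (with ``venc`` recorded on it) and the boolean
    record of affected samples.
    """
    if venc_cm_s <= 0:
        raise ConfigurationError("venc must be positive")
    v = field.velocity.copy()
    wrapped = np.abs(v) > venc_cm_s
    v[wrapped] -= 2.0 * venc_cm_s * np.sign(v[wrapped])
    out = field.copy_with(v)
    out.venc = float(venc_cm_s)
    return out, wrapped


# ---------------------------------------------------------------------------
# kinematic ventricle phantom
# ---------------------------------------------------------------------------


@dataclass
class VentricleParams:
    """Study-scale defaults for the kinematic left-ventricle phantom.

    The cavity is an ellipsoid centered at the origin with its long axis
    along z, scaled isotropically so its volume follows the filling curve.
    End-diastolic values are physiologic for a mid-size LV; the vortex sphere
    is prescribed to contain 53% of the cavity at end-diastole.
    """

    esv_ml: float = 70.0  # cavity volume at end-systole
    edv_ml: float = 150.0  # cavity volume at end-diastole
    semi_axes_ed_mm: tuple[float, float, float] = (28.5, 28.5, 44.2)
    e_window_ms: tuple[float, float] = (350.0, 650.0)  # early rapid filling
    a_window_ms: tuple[float, float] = (800.0, 950.0)  # atrial contraction
    e_fraction: float = 0.7  # share of the filling volume carried by the E wave
    vortex_fraction_ed: float = 0.53  # prescribed end-diastolic VV% / 100
    swirl_rad_s: float = 4.5
    orifice_diameter_mm: float = 27.0
    orifice_z_mm: float = 46.0
    jet_length_mm: float = 22.0
    slice_thickness_mm: float = 8.0
    venc_cm_s: float = 100.0

    def __post_init__(self):
        if not (0 < self.esv_ml < self.edv_ml):
            raise ConfigurationError("need 0 < ESV < EDV")
        if not (0 < self.vortex_fraction_ed < 1):
            raise ConfigurationError("vortex fraction must be in (0, 1)")
        axes_vol = 4.0 / 3.0 * np.pi * np.prod(self.semi_axes_ed_mm) / 1000.0
        if abs(axes_vol - self.edv_ml) > 0.05 * self.edv_ml:
            raise ConfigurationError(
                f"semi-axes volume {axes_vol:.1f} ml inconsistent with EDV {self.edv_ml} ml"
            )
        # the vortex sphere must fit inside the end-diastolic cavity
        a_ed = self.vortex_radius_ed_mm
        if a_ed > min(self.semi_axes_ed_mm):
            raise ConfigurationError(
                f"vortex sphere radius {a_ed:.1f} mm exceeds the smallest semi-axis"
            )

    @property
    def vortex_radius_ed_mm(self) -> float:
        v_mm3 = self.vortex_fraction_ed * self.edv_ml * 1000.0
        return float(np.cbrt(3.0 * v_mm3 / (4.0 * np.pi)))

    # -- filling curve ----------------------------------------------------
    def _bump_fraction(self, t_ms: float, window: tuple[float, float]) -> float:
        """Integral (0..1) of the raised-cosine flow bump over ``window``."""
        t0, t1 = window
        if t_ms <= t0:
            return 0.0
        if t_ms >= t1:
            return 1.0
        s = (t_ms - t0) / (t1 - t0)
        return s - np.sin(2.0 * np.pi * s) / (2.0 * np.pi)

    def _bump_rate(self, t_ms: float, window: tuple[float, float]) -> float:
        """d/dt of the bump integral, 1/ms."""
        t0, t1 = window
        if not (t0 < t_ms < t1):
            return 0.0
        s = (t_ms - t0) / (t1 - t0)
        return 2.0 * np.sin(np.pi * s) ** 2 / (t1 - t0)

    def filled_fraction(self, t_ms: float) -> float:
        return self.e_fraction * self._bump_fraction(t_ms, self.e_window_ms) + (
            1.0 - self.e_fraction
        ) * self._bump_fraction(t_ms, self.a_window_ms)

    def filled_fraction_rate(self, t_ms: float) -> float:
        return self.e_fraction * self._bump_rate(t_ms, self.e_window_ms) + (
            1.0 - self.e_fraction
        ) * self._bump_rate(t_ms, self.a_window_ms)

    def cavity_volume_ml(self, t_ms: float) -> float:
        return self.esv_ml + (self.edv_ml - self.esv_ml) * self.filled_fraction(t_ms)

    def inflow_rate_ml_s(self, t_ms: float) -> float:
        return (self.edv_ml - self.esv_ml) * self.filled_fraction_rate(t_ms) * 1000.0

    def semi_axes_mm(self, t_ms: float) -> np.ndarray:
        scale = np.cbrt(self.cavity_volume_ml(t_ms) / self.edv_ml)
        return scale * np.asarray(self.semi_axes_ed_mm)

    def vortex_radius_mm(self, t_ms: float) -> float:
        return self.vortex_radius_ed_mm * np.cbrt(max(self.filled_fraction(t_ms), 0.0))

    @property
    def e_onset_ms(self) -> float:
        """Time at which inflow first exceeds 5% of the E-wave peak (analytic)."""
        s = np.arcsin(np.sqrt(0.05)) / np.pi
        t0, t1 = self.e_window_ms
        return t0 + s * (t1 - t0)

    @property
    def e_volume_ml(self) -> float:
        return self.e_fraction * (self.edv_ml - self.esv_ml)

    # -- velocity field ---------------------------------------------------
    def velocity(self, points: np.ndarray, t_ms: float) -> np.ndarray:
        """Phantom velocity in cm/s: growing swirling vortex + transmitral jet."""
        pts = np.atleast_2d(points).astype(float)
        out = np.zeros_like(pts)

        a = self.vortex_radius_mm(t_ms)
        if a > 1e-6:
            r2 = np.sum(pts**2, axis=1)
            inside = r2 < a**2
            if np.any(inside):
                g = self.filled_fraction(t_ms)
                gdot = self.filled_fraction_rate(t_ms)
                growth = gdot / (3.0 * g) if g > 1e-12 else 0.0  # = (da/dt)/a, 1/ms
                omega = self.swirl_rad_s / 1000.0  # rad/ms
                p = pts[inside]
                # radial growth + rigid swirl about z, in mm/ms -> cm/s (x100)
                out[inside, 0] = 100.0 * (growth * p[:, 0] - omega * p[:, 1])
                out[inside, 1] = 100.0 * (growth * p[:, 1] + omega * p[:, 0])
                out[inside, 2] = 100.0 * growth * p[:, 2]

        q = self.inflow_rate_ml_s(t_ms)
        if q > 0:
            radius = self.orifice_diameter_mm / 2.0
            in_jet = (
                (pts[:, 0] ** 2 + pts[:, 1] ** 2 < radius**2)
                & (pts[:, 2] >= self.orifice_z_mm)
                & (pts[:, 2] <= self.orifice_z_mm + self.jet_length_mm)
            )
            # plug profile: vz (cm/s) carrying q ml/s through pi r^2 mm^2
            vz = -100.0 * q / (np.pi * radius**2)
            out[in_jet, 2] = vz
        return out


def synthetic_ventricle(
    grid: GridSpec | None = None,
    params: VentricleParams | None = None,
    seed: int = 0,
) -> tuple[VelocityField4D, GroundTruth]:
    """Generate the ventricle phantom with full analytic ground truth.

    Raises ``GenerationError`` if the time-integrated orifice inflow and the
    cavity volume change disagree by more than 2% (mass-consistency audit of
    the prescribed curves on the sampled time axis).
    """
    grid = grid or GridSpec.cardiac_default()
    p = params or VentricleParams()
    field = sample_to_field(p.velocity, grid, venc=p.venc_cm_s,
                            cycle_length=float(grid.time_points[-1] - grid.time_points[0]
                                               + np.diff(grid.time_points).mean()))

    times = grid.time_points
    # mass consistency: trapezoidal integral of Q vs Delta V over the cycle
    q = np.array([p.inflow_rate_ml_s(t) for t in times])
    integrated = float(np.trapezoid(q, times / 1000.0))
    delta_v = p.cavity_volume_ml(times[-1]) - p.cavity_volume_ml(times[0])
    if delta_v > 1.0 and abs(integrated - delta_v) > 0.02 * delta_v:
        raise GenerationError(
            f"inflow integral {integrated:.2f} ml vs cavity change {delta_v:.2f} ml "
            "disagree by more than 2%"
        )

    # slice geometry: short-axis planes, 8 mm apart, centered on the cavity
    th = p.slice_thickness_mm
    c_max = p.semi_axes_ed_mm[2]
    n_half = int(np.floor(c_max / th))
    slice_z = np.arange(-n_half, n_half + 1) * th

    endo = ContourSet(label="endocardium", slice_thickness=th)
    vortex = ContourSet(label="lcs", slice_thickness=th)
    lv_vol, vv_vol = {}, {}
    for tf, t in enumerate(times):
        ax, ay, az = p.semi_axes_mm(t)
        a = p.vortex_radius_mm(t)
        lv_vol[tf] = p.cavity_volume_ml(t)
        vv_vol[tf] = 4.0 / 3.0 * np.pi * a**3 / 1000.0
        for sl, z in enumerate(slice_z):
            if abs(z) < az:
                shrink = np.sqrt(1.0 - (z / az) ** 2)
                endo.add(tf, sl, geometry.ellipse_polygon((0, 0), ax * shrink, ay * shrink, z))
            if a > 1e-6 and abs(z) < a:
                r = np.sqrt(a**2 - z**2)
                if r > 0.5:
                    vortex.add(tf, sl, geometry.circle_polygon((0, 0), r, z))

    lv = pd.Series(lv_vol).sort_index()
    vv = pd.Series(vv_vol).sort_index()
    r_lv = np.cbrt(3.0 * lv * 1000.0 / (4.0 * np.pi))
    r_vv = np.cbrt(3.0 * vv * 1000.0 / (4.0 * np.pi))

    # stationary tissue: outside a 15%-inflated end-diastolic cavity and clear
    # of the jet column
    pts = grid.points()
    axes = np.asarray(p.semi_axes_ed_mm) * 1.15
    in_cavity = np.sum((pts / axes) ** 2, axis=1) < 1.0
    near_jet = (pts[:, 0] ** 2 + pts[:, 1] ** 2 < (p.orifice_diameter_mm / 2 + 6.0) ** 2) & (
        pts[:, 2] > p.orifice_z_mm - 6.0
    )
    nx, ny, nz = grid.shape
    mask = (~in_cavity & ~near_jet).reshape(nz, ny, nx)

    inflow = pd.DataFrame(
        {
            "timeframe": np.arange(len(times)),
            "time_ms": times,
            "flow_ml_s": q,
        }
    )
    truth = GroundTruth(
        velocity_fn=p.velocity,
        params={"ventricle": p},
        endo_contours=endo,
        vortex_contours=vortex,
        lv_volume_ml=lv,
        vortex_volume_ml=vv,
        vv_percent=100.0 * vv / lv,
        wall_distance_mm=r_lv - r_vv,
        inflow_rate=inflow,
        inflow_volume_ml=p.e_volume_ml,
        mitral_diameter_mm=p.orifice_diameter_mm,
        e_onset_ms=p.e_onset_ms,
        boundary_radius_mm=p.vortex_radius_mm,
        stationary_mask=StationaryTissueMask(mask),
        seed=seed,
    )
    return field, truth


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def generate_field(spec: SyntheticFlowSpec) -> tuple[VelocityField4D, GroundTruth]:
    """Sample the requested model onto the grid, with optional noise and wraps.

    The same seed always produces a bit-identical dataset.
    """
    if spec.model == "synthetic_ventricle":
        vp = spec.params.get("ventricle") or VentricleParams(
            **{k: v for k, v in spec.params.items() if k != "ventricle"}
        )
        field, truth = synthetic_ventricle(spec.grid, vp, seed=spec.seed)
    else:
        fn = _ANALYTIC_MODELS[spec.model]
        params = dict(spec.params)

        def velocity_fn(points, t_ms, _fn=fn, _params=params):
            return _fn(points, t_ms, **_params)

        field = sample_to_field(velocity_fn, spec.grid, venc=spec.venc)
        truth = GroundTruth(velocity_fn=velocity_fn, params=params, seed=spec.seed)

    if spec.noise_sigma > 0:
        field = inject_noise(field, spec.noise_sigma, seed=spec.seed)
    if spec.wrap_inject:
        field, wrapped = inject_wraps(field, spec.venc)
        truth.wrapped_voxels = wrapped
    elif spec.venc is not None:
        field.venc = spec.venc
    return field, truth
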