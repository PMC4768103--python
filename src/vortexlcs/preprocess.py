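"""Velocity-field preprocessing: background-phase correction, VENC unwrapping,
and space-time linear interpolation.

Phase-contrast velocity maps carry two characteristic artifacts. Eddy currents
produce a slowly varying background offset, modeled here (per timeframe and
component) as a first-order polynomial in world coordinates fitted to
stationary tissue and subtracted everywhere. Velocities beyond the encoding
limit VENC alias by multiples of 2*VENC; unwrapping shifts voxels that
disagree with a local reference by more than VENC back toward it.

"Linear upsampling in time and space" is realized as on-demand trilinear +
linear-in-time interpolation (``VelocityInterpolator``) rather than
materialized upsampled volumes: the values are identical and the upsampling
factor becomes irrelevant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase

from .exceptions import ConfigurationError, DomainError, FitError
from .flow_io import StationaryTissueMask, VelocityField4D

__all__ = [
    "BackgroundModel",
    "correct_background_phase",
    "unwrap_velocity",
    "VelocityInterpolator",
    "sample_velocity",
    "stationary_mask_from_temporal_std",
]


# ---------------------------------------------------------------------------
# background phase correction
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    """First-order background-phase model, per timeframe and velocity component.

    Coefficients (c0, cx, cy, cz) are expressed in world coordinates *centered
    on the fitted-voxel centroid* (units cm/s and cm/s/mm); centering
    conditions the least-squares system. ``world_coefficients`` converts to
    the uncentered frame.
    """

    coefficients: np.ndarray  # (nt, 3, 4)
    centroid: np.ndarray  # (3,) world mm
    residual_rms: np.ndarray  # (nt, 3) cm/s

    def __post_init__(self):
        if not np.all(np.isfinite(self.coefficients)):
            raise FitError("background model has non-finite coefficients")
        if np.any(self.residual_rms < 0):
            raise FitError("residual RMS must be non-negative")

    def world_coefficients(self) -> np.ndarray:
        """Coefficients (c0, cx, cy, cz) with respect to uncentered world mm."""
        out = self.coefficients.copy()
        out[..., 0] -= out[..., 1:] @ self.centroid
        return out

    def evaluate(self, points: np.ndarray, timeframe: int, component: int) -> np.ndarray:
        """Background velocity (cm/s) at world points (N, 3)."""
        c = self.coefficients[timeframe, component]
        d = np.asarray(points, dtype=float) - self.centroid
        return c[0] + d @ c[1:]


def _world_coordinate_grids(field: VelocityField4D):
    x = field.axis_coordinates(0)
    y = field.axis_coordinates(1)
    z = field.axis_coordinates(2)
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    return X, Y, Z


def correct_background_phase(
    field: VelocityField4D, mask: StationaryTissueMask
) -> tuple[VelocityField4D, BackgroundModel]:
    """Subtract a first-order polynomial fitted to stationary-tissue voxels.

    For each timeframe and component a plane ``c0 + cx*x + cy*y + cz*z`` is
    fitted by least squares over the masked voxels and subtracted from the
    whole volume, so the corrected masked-voxel mean is ~0. The operation is
    idempotent up to floating-point noise.
    """
    mask.validate_against(field)
    X, Y, Z = _world_coordinate_grids(field)
    m = mask.mask
    centroid = np.array([X[m].mean(), Y[m].mean(), Z[m].mean()])
    design = np.column_stack(
        [np.ones(int(m.sum())), X[m] - centroid[0], Y[m] - centroid[1], Z[m] - centroid[2]]
    )
    if np.linalg.matrix_rank(design) < 4:
        raise FitError(
            "stationary-mask geometry is degenerate (collinear voxels); "
            "the first-order fit is rank deficient"
        )
    full = np.stack([np.ones_like(X), X - centroid[0], Y - centroid[1], Z - centroid[2]], axis=-1)

    nt = field.n_timeframes
    coeffs = np.empty((nt, 3, 4))
    residual_rms = np.empty((nt, 3))
    corrected = field.velocity.copy()
    for t in range(nt):
        for c in range(3):
            values = field.velocity[t, ..., c][m]
            sol, *_ = np.linalg.lstsq(design, values, rcond=None)
            coeffs[t, c] = sol
            residual_rms[t, c] = float(np.sqrt(np.mean((values - design @ sol) ** 2)))
            corrected[t, ..., c] -= full @ sol
    model = BackgroundModel(coefficients=coeffs, centroid=centroid, residual_rms=residual_rms)
    return field.copy_with(corrected), model


# ---------------------------------------------------------------------------
# VENC unwrapping
# ---------------------------------------------------------------------------


def unwrap_velocity(
    field: VelocityField4D,
    max_iters: int = 50,
    neighborhood: int = 3,
    manual_overrides: list[dict] | None = None,
) -> tuple[VelocityField4D, int]:
    """Correct velocity aliasing by shifting wrapped voxels by multiples of 2*VENC.

    A velocity component map is the scaled phase of the acquisition: v maps to
    phi = pi v / VENC and aliasing wraps phi modulo 2 pi, i.e. v modulo
    2 VENC. Each timeframe/component volume is unwrapped spatially with the
    reliability-sorted 3-D phase unwrapper, then re-anchored to the dominant
    branch (the median wrap count is taken as zero, assuming most voxels are
    unaliased). A temporal pass follows: voxels still differing from the mean
    of their (already spatially unwrapped) neighbouring timeframes by more
    than VENC are shifted by +-2 VENC toward it, iterated to a fixed point
    with an iteration cap.

    ``manual_overrides`` is the declarative stand-in for the interactive part
    of semiautomatic unwrapping: entries
    ``{"timeframe": t, "voxel": [iz, iy, ix], "component": c, "wraps": k}``
    add ``k * 2 * venc`` to the stated voxel after the automatic passes (the
    operator has the final say).

    Returns the unwrapped field and the total number of voxel changes applied.
    """
    if field.venc is None:
        raise ConfigurationError("unwrap_velocity requires the field's venc to be set")
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ConfigurationError("neighborhood must be an odd integer >= 3")
    venc = float(field.venc)
    v = field.velocity.copy()
    n_changed = 0

    for t in range(field.n_timeframes):
        for c in range(3):
            vol = v[t, ..., c]
            phase = vol * (np.pi / venc)
            unwrapped = np.asarray(unwrap_phase(phase)) * (venc / np.pi)
            wraps = np.round((unwrapped - vol) / (2.0 * venc))
            wraps -= np.round(np.median(wraps))  # anchor: most voxels unaliased
            if np.any(wraps):
                vol += 2.0 * venc * wraps
                n_changed += int(np.count_nonzero(wraps))

    converged = False
    for _ in range(max_iters):
        changed_temporal = 0
        for t in range(field.n_timeframes):
            neigh = [v[s] for s in (t - 1, t + 1) if 0 <= s < field.n_timeframes]
            ref_t = np.mean(neigh, axis=0)
            for c in range(3):
                vol = v[t, ..., c]
                shift = np.zeros_like(vol)
                shift[vol - ref_t[..., c] > venc] = -2.0 * venc
                shift[vol - ref_t[..., c] < -venc] = 2.0 * venc
                if np.any(shift):
                    vol += shift
                    changed_temporal += int(np.count_nonzero(shift))
        n_changed += changed_temporal
        if changed_temporal == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            "unwrap_velocity did not reach a fixed point within "
            f"{max_iters} iterations; result is partial",
            RuntimeWarning,
            stacklevel=2,
        )

    for entry in manual_overrides or []:
        t = int(entry["timeframe"])
        iz, iy, ix = (int(i) for i in entry["voxel"])
        comp = int(entry.get("component", 2))
        v[t, iz, iy, ix, comp] += 2.0 * venc * int(entry["wraps"])
        n_changed += 1
    return field.copy_with(v), n_changed


# ---------------------------------------------------------------------------
# space-time interpolation
# ---------------------------------------------------------------------------


class VelocityInterpolator:
    """Trilinear-in-space, linear-in-time velocity sampler, vectorized over points.

    Outside the spatial grid the velocity is the zero vector and the
    out-of-domain flag is set (the particle is effectively frozen, which is
    detectable downstream). Times outside the acquired span raise
    ``DomainError``.
    """

    def __init__(self, field: VelocityField4D):
        self.field = field
        self._origin = field.grid_origin
        self._spacing = field.grid_spacing
        self._nxyz = np.array(field.shape_xyz)
        self._times = field.time_points

    def __call__(self, points: np.ndarray, time_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """Sample velocities (cm/s) at world points (N, 3) and a scalar time (ms).

        Returns ``(velocities (N, 3), out_of_domain (N,))``.
        """
        t = float(time_ms)
        times = self._times
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise DomainError(
                f"time {t} ms outside acquired span [{times[0]}, {times[-1]}] ms"
            )
        t = min(max(t, times[0]), times[-1])
        hi = int(np.searchsorted(times, t, side="right"))
        hi = min(max(hi, 1), len(times) - 1)
        lo = hi - 1
        wt = (t - times[lo]) / (times[hi] - times[lo])

        pts = np.atleast_2d(np.asarray(points, dtype=float))
        f = (pts - self._origin) / self._spacing  # fractional voxel coords (x, y, z)
        out = np.any((f < 0) | (f > self._nxyz - 1), axis=1)
        f = np.clip(f, 0.0, self._nxyz - 1)
        i0 = np.minimum(f.astype(int), self._nxyz - 2)
        d = f - i0

        vel = self.field.velocity
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        dx, dy, dz = d[:, 0, None], d[:, 1, None], d[:, 2, None]

        def gather(tf):
            v = vel[tf]
            c000 = v[iz, iy, ix]
            c100 = v[iz, iy, ix + 1]
            c010 = v[iz, iy + 1, ix]
            c110 = v[iz, iy + 1, ix + 1]
            c001 = v[iz + 1, iy, ix]
            c101 = v[iz + 1, iy, ix + 1]
            c011 = v[iz + 1, iy + 1, ix]
            c111 = v[iz + 1, iy + 1, ix + 1]
            c00 = c000 * (1 - dx) + c100 * dx
            c01 = c001 * (1 - dx) + c101 * dx
            c10 = c010 * (1 - dx) + c110 * dx
            c11 = c011 * (1 - dx) + c111 * dx
            c0 = c00 * (1 - dy) + c10 * dy
            c1 = c01 * (1 - dy) + c11 * dy
            return c0 * (1 - dz) + c1 * dz

        if wt == 0.0:
            result = gather(lo)
        elif wt == 1.0:
            result = gather(hi)
        else:
            result = gather(lo) * (1 - wt) + gather(hi) * wt
        result[out] = 0.0
        return result, out


def sample_velocity(
    field: VelocityField4D, position: np.ndarray, time_ms: float
) -> tuple[np.ndarray, bool]:
    """Velocity (cm/s) at a single world position (mm) and time (ms)."""
    vel, out = VelocityInterpolator(field)(np.asarray(position, float).reshape(1, 3), time_ms)
    return vel[0], bool(out[0])


# ---------------------------------------------------------------------------
# convenience mask builder
# ---------------------------------------------------------------------------


def stationary_mask_from_temporal_std(
    field: VelocityField4D, threshold_cm_s: float = 2.0
) -> StationaryTissueMask:
    """Threshold the temporal standard deviation of speed to find still voxels.

    Convenience helper only: stationary-tissue masks are normally supplied as
    input (drawn on anatomy); this is a rough automatic stand-in.
    """
    speed = np.linalg.norm(field.velocity, axis=-1)
    std = speed.std(axis=0)
    mean = speed.mean(axis=0)
    return StationaryTissueMask((std < threshold_cm_s) & (mean < threshold_cm_s))
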