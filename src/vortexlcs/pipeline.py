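"""End-to-end orchestration: synth -> preprocess -> ftle -> metrics -> stats.

Every stage writes plain files (HDF5 field, contour CSV, metrics CSV) so any
intermediate can be inspected or hand-edited and the run resumed — the
file-based analogue of the semi-manual clinical workflow. A manifest (config
copy, seed, package version, output hashes) plus a human-readable log make
each run reproducible: identical config and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, metrics as metrics_mod, stats as stats_mod
from .exceptions import ConfigurationError, VortexLCSError
from .flow_io import (
    ContourSet,
    StationaryTissueMask,
    VelocityField4D,
    read_contours,
    read_velocity_field,
    write_contours,
    write_mask,
    write_velocity_field,
)
from .geometry import circle_polygon
from .lcs_core import SeedingPlane, crop_to_endocardium, lcs_contours
from .preprocess import correct_background_phase, unwrap_velocity
from .synthetic_data import GridSpec, SyntheticFlowSpec, generate_field

logger = logging.getLogger("vortexlcs")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the published analysis settings.

    Seed spacing 0.8 mm, RK4 step 5 ms, 95th-percentile normalization with a
    50% threshold, alpha 0.05 over a 32-test battery.
    """

    stages: list[str] = dataclass_field(
        default_factory=lambda: ["synth", "preprocess", "ftle", "metrics", "stats"]
    )
    # synth
    model: str = "synthetic_ventricle"
    seed: int = 0
    noise_sigma_cm_s: float = 0.0
    wrap_inject: bool = False
    # preprocess
    venc_cm_s: float | None = None
    background_enabled: bool = True
    unwrap_max_iters: int = 50
    unwrap_neighborhood: int = 3
    manual_unwrap_overrides: list = dataclass_field(default_factory=list)
    # lcs
    seed_spacing_mm: float = 0.8
    step_ms: float = 5.0
    percentile: float = 95.0
    threshold_fraction: float = 0.5
    min_area_mm2: float = 30.0
    t_origin_ms: float | None = None  # None = auto-detect E-wave onset
    # metrics
    flow_threshold_cm_s: float = 10.0
    # stats
    alpha: float = 0.05
    n_tests: int = 32
    # inputs (used when the synth stage is disabled)
    field_path: str | None = None
    endo_contours_path: str | None = None
    metrics_per_subject_path: str | None = None
    subject_id: str = "synthetic-01"
    group: str = "control"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _detect_t_origin(field: VelocityField4D, orifice_z: float, orifice_radius: float):
    """E-wave onset from the transmitral through-plane flow profile."""
    z = field.axis_coordinates(2)
    jet_slices = np.where(z >= orifice_z + 1.0)[0]
    if len(jet_slices) == 0:
        raise VortexLCSError("no slice above the orifice plane for flow profiling")
    sl = int(jet_slices[0])
    roi = circle_polygon((0.0, 0.0), orifice_radius + 5.0, z[sl])
    profile = metrics_mod.through_plane_flow_profile(field, sl, roi, normal_sign=-1)
    timing = metrics_mod.detect_e_wave(profile)
    return timing, profile, sl


def _endo_planes(endo: ContourSet, margin: float = 6.0):
    """One fixed seeding window per slice, covering the endocardium over time."""
    bounds: dict[int, list[float]] = {}
    zs: dict[int, float] = {}
    for (_tf, sl), polys in endo.contours.items():
        for poly in polys:
            b = bounds.setdefault(sl, [np.inf, -np.inf, np.inf, -np.inf])
            b[0] = min(b[0], poly[:, 0].min())
            b[1] = max(b[1], poly[:, 0].max())
            b[2] = min(b[2], poly[:, 1].min())
            b[3] = max(b[3], poly[:, 1].max())
            zs[sl] = float(poly[:, 2].mean())
    planes = []
    for sl in sorted(bounds):
        x0, x1, y0, y1 = bounds[sl]
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
        half = 0.5 * max(x1 - x0, y1 - y0) + margin
        planes.append((sl, SeedingPlane.short_axis((cx, cy), zs[sl], half)))
    return planes


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Any stage failure raises with a stage-tagged message; outputs written so
    far are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    outputs: dict[str, Path] = {}
    field: VelocityField4D | None = None
    endo: ContourSet | None = None
    mask: StationaryTissueMask | None = None
    truth = None
    stage = "init"
    try:
        if "synth" in config.stages:
            stage = "synth"
            logger.info("synth: model=%s seed=%d", config.model, config.seed)
            spec = SyntheticFlowSpec(
                model=config.model,
                grid=GridSpec.cardiac_default(),
                noise_sigma=config.noise_sigma_cm_s,
                venc=config.venc_cm_s,
                wrap_inject=config.wrap_inject,
                seed=config.seed,
            )
            field, truth = generate_field(spec)
            outputs["field"] = write_velocity_field(field, out / "field.h5")
            if truth.endo_contours is not None:
                endo = truth.endo_contours
                outputs["endo_contours"] = write_contours(endo, out / "endo_contours.csv")
            if truth.stationary_mask is not None:
                mask = truth.stationary_mask
                outputs["stationary_mask"] = write_mask(mask, out / "stationary_mask.h5")
        else:
            stage = "load"
            if config.field_path is None:
                raise ConfigurationError("synth disabled and no field_path given")
            field = read_velocity_field(config.field_path)
            if config.endo_contours_path:
                endo = read_contours(config.endo_contours_path)

        if "preprocess" in config.stages:
            stage = "preprocess"
            if config.background_enabled and mask is not None:
                field, model = correct_background_phase(field, mask)
                logger.info(
                    "preprocess: background removed, max residual RMS %.3g cm/s",
                    float(model.residual_rms.max()),
                )
            if (field.venc or config.venc_cm_s) is not None:
                if field.venc is None:
                    field.venc = config.venc_cm_s
                field, n_changed = unwrap_velocity(
                    field,
                    max_iters=config.unwrap_max_iters,
                    neighborhood=config.unwrap_neighborhood,
                    manual_overrides=config.manual_unwrap_overrides,
                )
                logger.info("preprocess: unwrapped %d voxel values", n_changed)
            outputs["field_preprocessed"] = write_velocity_field(
                field, out / "field_preprocessed.h5"
            )

        timing = profile = None
        lcs_cropped: ContourSet | None = None
        if "ftle" in config.stages:
            stage = "ftle"
            if endo is None:
                raise ConfigurationError("ftle stage requires endocardial contours")
            orifice_z, orifice_r = 46.0, 13.5
            if truth is not None and truth.mitral_diameter_mm:
                orifice_r = truth.mitral_diameter_mm / 2.0
            timing, profile, _ = _detect_t_origin(field, orifice_z, orifice_r)
            t_origin = (
                config.t_origin_ms if config.t_origin_ms is not None else timing.onset_time_ms
            )
            logger.info("ftle: t_origin=%.1f ms (E onset)", t_origin)
            timeframes = [
                tf for tf, t in enumerate(field.time_points) if t > t_origin
            ]
            planes = _endo_planes(endo)
            logger.info(
                "ftle: %d timeframes x %d slices, spacing %.2f mm, step %.1f ms",
                len(timeframes), len(planes), config.seed_spacing_mm, config.step_ms,
            )
            lcs = lcs_contours(
                field,
                planes,
                timeframes,
                t_origin,
                spacing=config.seed_spacing_mm,
                step=config.step_ms,
                threshold_fraction=config.threshold_fraction,
                percentile=config.percentile,
                min_area_mm2=config.min_area_mm2,
                slice_thickness=endo.slice_thickness,
            )
            outputs["lcs_contours"] = write_contours(lcs, out / "lcs_contours.csv")
            lcs_cropped = crop_to_endocardium(lcs, endo)
            outputs["lcs_contours_cropped"] = write_contours(
                lcs_cropped, out / "lcs_contours_cropped.csv"
            )

        if "metrics" in config.stages:
            stage = "metrics"
            if endo is None or lcs_cropped is None:
                raise ConfigurationError("metrics stage requires endo and LCS contours")
            lv = metrics_mod.slice_summation_volume(endo)
            vv = metrics_mod.slice_summation_volume(lcs_cropped)
            time_ms = {tf: float(t) for tf, t in enumerate(field.time_points)}
            mitral_area = mitral_d = e_peak = inflow_vol = None
            if profile is not None and timing is not None:
                e_peak = timing.peak_velocity_cm_s
                flow = profile["flow_ml_s"].to_numpy()
                t_s = profile["time_ms"].to_numpy() / 1000.0
                i0 = timing.onset_timeframe
                i1 = timing.peak_timeframe
                while i1 + 1 < len(flow) and flow[i1 + 1] > 0.05 * timing.peak_flow_ml_s:
                    i1 += 1
                inflow_vol = float(np.trapezoid(flow[i0 : i1 + 1], t_s[i0 : i1 + 1]))
                z = field.axis_coordinates(2)
                jet_slices = [int(s) for s in np.where((z >= 47.0) & (z <= 60.0))[0]][:3]
                rois = {
                    sl: circle_polygon((0, 0), 13.5 + 5.0, z[sl]) for sl in jet_slices
                }
                try:
                    mitral_area, mitral_d, _, _ = metrics_mod.mitral_effective_diameter(
                        field,
                        jet_slices,
                        rois,
                        speed_threshold_cm_s=config.flow_threshold_cm_s,
                        normal_sign=-1,
                    )
                except VortexLCSError as e:
                    logger.warning("metrics: mitral measurement failed (%s)", e)
            table = metrics_mod.build_metrics_table(
                config.subject_id,
                config.group,
                lv,
                vv,
                time_ms,
                mitral_area_mm2=mitral_area,
                mitral_diameter_mm=mitral_d,
                lcs=lcs_cropped,
                inflow_volume_ml=inflow_vol,
                e_peak_velocity_cm_s=e_peak,
            )
            table.write(out / "metrics_per_timeframe.csv", out / "metrics_per_subject.csv")
            outputs["metrics_per_timeframe"] = out / "metrics_per_timeframe.csv"
            outputs["metrics_per_subject"] = out / "metrics_per_subject.csv"

        if "stats" in config.stages:
            stage = "stats"
            if config.metrics_per_subject_path:
                cohort = pd.read_csv(config.metrics_per_subject_path)
                report = stats_mod.correlation_battery(
                    cohort, alpha=config.alpha, n_tests=config.n_tests
                )
                report.comparisons.to_csv(out / "stats_report.csv", index=False)
                outputs["stats_report"] = out / "stats_report.csv"
                logger.info(
                    "stats: %d correlations, Bonferroni threshold %.7g",
                    len(report.comparisons), report.threshold,
                )
            else:
                logger.info("stats: no cohort table supplied; stage skipped")

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs": {k: {"path": p.name, "sha256": _sha256(p)} for k, p in outputs.items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        config.to_yaml(out / "config.yaml")
        logger.info("run complete: %d outputs", len(outputs))
    except VortexLCSError as e:
        logger.error("stage %s failed: %s", stage, e)
        raise VortexLCSError(f"[stage {stage}] {e}") from e
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
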