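"""Pose-sweep experiments: control vs optimized plans over distances/angles.

For every (distance, angle) pose the panel is placed along the lesion's
average normal, swung about the vertical axis through the lesion centre,
and two plans are evaluated on every lesion point:

* control — all units at the same intensity, the largest uniform drive
  keeping the maximum point irradiance at or below the top of the band;
* optimized — bounded least-squares intensities prescribing the target
  irradiance at the cluster centres.

The result is one tidy row per pose with both plans' statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .array_model import LEDArray, LEDSpec, illumination_matrix, pose_from_lesion, rotate_array
from .clustering import cluster_cloud
from .cloud import PointCloud
from .metrics import evaluate_field
from .optimizer import Prescription, evaluate_plan, solve_intensities, uniform_control_intensity

__all__ = ["RunConfig", "run_scenario", "plan_pose"]

log = logging.getLogger("pdtplan")

#: pose grid of the robustness study: five standoffs at normal incidence
#: plus four azimuthal swings at the nominal 100 mm standoff
DEFAULT_DISTANCES_MM = (120.0, 110.0, 100.0, 90.0, 80.0)
DEFAULT_ANGLES_DEG = (-10.0, -5.0, 5.0, 10.0)
DEFAULT_ANGLE_DISTANCE_MM = 100.0


@dataclass
class RunConfig:
    """Everything one pose-sweep run needs."""

    distances_mm: tuple = DEFAULT_DISTANCES_MM
    angles_deg: tuple = DEFAULT_ANGLES_DEG
    angle_distance_mm: float = DEFAULT_ANGLE_DISTANCE_MM
    max_clusters: int = 50
    prescription: Prescription = dc_field(default_factory=Prescription)
    rows: int = 15
    cols: int = 15
    pitch_mm: float = 10.0
    psi_deg: float = 15.0
    i0_min: float = 0.0
    i0_max: float = 750.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.distances_mm) + len(self.angles_deg) == 0:
            raise ValueError("the pose sweep is empty")

    def poses(self) -> list[tuple[float, float]]:
        out = [(float(d), 0.0) for d in self.distances_mm]
        out += [(float(self.angle_distance_mm), float(a)) for a in self.angles_deg]
        return out

    def make_array(self) -> LEDArray:
        spec = LEDSpec(psi_deg=self.psi_deg, ls=self.i0_min, hs=self.i0_max)
        return LEDArray.grid(self.rows, self.cols, self.pitch_mm, spec=spec)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        presc = raw.pop("prescription", None)
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        if presc:
            cfg.prescription = Prescription(**presc)
        return cfg


def plan_pose(
    array: LEDArray,
    cloud: PointCloud,
    assignment,
    distance_mm: float,
    angle_deg: float,
    prescription: Prescription,
) -> dict:
    """Control and optimized evaluation of one panel pose."""
    posed = pose_from_lesion(array, cloud, distance_cm=distance_mm / 10.0)
    if angle_deg != 0.0:
        posed = rotate_array(posed, angle_deg, cloud.centroid)
    full = illumination_matrix(posed, cloud)
    centers = assignment.center_cloud(frame=cloud.frame)
    center_matrix = illumination_matrix(posed, centers)

    u = uniform_control_intensity(full, band_high=prescription.band_high, ls=array.spec.ls, hs=array.spec.hs)
    control_field = evaluate_plan(posed.with_intensities(u), cloud, matrix=full)
    control = evaluate_field(control_field, prescription.band)

    sol = solve_intensities(center_matrix, prescription, ls=array.spec.ls, hs=array.spec.hs)
    opt_field = evaluate_plan(posed.with_intensities(sol.i0), cloud, matrix=full)
    optimized = evaluate_field(opt_field, prescription.band)

    return {
        "distance_mm": distance_mm,
        "angle_deg": angle_deg,
        "n_points": control.n_points,
        "control_i0_mw_sr": u,
        "control_n_effective": control.n_effective,
        "control_proportion_pct": round(control.effective_proportion, 2),
        "control_cv_pct": round(control.cv, 2),
        "optimized_n_effective": optimized.n_effective,
        "optimized_proportion_pct": round(optimized.effective_proportion, 2),
        "optimized_cv_pct": round(optimized.cv, 2),
        "residual_norm": sol.residual_norm,
        "n_active_bounds": int(sol.active_bounds.size),
        "i0": sol.i0,
    }


def run_scenario(config: RunConfig, cloud: PointCloud) -> pd.DataFrame:
    """Evaluate the full pose grid on one lesion cloud.

    Clustering is pose-independent and done once.  Deterministic for a
    fixed config seed.
    """
    array = config.make_array()
    assignment = cluster_cloud(cloud, max_clusters=config.max_clusters, seed=config.seed)
    log.info("scenario: %d points, %d clusters, %d poses", len(cloud), assignment.n_clusters, len(config.poses()))
    rows = []
    for distance_mm, angle_deg in config.poses():
        try:
            row = plan_pose(array, cloud, assignment, distance_mm, angle_deg, config.prescription)
        except Exception:
            log.exception("pose (%.0f mm, %.0f deg) failed", distance_mm, angle_deg)
            raise
        log.info(
            "pose %.0f mm / %+.0f deg: control %.2f%% / CV %.2f%%, optimized %.2f%% / CV %.2f%%",
            distance_mm, angle_deg,
            row["control_proportion_pct"], row["control_cv_pct"],
            row["optimized_proportion_pct"], row["optimized_cv_pct"],
        )
        rows.append({k: v for k, v in row.items() if k != "i0"})
    return pd.DataFrame(rows)
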