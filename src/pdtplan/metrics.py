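"""Evaluation statistics of an irradiance field.

Two figures of merit summarise dose quality over a lesion cloud:

* effective proportion — the percentage of points whose irradiance lies
  inside the prescribed band (inclusive endpoints), and
* coefficient of variation (CV) — 100 * population standard deviation /
  mean of the per-point irradiance, the uniformity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .array_model import IrradianceField

__all__ = ["EvaluationReport", "effective_proportion", "coefficient_of_variation", "evaluate_field", "compare_plans"]


def _values(field) -> np.ndarray:
    v = field.values if isinstance(field, IrradianceField) else np.asarray(field, dtype=float)
    if v.size == 0:
        raise ValueError("empty irradiance field")
    return v


@dataclass
class EvaluationReport:
    """Summary of one irradiance field against a prescription band."""

    n_points: int
    n_effective: int
    effective_proportion: float  # percent
    cv: float  # percent
    band: tuple[float, float]
    mean: float
    sd: float
    cloud_id: int | None = None

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "n_effective": self.n_effective,
            "effective_proportion_pct": round(self.effective_proportion, 2),
            "cv_pct": round(self.cv, 2),
            "band_low": self.band[0],
            "band_high": self.band[1],
            "mean_mw_cm2": self.mean,
            "sd_mw_cm2": self.sd,
        }


def effective_proportion(field, band: tuple[float, float]) -> tuple[int, float]:
    """Count and percentage of points inside the closed band [low, high]."""
    low, high = band
    if not low < high:
        raise ValueError("band_low must be below band_high")
    v = _values(field)
    count = int(np.count_nonzero((v >= low) & (v <= high)))
    return count, 100.0 * count / v.size


def coefficient_of_variation(field) -> float:
    """100 * population standard deviation / mean of the field values."""
    v = _values(field)
    mean = v.mean()
    if mean <= 0:
        raise ValueError("coefficient of variation undefined for non-positive mean")
    return 100.0 * v.std() / mean


def evaluate_field(field, band: tuple[float, float] = (90.0, 110.0)) -> EvaluationReport:
    """Full report for one field."""
    v = _values(field)
    count, pct = effective_proportion(v, band)
    cloud = getattr(field, "cloud_ref", None)
    return EvaluationReport(
        n_points=int(v.size),
        n_effective=count,
        effective_proportion=pct,
        cv=coefficient_of_variation(v),
        band=(float(band[0]), float(band[1])),
        mean=float(v.mean()),
        sd=float(v.std()),
        cloud_id=None if cloud is None else id(cloud),
    )


def compare_plans(before: EvaluationReport, after: EvaluationReport) -> dict:
    """Percentage-point changes from a control plan to an optimized plan."""
    if before.n_points != after.n_points or before.band != after.band:
        raise ValueError("reports must evaluate the same cloud and band")
    if before.cloud_id is not None and after.cloud_id is not None and before.cloud_id != after.cloud_id:
        raise ValueError("reports evaluate different clouds")
    return {
        "delta_effective_proportion_pp": after.effective_proportion - before.effective_proportion,
        "delta_cv_pp": after.cv - before.cv,
        "delta_n_effective": after.n_effective - before.n_effective,
    }
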