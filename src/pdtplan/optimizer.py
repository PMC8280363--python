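"""Bounded least-squares solution of the per-LED intensities.

With the illumination matrix A (rows = cluster centres, columns = LED
units) the planner solves

    min_I0  1/2 || A I0 - E~ ||^2     subject to  ls <= I0 <= hs

where E~ is the prescribed irradiance at every centre.  The objective is
linear in I0, so this is a convex bound-constrained linear least-squares
problem with a deterministic global optimum; scipy's BVLS active-set
solver is used.  The returned solution is KKT-checked: the gradient
vanishes on interior coordinates and pushes outward on the ones clipped
at a bound.

The control condition used in comparisons drives every unit at the same
intensity, chosen as the largest uniform value that keeps the maximum
point irradiance at or below the top of the prescription band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .array_model import IlluminationMatrix, IrradianceField, LEDArray, irradiance_field
from .cloud import PointCloud

__all__ = [
    "Prescription",
    "OptimizationResult",
    "solve_intensities",
    "uniform_control_intensity",
    "evaluate_plan",
    "kkt_residuals",
]


@dataclass
class Prescription:
    """Target irradiance and tolerance band, mW/cm^2."""

    e_target: float = 100.0
    band_low: float = 90.0
    band_high: float = 110.0

    def __post_init__(self) -> None:
        if not 0.0 < self.band_low <= self.e_target <= self.band_high:
            raise ValueError("need 0 < band_low <= e_target <= band_high")

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low, self.band_high)


@dataclass
class OptimizationResult:
    """Solved intensities with diagnostics."""

    i0: np.ndarray  # (n_units,), mW/Sr
    residual_norm: float  # 1/2 ||A i0 - target||^2
    center_irradiance: np.ndarray  # (K,), mW/cm^2
    active_lower: np.ndarray  # indices clipped at ls
    active_upper: np.ndarray  # indices clipped at hs
    converged: bool

    @property
    def active_bounds(self) -> np.ndarray:
        return np.union1d(self.active_lower, self.active_upper)


def solve_intensities(
    center_matrix: IlluminationMatrix | np.ndarray,
    prescription: Prescription | float = 100.0,
    ls: float = 0.0,
    hs: float = 750.0,
) -> OptimizationResult:
    """Globally optimal bounded intensities for the prescribed centre irradiance.

    ``prescription`` may be a Prescription, a scalar target broadcast over
    all centres, or a per-centre target vector.
    """
    a = center_matrix.entries if isinstance(center_matrix, IlluminationMatrix) else np.asarray(center_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] < 1:
        raise ValueError("center matrix must be K x n_units with K >= 1")
    if not ls < hs:
        raise ValueError("infeasible bounds: need ls < hs")
    if isinstance(prescription, Prescription):
        target = np.full(a.shape[0], prescription.e_target)
    else:
        target = np.broadcast_to(np.asarray(prescription, dtype=float), (a.shape[0],)).copy()
    dead = ~a.any(axis=1)
    if dead.any():
        warnings.warn(f"unreachable cluster centers (all-zero matrix rows): {np.flatnonzero(dead).tolist()}", stacklevel=2)
    res = lsq_linear(a, target, bounds=(ls, hs), method="bvls", tol=1e-14)
    if res.status <= 0:  # BVLS hit its iteration cap; polish with TRF
        res = lsq_linear(a, target, bounds=(ls, hs), method="trf", tol=1e-14)
    i0 = np.clip(res.x, ls, hs)
    fitted = a @ i0
    tol = 1e-9 * max(1.0, hs - ls)
    return OptimizationResult(
        i0=i0,
        residual_norm=0.5 * float(((fitted - target) ** 2).sum()),
        center_irradiance=fitted,
        active_lower=np.flatnonzero(i0 <= ls + tol),
        active_upper=np.flatnonzero(i0 >= hs - tol),
        converged=bool(res.status > 0),
    )


def kkt_residuals(a: np.ndarray, target: np.ndarray, i0: np.ndarray, ls: float, hs: float, tol: float = 1e-9):
    """First-order optimality violations of a candidate bounded LSQ solution.

    Returns (interior, lower, upper): the largest |gradient| over interior
    coordinates, the most negative gradient at the lower bound and the most
    positive at the upper bound (all ~<= 0 at scale for a true optimum).
    """
    g = a.T @ (a @ i0 - target)
    span = max(1.0, hs - ls)
    at_lo = i0 <= ls + tol * span
    at_hi = i0 >= hs - tol * span
    interior = ~(at_lo | at_hi)
    m_int = float(np.abs(g[interior]).max()) if interior.any() else 0.0
    m_lo = float(np.maximum(-g[at_lo], 0.0).max()) if at_lo.any() else 0.0
    m_hi = float(np.maximum(g[at_hi], 0.0).max()) if at_hi.any() else 0.0
    return m_int, m_lo, m_hi


def uniform_control_intensity(
    full_matrix: IlluminationMatrix | np.ndarray,
    band_high: float = 110.0,
    ls: float = 0.0,
    hs: float = 750.0,
) -> float:
    """Uniform drive of the control condition.

    The largest common intensity such that the maximum per-point irradiance
    does not exceed ``band_high``, clipped into the drivable range.
    """
    a = full_matrix.entries if isinstance(full_matrix, IlluminationMatrix) else np.asarray(full_matrix, dtype=float)
    row_sum_max = a.sum(axis=1).max()
    if row_sum_max <= 0:
        raise ValueError("no point is illuminated; cannot scale a uniform drive")
    return float(np.clip(band_high / row_sum_max, ls, hs))


def evaluate_plan(array: LEDArray, cloud: PointCloud, matrix: IlluminationMatrix | None = None) -> IrradianceField:
    """Full-cloud irradiance under the array's currently set intensities."""
    if np.any(array.i0 < array.spec.ls - 1e-9) or np.any(array.i0 > array.spec.hs + 1e-9):
        raise ValueError("array intensities violate the drive bounds")
    return irradiance_field(array, cloud, matrix=matrix)
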