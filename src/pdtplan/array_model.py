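"""Radiometric forward model of the 15 x 15 LED treatment panel.

Each LED is a generalized Lambertian emitter: its radiant intensity falls
off the optical axis as I(phi) = I0 * cos^m(phi), where the Lambertian
order m = -ln 2 / ln cos(psi) is fixed by the half luminous angle psi (the
off-axis angle at which intensity halves).  The irradiance a surface point
receives from one unit is

    Ep = I0 * cos(theta) * cos^m(phi) / r^2      [mW/cm^2]

with r the LED-to-point distance (cm), theta the angle between the surface
normal and the point-to-LED direction, and phi the off-axis angle at the
LED.  The panel field is the superposition of all units, which is linear
in the per-unit intensities I0 — the basis of the planner's bounded
least-squares step.

Geometry is carried in mm (scanner convention); radiometry divides by 10
internally so intensities in mW/Sr yield irradiance in mW/cm^2.
Back-facing geometry (cos theta <= 0 or cos phi <= 0) contributes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .cloud import PointCloud
from .phantoms import average_normal

__all__ = [
    "LEDSpec",
    "LEDArray",
    "RaySample",
    "IrradianceField",
    "IlluminationMatrix",
    "lambert_exponent",
    "ray_geometry",
    "single_led_irradiance",
    "illumination_matrix",
    "irradiance_field",
    "pose_from_lesion",
    "rotate_array",
]


def lambert_exponent(psi_deg: float) -> float:
    """Lambertian order m = -ln 2 / ln cos(psi) from the half angle psi."""
    if not 0.0 < psi_deg < 90.0:
        raise ValueError("half luminous angle must lie strictly between 0 and 90 degrees")
    return -np.log(2.0) / np.log(np.cos(np.radians(psi_deg)))


@dataclass
class LEDSpec:
    """Emission model and drive limits of one LED unit.

    i0 is the axial radiant intensity (mW/Sr), psi_deg the half luminous
    angle, m the Lambertian order (derived from psi unless given), and
    [ls, hs] the intensity range reachable by the unit's driver.
    """

    i0: float = 372.0
    psi_deg: float = 15.0
    m: float | None = None
    ls: float = 0.0
    hs: float = 750.0

    def __post_init__(self) -> None:
        expected = lambert_exponent(self.psi_deg)
        if self.m is None:
            self.m = expected
        elif abs(self.m - expected) > 1e-9:
            raise ValueError("m is inconsistent with psi_deg (m = -ln2/ln cos psi)")
        if not (0.0 <= self.ls <= self.i0 <= self.hs):
            raise ValueError("intensity bounds must satisfy 0 <= ls <= i0 <= hs")


@dataclass
class RaySample:
    """Geometry of one LED-to-point ray."""

    r_cm: float
    cos_theta: float
    cos_phi: float

    def __post_init__(self) -> None:
        if self.r_cm <= 0:
            raise ValueError("r_cm must be positive")
        if not (-1.0 - 1e-12 <= self.cos_theta <= 1.0 + 1e-12):
            raise ValueError("cos_theta out of [-1, 1]")
        if not (-1.0 - 1e-12 <= self.cos_phi <= 1.0 + 1e-12):
            raise ValueError("cos_phi out of [-1, 1]")


@dataclass
class LEDArray:
    """Rigid LED panel: unit layout in the panel frame plus a pose.

    The panel frame has the units in the z = 0 plane and every optical axis
    along +z.  ``rotation`` / ``translation_mm`` map panel coordinates into
    the target frame.
    """

    unit_positions: np.ndarray  # (n, 3) mm, panel frame
    spec: LEDSpec = dc_field(default_factory=LEDSpec)
    i0: np.ndarray | None = None  # per-unit intensities, mW/Sr
    rotation: np.ndarray = dc_field(default_factory=lambda: np.eye(3))
    translation_mm: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.unit_positions = np.atleast_2d(np.asarray(self.unit_positions, dtype=float))
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (determinant +1)")
        if self.i0 is None:
            self.i0 = np.full(self.n_units, self.spec.i0)
        else:
            self.i0 = np.asarray(self.i0, dtype=float)
            if self.i0.shape != (self.n_units,):
                raise ValueError("i0 must have one entry per unit")

    @classmethod
    def grid(
        cls,
        rows: int = 15,
        cols: int = 15,
        pitch_mm: float = 10.0,
        spec: LEDSpec | None = None,
    ) -> "LEDArray":
        """Centred rows x cols grid at the given pitch (default 15 x 15, 1 cm)."""
        if rows < 1 or cols < 1 or pitch_mm <= 0:
            raise ValueError("invalid grid parameters")
        gx = (np.arange(cols) - (cols - 1) / 2.0) * pitch_mm
        gy = (np.arange(rows) - (rows - 1) / 2.0) * pitch_mm
        x, y = np.meshgrid(gx, gy)
        pos = np.column_stack([x.ravel(), y.ravel(), np.zeros(x.size)])
        return cls(pos, spec=spec or LEDSpec())

    @property
    def n_units(self) -> int:
        return self.unit_positions.shape[0]

    @property
    def unit_positions_world(self) -> np.ndarray:
        return self.unit_positions @ self.rotation.T + self.translation_mm

    @property
    def axis_world(self) -> np.ndarray:
        """Shared optical-axis direction in the target frame."""
        return self.rotation[:, 2]

    @property
    def panel_center_world(self) -> np.ndarray:
        return self.translation_mm.copy()

    def with_intensities(self, i0) -> "LEDArray":
        i0 = np.broadcast_to(np.asarray(i0, dtype=float), (self.n_units,)).copy()
        return LEDArray(self.unit_positions.copy(), self.spec, i0, self.rotation.copy(), self.translation_mm.copy())

    def with_pose(self, rotation: np.ndarray, translation_mm: np.ndarray) -> "LEDArray":
        return LEDArray(self.unit_positions.copy(), self.spec, self.i0.copy(), rotation, translation_mm)


def ray_geometry(led_position, led_axis, point, point_normal) -> RaySample:
    """Distance and incidence/emission cosines for one LED-to-point ray.

    Positions in mm; the returned distance is in cm.
    """
    led_position = np.asarray(led_position, dtype=float)
    led_axis = np.asarray(led_axis, dtype=float)
    point = np.asarray(point, dtype=float)
    point_normal = np.asarray(point_normal, dtype=float)
    d = point - led_position
    r_mm = np.linalg.norm(d)
    if r_mm == 0:
        raise ValueError("point coincides with the LED (degenerate geometry)")
    u = d / r_mm
    return RaySample(
        r_cm=r_mm / 10.0,
        cos_theta=float(np.clip(point_normal @ (-u), -1.0, 1.0)),
        cos_phi=float(np.clip(led_axis @ u, -1.0, 1.0)),
    )


def single_led_irradiance(spec: LEDSpec, ray: RaySample) -> float:
    """Irradiance (mW/cm^2) at a point from one unit; back-facing rays give 0."""
    ct = max(ray.cos_theta, 0.0)
    cp = max(ray.cos_phi, 0.0)
    return spec.i0 * ct * cp**spec.m / ray.r_cm**2


@dataclass
class IlluminationMatrix:
    """Linear map from per-unit intensities (mW/Sr) to irradiance (mW/cm^2).

    entries[i, j] is the irradiance point i receives from unit j at unit
    intensity; the field under intensities I0 is entries @ I0.
    """

    entries: np.ndarray  # (N, n_units)
    cloud_ref: PointCloud | None = None
    array_ref: LEDArray | None = None

    def field(self, i0: np.ndarray) -> np.ndarray:
        return self.entries @ np.asarray(i0, dtype=float)


@dataclass
class IrradianceField:
    """Per-point irradiance values (mW/cm^2) for one panel drive state."""

    values: np.ndarray
    cloud_ref: PointCloud | None = None
    i0: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("irradiance values must be non-negative")


def illumination_matrix(array: LEDArray, cloud: PointCloud, chunk: int = 4096) -> IlluminationMatrix:
    """Per-point x per-unit irradiance matrix at unit intensity.

    Evaluated in chunks of points to bound memory on dense clouds.
    """
    if cloud.normals is None:
        raise ValueError("cloud must carry normals; run estimate_normals first")
    led = array.unit_positions_world
    axis = array.axis_world
    m = array.spec.m
    pts = cloud.positions
    nrm = cloud.normals
    out = np.empty((len(cloud), array.n_units))
    for lo in range(0, len(cloud), chunk):
        hi = min(lo + chunk, len(cloud))
        d = pts[lo:hi, None, :] - led[None, :, :]  # point - LED
        r_mm = np.linalg.norm(d, axis=2)
        if np.any(r_mm == 0):
            i, j = np.argwhere(r_mm == 0)[0]
            raise ValueError(f"point {lo + i} coincides with LED unit {j}")
        cos_phi = (d @ axis) / r_mm
        cos_theta = np.einsum("ij,ikj->ik", nrm[lo:hi], -d) / r_mm
        np.clip(cos_phi, 0.0, None, out=cos_phi)
        np.clip(cos_theta, 0.0, None, out=cos_theta)
        out[lo:hi] = cos_theta * cos_phi**m / (r_mm / 10.0) ** 2
    return IlluminationMatrix(out, cloud_ref=cloud, array_ref=array)


def irradiance_field(array: LEDArray, cloud: PointCloud, matrix: IlluminationMatrix | None = None) -> IrradianceField:
    """Total panel irradiance at every cloud point under the array's current I0."""
    if matrix is None:
        matrix = illumination_matrix(array, cloud)
    return IrradianceField(matrix.field(array.i0), cloud_ref=cloud, i0=array.i0.copy())


def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Deterministic right-handed rotation whose third column is ``axis``."""
    e3 = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0]) if abs(e3[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ e3) * e3
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(e3, e1)
    return np.column_stack([e1, e2, e3])


def pose_from_lesion(array: LEDArray, cloud: PointCloud, distance_cm: float = 10.0) -> LEDArray:
    """Pose the panel facing the lesion along its average normal.

    The panel centre is placed ``distance_cm`` from the lesion centroid along
    the cloud's average normal (which points away from the surface, toward
    the source side), and the panel optical axis points back at the lesion.
    """
    if distance_cm <= 0:
        raise ValueError("distance_cm must be positive")
    nbar = average_normal(cloud)
    centre = cloud.centroid + distance_cm * 10.0 * nbar
    rotation = _orthonormal_frame(-nbar)
    return array.with_pose(rotation, centre)


def rotate_array(array: LEDArray, angle_deg: float, pivot_point) -> LEDArray:
    """Rigidly rotate the panel about the vertical (0,0,1) axis through a pivot.

    Used to probe pose robustness: the pivot is the lesion centre, so the
    panel swings around the target while keeping its distance to it.
    """
    pivot = np.asarray(pivot_point, dtype=float)
    if not np.all(np.isfinite(pivot)):
        raise ValueError("pivot must be finite")
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rotation = rz @ array.rotation
    translation = rz @ (array.translation_mm - pivot) + pivot
    return array.with_pose(rotation, translation)
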