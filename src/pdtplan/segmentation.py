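"""Color-based lesion extraction from a scanned point cloud.

The colored cloud is projected through an ideal pinhole camera onto a 2D
image (z-buffered, with a pixel-to-point index map), converted from sRGB
to CIE-L*a*b*, and the lightness channel is affinely rescaled to a fixed
reference range so that global illumination changes cancel.  Pixels are
then scored by a chromatic saliency — the distance in the (a*, b*) plane
to the background eigen-color minus the distance to the foreground
(lesion) eigen-color — and thresholded (Otsu by default).  The binary
mask is mapped back through the index map to yield the lesion sub-cloud.

The eigen-colors are either supplied explicitly or auto-estimated by a
2-class k-means in (a*, b*), taking the redder centroid (larger a*) as
the lesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .cloud import PointCloud
from .phantoms import average_normal

__all__ = [
    "Camera",
    "ProjectedImage",
    "default_camera",
    "project_pinhole",
    "normalize_lightness",
    "saliency_segment",
    "backproject_mask",
    "segment_lesion",
]

#: reference range the L* channel is rescaled to
L_REF_RANGE = (10.0, 90.0)


@dataclass
class Camera:
    """Ideal pinhole camera: pose plus intrinsics (pixels)."""

    rotation: np.ndarray  # (3, 3), rows are the camera x/y/z axes in world coords
    position: np.ndarray  # (3,) mm, optical centre in world coords
    focal_px: float
    cx: float
    cy: float
    width: int
    height: int

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        return (points - self.position) @ self.rotation.T


@dataclass
class ProjectedImage:
    """RGB image of a projected cloud plus the pixel-to-point index map."""

    pixels: np.ndarray  # (H, W, 3) RGB in [0, 1]
    index_map: np.ndarray  # (H, W) int, -1 where no point projected
    camera: Camera

    @property
    def valid(self) -> np.ndarray:
        return self.index_map >= 0


def default_camera(cloud: PointCloud, margin_px: int = 4) -> Camera:
    """Long-focal pinhole looking at the cloud along its average normal.

    The camera sits far from the cloud (20x its extent) on the side the
    normals point toward, with the focal length chosen so one pixel spans
    roughly the cloud's median point spacing — every point then gets its
    own pixel, which the projection coverage requires.
    """
    if cloud.normals is None:
        raise ValueError("cloud needs normals to choose a viewing direction")
    nbar = average_normal(cloud)
    centre = cloud.centroid
    extent = float(np.ptp(cloud.positions, axis=0).max())
    tree = cKDTree(cloud.positions)
    d, _ = tree.query(cloud.positions, k=2)
    spacing = float(np.median(d[:, 1]))
    dist = 20.0 * max(extent, 1.0)
    position = centre + dist * nbar
    # camera z looks back at the cloud
    z = -nbar
    ref = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    rotation = np.stack([x, y, z])
    # ~1 px per point spacing at the cloud, slightly oversampled so tilted
    # regions (which project denser) still give almost every point a pixel
    focal = 1.2 * dist / spacing
    cam_pts = (cloud.positions - position) @ rotation.T
    u = focal * cam_pts[:, 0] / cam_pts[:, 2]
    v = focal * cam_pts[:, 1] / cam_pts[:, 2]
    width = int(np.ceil(np.ptp(u))) + 2 * margin_px + 1
    height = int(np.ceil(np.ptp(v))) + 2 * margin_px + 1
    cx = margin_px - float(np.floor(u.min()))
    cy = margin_px - float(np.floor(v.min()))
    return Camera(rotation, position, focal, cx, cy, width, height)


def project_pinhole(cloud: PointCloud, camera: Camera | None = None) -> ProjectedImage:
    """Z-buffered pinhole projection; the nearest point wins each pixel."""
    if camera is None:
        camera = default_camera(cloud)
    cam_pts = camera.to_camera(cloud.positions)
    front = cam_pts[:, 2] > 0
    if not front.any():
        raise ValueError("all points are behind the camera")
    u = np.round(camera.focal_px * cam_pts[:, 0] / cam_pts[:, 2] + camera.cx).astype(int)
    v = np.round(camera.focal_px * cam_pts[:, 1] / cam_pts[:, 2] + camera.cy).astype(int)
    inside = front & (u >= 0) & (u < camera.width) & (v >= 0) & (v < camera.height)
    idx = np.flatnonzero(inside)
    # sort decreasing depth so the nearest point is written last
    order = idx[np.argsort(-cam_pts[idx, 2], kind="stable")]
    index_map = np.full((camera.height, camera.width), -1, dtype=int)
    index_map[v[order], u[order]] = order
    pixels = np.zeros((camera.height, camera.width, 3))
    hit = index_map >= 0
    if cloud.colors is not None:
        pixels[hit] = cloud.colors[index_map[hit]]
    return ProjectedImage(pixels, index_map, camera)


def normalize_lightness(image, foreground: np.ndarray | None = None) -> np.ndarray:
    """sRGB (D65) -> CIE-L*a*b* with L* affinely rescaled to a fixed range.

    The rescaling is computed over foreground pixels (the projected ones,
    when given a ProjectedImage) and makes the result invariant to global
    lightness scaling, which acts affinely on L*.  a* and b* pass through
    the standard conversion unchanged.  A constant-L image maps to the
    reference midpoint.
    """
    if isinstance(image, ProjectedImage):
        foreground = image.valid if foreground is None else foreground
        rgb = image.pixels
    else:
        rgb = np.asarray(image, dtype=float)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB must lie in [0, 1]")
    lab = rgb2lab(rgb)
    fg = np.ones(rgb.shape[:2], dtype=bool) if foreground is None else foreground
    lo, hi = L_REF_RANGE
    lvals = lab[..., 0][fg]
    lmin, lmax = lvals.min(), lvals.max()
    if lmax - lmin < 1e-9:
        lab[..., 0][fg] = 0.5 * (lo + hi)
    else:
        lab[..., 0][fg] = lo + (lab[..., 0][fg] - lmin) * (hi - lo) / (lmax - lmin)
    return lab


def saliency_segment(
    image,
    fg_seed: np.ndarray | None = None,
    bg_seed: np.ndarray | None = None,
    threshold: float | None = None,
) -> np.ndarray:
    """Binary lesion mask from chromatic saliency.

    ``image`` is a ProjectedImage (lightness-normalised internally) or an
    L*a*b* array.  Seeds are (a*, b*) eigen-colors; when omitted they are
    estimated by seeded 2-class k-means over the foreground chromaticities,
    with the larger-a* centroid as the lesion.  Saliency is
    ``|ab - bg| - |ab - fg|`` and the mask keeps pixels above ``threshold``
    (Otsu on the foreground saliency histogram by default).
    """
    if isinstance(image, ProjectedImage):
        fg_pixels = image.valid
        lab = normalize_lightness(image)
    else:
        lab = np.asarray(image, dtype=float)
        fg_pixels = np.ones(lab.shape[:2], dtype=bool)
    ab = lab[..., 1:]
    if fg_seed is None or bg_seed is None:
        samples = ab[fg_pixels]
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(samples)
        c0, c1 = km.cluster_centers_
        fg_seed, bg_seed = (c0, c1) if c0[0] > c1[0] else (c1, c0)
    fg_seed = np.asarray(fg_seed, dtype=float)
    bg_seed = np.asarray(bg_seed, dtype=float)
    if np.linalg.norm(fg_seed - bg_seed) < 1.0:
        raise ValueError("foreground and background eigen-colors are indistinguishable in (a*, b*)")
    d_fg = np.linalg.norm(ab - fg_seed, axis=-1)
    d_bg = np.linalg.norm(ab - bg_seed, axis=-1)
    saliency = d_bg - d_fg
    if threshold is None:
        svals = saliency[fg_pixels]
        if np.ptp(svals) < 1e-12:
            threshold = 0.0
        else:
            threshold = float(threshold_otsu(svals))
    return (saliency > threshold) & fg_pixels


def backproject_mask(mask: np.ndarray, image: ProjectedImage, cloud: PointCloud) -> PointCloud | None:
    """Sub-cloud of the points whose winning pixel is inside the mask.

    Normals, colors and per-point attributes are preserved.  An empty mask
    yields ``None`` with a warning.
    """
    if mask.shape != image.index_map.shape:
        raise ValueError("mask shape must match the projected image")
    idx = image.index_map[mask & image.valid]
    idx = np.unique(idx)
    if idx.size == 0:
        warnings.warn("mask selects no points; returning an empty result", stacklevel=2)
        return None
    return cloud.select(idx)


def segment_lesion(
    cloud: PointCloud,
    camera: Camera | None = None,
    fg_seed: np.ndarray | None = None,
    bg_seed: np.ndarray | None = None,
) -> tuple[PointCloud | None, np.ndarray, ProjectedImage]:
    """Project, segment and back-project in one call."""
    if cloud.colors is None:
        raise ValueError("cloud has no colors to segment on")
    image = project_pinhole(cloud, camera)
    mask = saliency_segment(image, fg_seed=fg_seed, bg_seed=bg_seed)
    sub = backproject_mask(mask, image, cloud)
    return sub, mask, image
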