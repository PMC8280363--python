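"""Point-cloud container shared by every stage of the planning pipeline.

Positions are stored in millimetres (structured-light scanner convention).
Normals, when present, are unit vectors; in the array frame the panel sits
in the XOY plane with +z pointing toward the target, so surface normals of
a lesion facing the panel have negative z-components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PointCloud"]

_UNIT_TOL = 1e-9


@dataclass
class PointCloud:
    """Surface samples with optional per-point unit normals and RGB colors.

    Parameters
    ----------
    positions : (N, 3) float array
        Sample coordinates in mm.
    normals : (N, 3) float array, optional
        Unit surface normals (renormalised on construction).
    colors : (N, 3) float array, optional
        RGB in [0, 1].
    frame : str
        Label of the coordinate frame the positions live in.
    attributes : dict
        Free-form per-cloud metadata (e.g. a ground-truth lesion mask).
    """

    positions: np.ndarray
    normals: np.ndarray | None = None
    colors: np.ndarray | None = None
    frame: str = "array"
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 1:
            raise ValueError("a point cloud needs at least one point")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.normals is not None:
            n = np.atleast_2d(np.asarray(self.normals, dtype=float))
            if n.shape != self.positions.shape:
                raise ValueError("normals must match positions in shape")
            norms = np.linalg.norm(n, axis=1)
            if np.any(norms <= 0) or not np.all(np.isfinite(norms)):
                raise ValueError("normals must be non-zero finite vectors")
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("normals must be unit length")
            # snap to unit length so downstream dot products stay within 1e-9
            self.normals = n / norms[:, None]
        if self.colors is not None:
            c = np.atleast_2d(np.asarray(self.colors, dtype=float))
            if c.shape != self.positions.shape:
                raise ValueError("colors must be an (N, 3) RGB array")
            if c.min() < -1e-12 or c.max() > 1 + 1e-12:
                raise ValueError("colors must lie in [0, 1]")
            self.colors = np.clip(c, 0.0, 1.0)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at ``index`` (boolean mask or integer indices)."""
        index = np.asarray(index)
        return PointCloud(
            positions=self.positions[index],
            normals=None if self.normals is None else self.normals[index],
            colors=None if self.colors is None else self.colors[index],
            frame=self.frame,
            attributes={
                k: (v[index] if isinstance(v, np.ndarray) and len(v) == len(self) else v)
                for k, v in self.attributes.items()
            },
        )

    def with_normals(self, normals: np.ndarray) -> "PointCloud":
        return PointCloud(self.positions.copy(), normals, None if self.colors is None else self.colors.copy(), self.frame, dict(self.attributes))
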