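"""Point-cloud container.

Coordinates are millimetres throughout.  The synthetic generator and the
exposure reconstructions use a right-handed frame with +y cranio-caudal,
+z dorsal, and the anatomical midline at x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpineCongruenceError

#: Region vocabulary used by the synthetic vertebra generator.  Arbitrary
#: label strings are accepted (e.g. ``surface`` for primitive patches);
#: these are the ones the exposure reconstructions understand.
REGION_LABELS = (
    "left_hemilamina",
    "right_hemilamina",
    "sp_base",
    "sp_tip",
    "facet",
    "transverse_process",
    "outlier",
)

_UNIT_TOL = 1e-9


@dataclass
class PointCloud:
    """N x 3 point set with optional unit normals and per-point region labels.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates in mm; all finite, N >= 1.
    normals : (N, 3) float array, optional
        Unit vectors (norm 1 within 1e-9), one per point.
    labels : (N,) array of str, optional
        Region tag per point; see :data:`REGION_LABELS`.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise SpineCongruenceError(
                f"points must be (N, 3), got shape {self.points.shape}"
            )
        if len(self.points) < 1:
            raise SpineCongruenceError("point cloud must contain at least one point")
        if not np.all(np.isfinite(self.points)):
            raise SpineCongruenceError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float)
            if self.normals.shape != self.points.shape:
                raise SpineCongruenceError(
                    "normals must match points in shape "
                    f"({self.normals.shape} vs {self.points.shape})"
                )
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.all(np.abs(norms - 1.0) <= 1e-6):
                raise SpineCongruenceError("normals must be unit length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.points),):
                raise SpineCongruenceError("labels must be one string per point")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array, preserving point order."""
        mask = np.asarray(mask)
        return PointCloud(
            points=self.points[mask],
            normals=None if self.normals is None else self.normals[mask],
            labels=None if self.labels is None else self.labels[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        """Apply a rigid motion ``p -> R p + t`` (normals rotate only)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        return PointCloud(
            points=self.points @ rotation.T + translation,
            normals=None if self.normals is None else self.normals @ rotation.T,
            labels=self.labels,
        )
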