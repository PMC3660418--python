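"""Small geometric primitives shared across the pipeline.

World coordinates are in micrometres and ordered ``(z, y, x)`` to match
array indexing (0-based).  The centre of voxel ``(i, j, k)`` sits at
``(i*h, j*h, k*h)`` where ``h`` is the isotropic voxel size in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Plane", "voxel_center", "signed_distance_grid"]


@dataclass(frozen=True)
class Plane:
    """An oriented plane, stored as point + unit normal in µm, (z, y, x) order."""

    point_um: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if not np.isfinite(norm) or norm == 0.0:
            raise ValueError("plane normal must be a nonzero finite vector")
        object.__setattr__(self, "normal", tuple((n / norm).tolist()))
        object.__setattr__(self, "point_um", tuple(float(v) for v in self.point_um))

    def signed_distance(self, points_um: np.ndarray) -> np.ndarray:
        """Signed distance (µm) of ``points_um`` with shape (..., 3)."""
        p = np.asarray(points_um, dtype=float)
        return (p - np.asarray(self.point_um)) @ np.asarray(self.normal)

    def to_dict(self) -> dict:
        return {"point_um": list(self.point_um), "normal": list(self.normal)}

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(tuple(d["point_um"]), tuple(d["normal"]))


def voxel_center(index: tuple[int, int, int], voxel_size_um: float) -> np.ndarray:
    """µm coordinates of a voxel centre."""
    return np.asarray(index, dtype=float) * float(voxel_size_um)


def signed_distance_grid(
    plane: Plane, shape: tuple[int, int, int], voxel_size_um: float
) -> np.ndarray:
    """Signed distance (µm) from every voxel centre of a grid to ``plane``.

    Evaluated separably along each axis, so the full (z, y, x) array is
    assembled by broadcasting three 1-D terms.
    """
    h = float(voxel_size_um)
    nz, ny, nx = shape
    pz, py, px = plane.point_um
    az, ay, ax = plane.normal
    z = (np.arange(nz) * h - pz) * az
    y = (np.arange(ny) * h - py) * ay
    x = (np.arange(nx) * h - px) * ax
    return z[:, None, None] + y[None, :, None] + x[None, None, :]
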