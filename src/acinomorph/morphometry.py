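"""3D morphometry of terminal branching units.

Seven parameters characterise one unit: the mother terminal-bronchiole
diameter ``d0``; the mouth diameters ``d1 >= d2`` of the major and minor
daughter alveolar sacs; their surface areas ``S1, S2`` and volumes
``V1, V2``.  Conventions:

* A *diameter* is the geometric mean of a long and a short in-plane axis
  measured on a ring of interface points: the long axis is the maximal
  pairwise chord, the short axis the extent along the in-plane direction
  perpendicular to that chord.
* *Surface area* counts exposed voxel faces on the 6-neighbour basis and
  multiplies by the voxel face area.  On smooth surfaces this estimator
  is biased high by a factor converging to 3/2 (the spherical mean of
  |n_x|+|n_y|+|n_z|); the bias is reproduced deliberately, not corrected,
  so that measurements stay comparable across the package.
* *Volume* is voxel count times voxel volume, reported in nL
  (1 nL = 1e6 µm³).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .extraction import TerminalUnitLabels

__all__ = [
    "MorphometryRecord",
    "mouth_axes",
    "mouth_diameter",
    "surface_area",
    "region_volume",
    "count_exposed_faces",
    "measure_unit",
    "records_to_frame",
    "write_morphometry_csv",
    "read_morphometry_csv",
    "round_sig",
]

UM3_PER_NL = 1.0e6

CSV_COLUMNS = ["unit_id", "d0_um", "d1_um", "d2_um", "S1_um2", "S2_um2", "V1_nL", "V2_nL"]


@dataclass(frozen=True)
class MorphometryRecord:
    """One terminal branching unit's seven morphological parameters."""

    unit_id: str
    d0_um: float
    d1_um: float
    d2_um: float
    S1_um2: float
    S2_um2: float
    V1_nL: float
    V2_nL: float

    def __post_init__(self) -> None:
        for name in ("d0_um", "d1_um", "d2_um", "S1_um2", "S2_um2", "V1_nL", "V2_nL"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.d1_um < self.d2_um:
            raise ValueError(
                "major/minor ordering violated: d1_um must be >= d2_um "
                f"({self.d1_um} < {self.d2_um})"
            )

    def as_dict(self) -> dict:
        return asdict(self)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (export/report formatting)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")


def mouth_axes(points_um: np.ndarray, normal: Sequence[float] | None = None):
    """Long and short axis (µm) of a ring of points.

    Parameters
    ----------
    points_um : (N, 3) array
        Ring points in µm.  They are expected to lie near a common plane.
    normal : optional unit vector
        Plane normal.  When given, points are projected into the plane
        before measuring; otherwise the best-fit plane normal (smallest
        principal component) is used.

    Returns
    -------
    (long_axis_um, short_axis_um)
        Long axis = maximal pairwise distance; short axis = extent along
        the in-plane direction perpendicular to the long axis.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("mouth ring needs at least 3 points of dimension 3")
    centred = pts - pts.mean(axis=0)
    if normal is None:
        # smallest principal axis of the point cloud
        _, s, vt = np.linalg.svd(centred, full_matrices=False)
        if s[1] <= 1e-9 * max(s[0], 1e-30):  # rank < 2: collinear or identical
            raise ValueError("degenerate mouth ring: points are collinear or identical")
        n = vt[-1]
    else:
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
    # project into the plane
    proj = centred - np.outer(centred @ n, n)

    diff = proj[:, None, :] - proj[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    long_axis = math.sqrt(float(d2[i, j]))
    if long_axis <= 0:
        raise ValueError("degenerate mouth ring: all points identical")
    u = (proj[i] - proj[j]) / long_axis
    w = np.cross(n, u)
    w_norm = np.linalg.norm(w)
    if w_norm == 0:
        raise ValueError("degenerate mouth ring geometry")
    w = w / w_norm
    t = proj @ w
    short_axis = float(t.max() - t.min())
    if short_axis <= 0:
        raise ValueError("degenerate mouth ring: points are collinear")
    return long_axis, short_axis


def mouth_diameter(long_axis_um: float, short_axis_um: float) -> float:
    """Effective mouth diameter: geometric mean of the two axes."""
    if not (long_axis_um > 0 and short_axis_um > 0):
        raise ValueError("axes must be positive")
    return math.sqrt(long_axis_um * short_axis_um)


def _pair_counts(region: np.ndarray) -> int:
    """Number of 6-neighbour pairs with both voxels inside the region."""
    pairs = 0
    for axis in range(region.ndim):
        a = np.swapaxes(region, 0, axis)
        pairs += int(np.count_nonzero(a[:-1] & a[1:]))
    return pairs


def count_exposed_faces(region: np.ndarray) -> int:
    """6-neighbour faces between region voxels and anything else.

    Faces on the array border count as exposed.
    """
    region = np.asarray(region, dtype=bool)
    n = int(np.count_nonzero(region))
    if n == 0:
        raise ValueError("empty region")
    return 6 * n - 2 * _pair_counts(region)


def surface_area(region: np.ndarray, voxel_size_um: float) -> float:
    """Face-counting surface area in µm²."""
    return count_exposed_faces(region) * float(voxel_size_um) ** 2


def region_volume(region: np.ndarray, voxel_size_um: float) -> float:
    """Voxel-counting volume in nL."""
    region = np.asarray(region, dtype=bool)
    n = int(np.count_nonzero(region))
    if n == 0:
        raise ValueError("empty region")
    return n * float(voxel_size_um) ** 3 / UM3_PER_NL


def measure_unit(unit: "TerminalUnitLabels", unit_id: str = "unit") -> MorphometryRecord:
    """Measure all seven parameters of an extracted terminal unit.

    ``d0`` comes from the mother cross-section ring at the mother cap
    plane; ``d1, d2`` from the daughter mouth rings; ``S`` and ``V``
    from the labelled daughter regions (2 = major, 3 = minor).
    """
    h = unit.voxel_size_um
    rings = {
        "mother": (unit.mother_ring_um, unit.mother_cap_plane),
        "major": (unit.mouth_ring_major_um, unit.mouth_plane_major),
        "minor": (unit.mouth_ring_minor_um, unit.mouth_plane_minor),
    }
    d = {}
    for name, (ring, plane) in rings.items():
        if ring is None or len(ring) < 3:
            raise ValueError(f"missing or degenerate ring for region: {name}")
        lo, sh = mouth_axes(ring, normal=plane.normal if plane is not None else None)
        d[name] = mouth_diameter(lo, sh)

    out = {}
    for label, tag in ((2, "1"), (3, "2")):
        region = unit.labels == label
        if not region.any():
            raise ValueError(f"missing region: label {label}")
        out[f"S{tag}_um2"] = surface_area(region, h)
        out[f"V{tag}_nL"] = region_volume(region, h)

    d1, d2 = d["major"], d["minor"]
    if d1 < d2:  # ordering is decided upstream on the same rings; keep invariant
        d1, d2 = d2, d1
    return MorphometryRecord(
        unit_id=unit_id,
        d0_um=d["mother"],
        d1_um=d1,
        d2_um=d2,
        **out,
    )


def records_to_frame(records: Iterable[MorphometryRecord], sig: int | None = 3) -> pd.DataFrame:
    rows = []
    for r in records:
        row = r.as_dict()
        if sig is not None:
            for k, v in row.items():
                if k != "unit_id":
                    row[k] = round_sig(v, sig)
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_morphometry_csv(records: Iterable[MorphometryRecord], path, sig: int | None = 3) -> None:
    records_to_frame(records, sig=sig).to_csv(path, index=False)


def read_morphometry_csv(path) -> list[MorphometryRecord]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"morphometry CSV missing columns: {sorted(missing)}")
    return [
        MorphometryRecord(
            unit_id=str(row.unit_id),
            d0_um=float(row.d0_um),
            d1_um=float(row.d1_um),
            d2_um=float(row.d2_um),
            S1_um2=float(row.S1_um2),
            S2_um2=float(row.S2_um2),
            V1_nL=float(row.V1_nL),
            V2_nL=float(row.V2_nL),
        )
        for row in df.itertuples(index=False)
    ]
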