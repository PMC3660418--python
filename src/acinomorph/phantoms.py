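"""Synthetic terminal-branching-unit phantoms with known morphometry.

A terminal branching unit is modelled as a "mother" terminal bronchiole —
a cylinder of radius ``mother_radius_um`` along +z — ending at a
bifurcation from which two short cylindrical necks (radius = mouth
radius) diverge at ``bifurcation_angle_deg``.  Each neck opens through a
circular *mouth* into a "daughter" alveolar sac, an ellipsoid whose wall
is perturbed by smooth seeded bumps emulating alveolation.  The mouth
plane is perpendicular to the sac's long axis and its intersection with
the sac is exactly the circle of the stated mouth radius, so mouth
diameters have closed-form ground truth; sac volumes and surface areas
are computed by a brute-force oracle that voxelizes the same geometry at
4x finer resolution and applies the same counting estimators.

Conventions: 0-based (z, y, x) indices, voxel centres at ``index * h``
µm, voxel membership by centre inclusion.  Labels: 0 = tissue, 1 =
mother lumen (trunk + necks), 2 = major daughter, 3 = minor daughter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .geometry import Plane
from .morphometry import MorphometryRecord, count_exposed_faces, UM3_PER_NL

__all__ = [
    "PhantomSpec",
    "LabeledVolume",
    "GroundTruth",
    "make_calibration_phantom",
    "make_terminal_unit_phantom",
    "ground_truth_morphometry",
    "boundary_mask_from_labels",
]

SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric parameters of one terminal branching unit (lengths in µm).

    Defaults put the unit at real mouse-lung scale: a d0 = 72 µm mother,
    mouth diameters 50 and 42 µm, sac volumes ~0.2-0.3 nL — inside the
    observed ranges for terminal bronchioles and alveolar sacs.
    """

    mother_radius_um: float = 36.0
    mother_length_um: float = 50.0
    daughter1_semiaxes_um: tuple[float, float, float] = (45.0, 37.0, 37.0)
    daughter2_semiaxes_um: tuple[float, float, float] = (40.0, 33.0, 33.0)
    mouth1_radius_um: float = 25.0
    mouth2_radius_um: float = 21.0
    bifurcation_angle_deg: float = 90.0
    wall_bumpiness: float = 0.1
    voxel_size_um: float = 1.74
    grid_shape: tuple[int, int, int] = (128, 128, 128)
    rng_seed: int = 0
    # secondary geometry knobs (artifact choices, see docs/methods.md)
    neck_length_um: float = 10.0
    septum_gap_um: float = 6.0
    bump_correlation_um: float = 9.0
    mouth_taper_um: float = 12.0

    def validate(self) -> None:
        h = self.voxel_size_um
        if not (h > 0):
            raise ValueError("voxel_size_um must be positive")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if not (0.0 < self.bifurcation_angle_deg < 180.0):
            raise ValueError("bifurcation_angle_deg must lie in (0, 180)")
        if self.wall_bumpiness < 0:
            raise ValueError("wall_bumpiness must be >= 0")
        for name in ("mother_radius_um", "mother_length_um", "mouth1_radius_um",
                     "mouth2_radius_um", "neck_length_um"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("daughter1_semiaxes_um", "daughter2_semiaxes_um"):
            ax = getattr(self, name)
            if len(ax) != 3 or any(not (a > 0) for a in ax):
                raise ValueError(f"{name} must be three positive lengths")
        if self.mouth1_radius_um > min(self.daughter1_semiaxes_um):
            raise ValueError("mouth1_radius_um exceeds smallest daughter-1 semiaxis")
        if self.mouth2_radius_um > min(self.daughter2_semiaxes_um):
            raise ValueError("mouth2_radius_um exceeds smallest daughter-2 semiaxis")
        geo = _Geometry.from_spec(self)
        margin = 3.0 * h
        extent = np.asarray(self.grid_shape, dtype=float) * h - h  # last centre
        for k, tag in ((0, "daughter 1"), (1, "daughter 2")):
            lo, hi = geo.sac_bounds_um(k, self)
            if (lo < margin - 1e-9).any() or (hi > extent - margin + 1e-9).any():
                axis = "zyx"[int(np.argmax(np.maximum(margin - lo, hi - (extent - margin))))]
                raise ValueError(
                    f"{tag} sac does not fit in the grid with a 3-voxel margin "
                    f"(offending axis: {axis})"
                )
        if geo.z_bif + h > extent[0] - margin or self.mother_radius_um > min(
            extent[1], extent[2]
        ) / 2 - margin:
            raise ValueError("mother bronchiole does not fit in the grid")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["daughter1_semiaxes_um"] = list(self.daughter1_semiaxes_um)
        d["daughter2_semiaxes_um"] = list(self.daughter2_semiaxes_um)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("daughter1_semiaxes_um", "daughter2_semiaxes_um", "grid_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class LabeledVolume:
    """Ground-truth labels: 0 tissue, 1 mother lumen, 2/3 daughter lumens."""

    labels: np.ndarray
    voxel_size_um: float

    def region(self, label: int) -> np.ndarray:
        return self.labels == label

    def validate(self) -> None:
        vals = np.unique(self.labels)
        if not np.isin(vals, [0, 1, 2, 3]).all():
            raise ValueError("labels must be within {0,1,2,3}")
        for lab in (1, 2, 3):
            region = self.labels == lab
            if region.any():
                _, n = ndimage.label(region, structure=SIX_CONN)
                if n != 1:
                    raise ValueError(f"label {lab} is not 6-connected ({n} components)")


@dataclass(frozen=True)
class GroundTruth:
    """Oracle morphometry of a phantom (diameters analytic, S/V voxelized 4x fine)."""

    record: MorphometryRecord


# ---------------------------------------------------------------------------
# internal geometry


@dataclass(frozen=True)
class _Geometry:
    axis_yx: tuple[float, float]        # trunk axis position (y, x) in µm
    z_top: float                        # proximal end of the trunk stub
    z_cap: float                        # mother cap plane position
    z_bif: float                        # bifurcation (trunk end) plane
    dirs: tuple[np.ndarray, np.ndarray]     # daughter long-axis directions (z,y,x)
    junctions: tuple[np.ndarray, np.ndarray]  # neck proximal centres (µm)
    mouths: tuple[np.ndarray, np.ndarray]     # mouth-plane centres (µm)
    frames: tuple[np.ndarray, np.ndarray]     # (3,3) rows u1,u2,u3 per daughter
    centers: tuple[np.ndarray, np.ndarray]    # sac centres (µm)
    mouth_offsets: tuple[float, float]        # t_k along the axis, µm
    septum_normal: np.ndarray

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "_Geometry":
        h = spec.voxel_size_um
        nz, ny, nx = spec.grid_shape
        axis_yx = ((ny - 1) / 2.0 * h, (nx - 1) / 2.0 * h)
        z_top = 3.0 * h
        z_cap = z_top + 4.0 * h
        z_bif = z_cap + spec.mother_length_um
        phi = math.radians(spec.bifurcation_angle_deg) / 2.0
        g = spec.septum_gap_um
        dirs, junctions, mouths, frames, centers, offsets = [], [], [], [], [], []
        for sign, semiaxes, r_m in (
            (+1.0, spec.daughter1_semiaxes_um, spec.mouth1_radius_um),
            (-1.0, spec.daughter2_semiaxes_um, spec.mouth2_radius_um),
        ):
            d = np.array([math.cos(phi), 0.0, sign * math.sin(phi)])  # (z,y,x)
            c_off = r_m + g / 2.0
            j = np.array([z_bif, axis_yx[0], axis_yx[1] + sign * c_off])
            m = j + spec.neck_length_um * d
            a, b, c = semiaxes
            if r_m > min(b, c):
                raise ValueError("mouth radius exceeds sac cross-section semiaxes")
            t = a * math.sqrt(max(0.0, 1.0 - (r_m / min(b, c)) ** 2))
            center = m + t * d
            u2 = np.array([0.0, 1.0, 0.0])
            u3 = np.cross(d, u2)
            u3 /= np.linalg.norm(u3)
            frames.append(np.stack([d, u2, u3]))
            dirs.append(d)
            junctions.append(j)
            mouths.append(m)
            centers.append(center)
            offsets.append(t)
        n_sep = dirs[0] - dirs[1]
        n_sep /= np.linalg.norm(n_sep)
        return cls(
            axis_yx=axis_yx, z_top=z_top, z_cap=z_cap, z_bif=z_bif,
            dirs=(dirs[0], dirs[1]), junctions=(junctions[0], junctions[1]),
            mouths=(mouths[0], mouths[1]), frames=(frames[0], frames[1]),
            centers=(centers[0], centers[1]), mouth_offsets=(offsets[0], offsets[1]),
            septum_normal=n_sep,
        )

    def semiaxes(self, spec: PhantomSpec, k: int) -> np.ndarray:
        return np.asarray(
            (spec.daughter1_semiaxes_um, spec.daughter2_semiaxes_um)[k], dtype=float
        )

    def bump_amp(self, spec: PhantomSpec, k: int) -> float:
        return spec.wall_bumpiness * float(self.semiaxes(spec, k).min())

    def sac_bounds_um(self, k: int, spec: PhantomSpec,
                      pad: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of sac k including bumps (+pad µm)."""
        axes = self.semiaxes(spec, k)
        U = self.frames[k]  # rows u1,u2,u3
        # extent along world axis e: sqrt(sum_j (a_j * (u_j . e))^2)
        ext = np.sqrt(((axes[:, None] * U) ** 2).sum(axis=0))
        amp = self.bump_amp(spec, k) + pad
        return self.centers[k] - ext - amp, self.centers[k] + ext + amp


def _bump_fields(spec: PhantomSpec) -> np.ndarray:
    """Two smooth seeded noise fields on the coarse grid, max-abs normalised.

    Fields live on grid indices; arbitrary µm positions are sampled by
    trilinear interpolation, so the coarse voxelization and the fine
    oracle see the same continuous bump field.
    """
    rng = np.random.default_rng(spec.rng_seed)
    sigma_vox = max(spec.bump_correlation_um / spec.voxel_size_um, 1.0)
    fields = []
    for _ in range(2):
        noise = rng.standard_normal(spec.grid_shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
        peak = np.abs(smooth).max()
        fields.append((smooth / peak if peak > 0 else smooth).astype(np.float32))
    return np.stack(fields)


def _sample_field(field_vox: np.ndarray, pts_um: np.ndarray, h: float) -> np.ndarray:
    coords = (pts_um / h).reshape(-1, 3).T
    out = ndimage.map_coordinates(field_vox, coords, order=1, mode="nearest")
    return out.reshape(pts_um.shape[:-1])


class _UnitEvaluator:
    """Point-membership tests for the terminal-unit solid geometry."""

    def __init__(self, spec: PhantomSpec, geo: _Geometry, fields: np.ndarray):
        self.spec = spec
        self.geo = geo
        self.fields = fields

    def _sac_raw(self, pts: np.ndarray, k: int, inflate: float = 0.0) -> np.ndarray:
        spec, geo = self.spec, self.geo
        axes = geo.semiaxes(spec, k)
        rel = pts - geo.centers[k]
        local = rel @ geo.frames[k].T
        rho = np.sqrt(((local / axes) ** 2).sum(axis=-1))
        dist = np.sqrt((rel**2).sum(axis=-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r_dir = np.where(rho > 1e-12, dist / np.maximum(rho, 1e-12), np.inf)
        amp = geo.bump_amp(spec, k)
        if amp > 0:
            s_mouth = (pts - geo.mouths[k]) @ geo.dirs[k]
            taper = np.clip(s_mouth / max(spec.mouth_taper_um, 1e-9), 0.0, 1.0)
            bump = amp * taper * _sample_field(self.fields[k], pts, spec.voxel_size_um)
        else:
            bump = 0.0
        inside = dist <= r_dir + bump + inflate
        distal = (pts - geo.mouths[k]) @ geo.dirs[k] > 0
        return inside & distal

    def _neck(self, pts: np.ndarray, k: int, inflate: float = 0.0) -> np.ndarray:
        spec, geo = self.spec, self.geo
        r_m = (spec.mouth1_radius_um, spec.mouth2_radius_um)[k]
        rel = pts - geo.junctions[k]
        s = rel @ geo.dirs[k]
        radial2 = (rel**2).sum(axis=-1) - s**2
        in_tube = radial2 <= (r_m + inflate) ** 2
        # extends a little proximally into the trunk so the lumens join
        return in_tube & (s >= -3.0 * spec.voxel_size_um - inflate) & (
            s <= spec.neck_length_um + inflate
        )

    def _trunk(self, pts: np.ndarray) -> np.ndarray:
        spec, geo = self.spec, self.geo
        r2 = (pts[..., 1] - geo.axis_yx[0]) ** 2 + (pts[..., 2] - geo.axis_yx[1]) ** 2
        return (r2 <= spec.mother_radius_um**2) & (pts[..., 0] >= geo.z_top) & (
            pts[..., 0] <= geo.z_bif
        )

    def _air_infl(self, pts: np.ndarray, k: int, inflate: float) -> np.ndarray:
        return self._sac_raw(pts, k, inflate) | self._neck(pts, k, inflate)

    def sac(self, pts: np.ndarray, k: int) -> np.ndarray:
        """Final sac lumen: raw sac minus the interalveolar septum carve."""
        g = self.spec.septum_gap_um
        raw = self._sac_raw(pts, k)
        if not raw.any():
            return raw
        other = 1 - k
        s_sep = (pts - self.geo.mouths[0]) @ self.geo.septum_normal
        near_other = self._air_infl(pts, other, g / 2.0)
        keep_side = s_sep >= g / 2.0 if k == 0 else s_sep <= -g / 2.0
        return raw & (keep_side | ~near_other)

    def mother(self, pts: np.ndarray) -> np.ndarray:
        air = self._trunk(pts) | self._neck(pts, 0) | self._neck(pts, 1)
        return air & ~self._sac_raw(pts, 0) & ~self._sac_raw(pts, 1)

    def raw_overlap(self, pts: np.ndarray) -> np.ndarray:
        return self._sac_raw(pts, 0) & self._sac_raw(pts, 1)


def _grid_points(z_um: np.ndarray, y_um: np.ndarray, x_um: np.ndarray) -> np.ndarray:
    zz = z_um[:, None, None]
    yy = y_um[None, :, None]
    xx = x_um[None, None, :]
    shape = (len(z_um), len(y_um), len(x_um))
    pts = np.empty(shape + (3,), dtype=np.float64)
    pts[..., 0] = np.broadcast_to(zz, shape)
    pts[..., 1] = np.broadcast_to(yy, shape)
    pts[..., 2] = np.broadcast_to(xx, shape)
    return pts


# ---------------------------------------------------------------------------
# public API


def make_calibration_phantom(kind: str, params: dict, grid_shape) -> LabeledVolume:
    """Analytic calibration solid, voxelized by centre inclusion.

    ``params`` are in voxel units.  Supported kinds: sphere {radius,
    center}, cuboid {shape, corner}, cylinder {radius, length, axis},
    disk {radius, thickness, center}, impulse {position}.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    nz, ny, nx = grid_shape
    labels = np.zeros(grid_shape, dtype=np.int16)
    idx = np.indices(grid_shape, dtype=float)
    center_default = (np.asarray(grid_shape, dtype=float) - 1) / 2.0

    def _check_bounds(lo, hi, what):
        for axis, (l, u, n) in enumerate(zip(lo, hi, grid_shape)):
            if l < -0.5 or u > n - 0.5:
                raise ValueError(
                    f"{what} exceeds the grid along axis {'zyx'[axis]} "
                    f"([{l:.1f}, {u:.1f}] vs {n} voxels)"
                )

    if kind == "sphere":
        r = float(params["radius"])
        c = np.asarray(params.get("center", center_default), dtype=float)
        _check_bounds(c - r, c + r, "sphere")
        d2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
        labels[d2 <= r * r] = 1
    elif kind == "cuboid":
        shape = np.asarray(params["shape"], dtype=int)
        corner = np.asarray(params.get("corner", (0, 0, 0)), dtype=int)
        _check_bounds(corner, corner + shape - 1, "cuboid")
        sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
        labels[sl] = 1
    elif kind == "cylinder":
        r = float(params["radius"])
        length = int(params["length"])
        axis = int(params.get("axis", 0))
        c = np.asarray(params.get("center", center_default), dtype=float)
        others = [a for a in range(3) if a != axis]
        lo = c.copy(); hi = c.copy()
        lo[axis] = c[axis] - (length - 1) / 2.0
        hi[axis] = c[axis] + (length - 1) / 2.0
        for a in others:
            lo[a] -= r; hi[a] += r
        _check_bounds(lo, hi, "cylinder")
        d2 = sum((idx[a] - c[a]) ** 2 for a in others)
        along = np.abs(idx[axis] - c[axis])
        labels[(d2 <= r * r) & (along <= (length - 1) / 2.0 + 1e-9)] = 1
    elif kind == "disk":
        params = dict(params)
        params.setdefault("length", int(params.pop("thickness", 1)))
        return make_calibration_phantom("cylinder", params, grid_shape)
    elif kind == "impulse":
        pos = tuple(int(v) for v in params["position"])
        _check_bounds(np.asarray(pos), np.asarray(pos), "impulse")
        labels[pos] = 1
    else:
        raise ValueError(
            f"unknown calibration phantom kind {kind!r}; "
            "expected one of sphere, cuboid, cylinder, disk, impulse"
        )
    return LabeledVolume(labels=labels, voxel_size_um=1.0)


def make_terminal_unit_phantom(spec: PhantomSpec):
    """Build the labelled phantom, its ground truth and its annotation.

    Returns ``(LabeledVolume, GroundTruth, UnitAnnotation)``.  Identical
    specs (including ``rng_seed``) give bit-identical output.
    """
    from .extraction import UnitAnnotation  # local import to avoid a cycle

    spec.validate()
    geo = _Geometry.from_spec(spec)
    fields = _bump_fields(spec)
    ev = _UnitEvaluator(spec, geo, fields)
    h = spec.voxel_size_um
    nz, ny, nx = spec.grid_shape

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    y_um = np.arange(ny) * h
    x_um = np.arange(nx) * h
    overlap_err = None
    guard = (max(spec.mouth1_radius_um, spec.mouth2_radius_um) + spec.septum_gap_um)
    for z0 in range(0, nz, 16):
        z_um = np.arange(z0, min(z0 + 16, nz)) * h
        pts = _grid_points(z_um, y_um, x_um)
        sac1 = ev.sac(pts, 0)
        sac2 = ev.sac(pts, 1)
        mother = ev.mother(pts)
        block = labels[z0 : z0 + len(z_um)]
        block[mother] = 1
        block[sac1] = 2
        block[sac2] = 3
        if overlap_err is None:
            ov = ev.raw_overlap(pts)
            if ov.any():
                far = np.sqrt(((pts - np.array([geo.z_bif, *geo.axis_yx])) ** 2).sum(-1))
                if (ov & (far > guard)).any():
                    overlap_err = True
    if overlap_err:
        raise ValueError(
            "daughter sacs overlap beyond the mouth region; "
            "reduce sac sizes or widen the bifurcation angle"
        )

    lv = LabeledVolume(labels=labels, voxel_size_um=h)
    lv.validate()

    def _seed_for(label: int, guess_um: np.ndarray) -> tuple[int, int, int]:
        g = np.clip(np.round(guess_um / h).astype(int), 0, np.array(spec.grid_shape) - 1)
        if labels[tuple(g)] == label:
            return tuple(int(v) for v in g)
        region = np.argwhere(labels == label)
        if len(region) == 0:
            raise ValueError(f"phantom produced an empty region for label {label}")
        j = np.argmin(((region - g) ** 2).sum(axis=1))
        return tuple(int(v) for v in region[j])

    mother_mid = np.array([(geo.z_cap + geo.z_bif) / 2.0, *geo.axis_yx])
    ann = UnitAnnotation(
        mother_seed=_seed_for(1, mother_mid),
        daughter1_seed=_seed_for(2, geo.centers[0]),
        daughter2_seed=_seed_for(3, geo.centers[1]),
        mother_cap_plane=Plane((geo.z_cap, *geo.axis_yx), (1.0, 0.0, 0.0)),
        mouth_plane_1=Plane(tuple(geo.mouths[0]), tuple(geo.dirs[0])),
        mouth_plane_2=Plane(tuple(geo.mouths[1]), tuple(geo.dirs[1])),
    )
    gt = GroundTruth(record=ground_truth_morphometry(spec))
    return lv, gt, ann


def _oracle_sac(spec: PhantomSpec, geo: _Geometry, ev: _UnitEvaluator, k: int,
                refine: int) -> tuple[float, float]:
    """(volume nL, surface µm²) of sac k, voxelized at ``refine``x resolution."""
    h_f = spec.voxel_size_um / refine
    lo, hi = geo.sac_bounds_um(k, spec, pad=2 * h_f)
    n = np.maximum(np.ceil((hi - lo) / h_f).astype(int) + 1, 1)
    z_um = lo[0] + np.arange(n[0]) * h_f
    y_um = lo[1] + np.arange(n[1]) * h_f
    x_um = lo[2] + np.arange(n[2]) * h_f
    region = np.empty(tuple(n), dtype=bool)
    step = max(1, int(4e6 // (n[1] * n[2])))
    for i0 in range(0, n[0], step):
        pts = _grid_points(z_um[i0 : i0 + step], y_um, x_um)
        region[i0 : i0 + step] = ev.sac(pts, k)
    count = int(np.count_nonzero(region))
    if count == 0:
        raise ValueError(f"oracle voxelization produced an empty sac {k + 1}")
    faces = count_exposed_faces(region)
    return count * h_f**3 / UM3_PER_NL, faces * h_f**2


def ground_truth_morphometry(spec: PhantomSpec, refine: int = 4) -> MorphometryRecord:
    """Oracle morphometry: analytic diameters, brute-force voxelized S and V.

    S and V use the same estimators as the measurement path (6-neighbour
    face counting, voxel counting) on a ``refine``-times finer grid, so
    the face-counting bias of the estimator is reproduced, not corrected.
    """
    from .extraction import assign_major_minor

    spec.validate()
    geo = _Geometry.from_spec(spec)
    ev = _UnitEvaluator(spec, geo, _bump_fields(spec))
    v1, s1 = _oracle_sac(spec, geo, ev, 0, refine)
    v2, s2 = _oracle_sac(spec, geo, ev, 1, refine)
    d_raw = (2.0 * spec.mouth1_radius_um, 2.0 * spec.mouth2_radius_um)
    order = assign_major_minor(d_raw[0], d_raw[1], v1, v2)
    d = (d_raw[order[0]], d_raw[order[1]])
    S = ((s1, s2)[order[0]], (s1, s2)[order[1]])
    V = ((v1, v2)[order[0]], (v1, v2)[order[1]])
    return MorphometryRecord(
        unit_id=f"phantom-seed{spec.rng_seed}",
        d0_um=2.0 * spec.mother_radius_um,
        d1_um=d[0], d2_um=d[1],
        S1_um2=S[0], S2_um2=S[1],
        V1_nL=V[0], V2_nL=V[1],
    )


def boundary_mask_from_labels(lv: LabeledVolume):
    """Ground-truth boundary: tissue voxels 6-adjacent to any lumen.

    The wall layer is marked, matching the convention that the detected
    air-tissue boundary represents tissue wall.
    """
    from .segmentation import BoundaryMask

    air = lv.labels > 0
    wall = ndimage.binary_dilation(air, structure=SIX_CONN) & ~air
    return BoundaryMask(mask=wall, voxel_size_um=lv.voxel_size_um)
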