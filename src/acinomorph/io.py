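"""Volume and sinogram interchange: multi-page TIFF + JSON sidecar.

Every artifact written by the pipeline is a multi-page TIFF (one z-slice
— or one projection angle — per page) accompanied by a ``.json`` sidecar
holding the voxel size, axis order, stage parameters, seeds and input
hashes, sufficient to re-run the producing stage.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

from .phantoms import LabeledVolume
from .projection import ProjectionSet
from .recon import VoxelVolume
from .segmentation import BoundaryMask

__all__ = [
    "file_sha256",
    "sidecar_path",
    "write_sidecar",
    "read_sidecar",
    "save_volume",
    "load_volume",
    "save_labels",
    "load_labels",
    "save_mask",
    "load_mask",
    "save_projections",
    "load_projections",
]


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_sidecar(path, payload: dict) -> None:
    payload = dict(payload)
    payload.setdefault("axis_order", "zyx")
    payload.setdefault("created", datetime.datetime.now().isoformat(timespec="seconds"))
    with open(sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_sidecar(path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise FileNotFoundError(f"missing sidecar {sp}")
    with open(sp) as fh:
        return json.load(fh)


def _save_stack(path, array: np.ndarray, voxel_size_um: float, kind: str, **meta) -> None:
    tifffile.imwrite(path, array, photometric="minisblack")
    write_sidecar(path, {"kind": kind, "voxel_size_um": voxel_size_um,
                         "shape": list(array.shape), "dtype": str(array.dtype), **meta})


def save_volume(path, volume: VoxelVolume, **meta) -> None:
    _save_stack(path, np.asarray(volume.values, dtype=np.float32),
                volume.voxel_size_um, "volume", **meta)


def load_volume(path) -> VoxelVolume:
    side = read_sidecar(path)
    return VoxelVolume(values=tifffile.imread(path), voxel_size_um=side["voxel_size_um"])


def save_labels(path, lv: LabeledVolume, **meta) -> None:
    _save_stack(path, lv.labels.astype(np.uint16), lv.voxel_size_um, "labels", **meta)


def load_labels(path) -> LabeledVolume:
    side = read_sidecar(path)
    return LabeledVolume(labels=tifffile.imread(path).astype(np.int16),
                         voxel_size_um=side["voxel_size_um"])


def save_mask(path, mask: BoundaryMask, **meta) -> None:
    _save_stack(path, (mask.mask.astype(np.uint8) * 255), mask.voxel_size_um,
                "boundary_mask", **meta)


def load_mask(path) -> BoundaryMask:
    side = read_sidecar(path)
    return BoundaryMask(mask=tifffile.imread(path) > 0,
                        voxel_size_um=side["voxel_size_um"])


def save_projections(path, ps: ProjectionSet, **meta) -> None:
    # one page per angle: (angle, slice, detector)
    arr = np.ascontiguousarray(np.swapaxes(ps.sinograms, 0, 1)).astype(np.float32)
    _save_stack(path, arr, ps.detector_pitch_um, "projections",
                angles_deg=list(ps.angles_deg), metadata=ps.metadata, **meta)


def load_projections(path) -> ProjectionSet:
    side = read_sidecar(path)
    arr = tifffile.imread(path)
    return ProjectionSet(
        sinograms=np.ascontiguousarray(np.swapaxes(arr, 0, 1)),
        angles_deg=np.asarray(side["angles_deg"], dtype=float),
        detector_pitch_um=side["voxel_size_um"],
        metadata=side.get("metadata", {}),
    )
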