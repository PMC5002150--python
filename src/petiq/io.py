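"""Standard-format I/O: NIfTI volumes, event-stream CSV/binary, JSON sidecars.

Event streams are stored either as a two-column CSV (bin_index, is_random)
with a JSON header sidecar, or as a compact binary file: a little-endian
record per event of int32 bin index followed by uint8 random flag (5 bytes
per event), with the same JSON header alongside.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import ActivityPhantom, EventStream

__all__ = [
    "load_nifti",
    "load_stream",
    "save_mask_nifti",
    "save_nifti",
    "save_phantom",
    "save_stream",
    "sha256_file",
]

_STREAM_DTYPE = np.dtype([("bin_index", "<i4"), ("is_random", "u1")])


def _affine(voxel_size) -> np.ndarray:
    """RAS+ affine with the grid origin at the corner voxel center."""
    aff = np.eye(4)
    for i, s in enumerate(voxel_size[:3]):
        aff[i, i] = s
    return aff


def save_nifti(data: np.ndarray, voxel_size, path: str | Path) -> Path:
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[..., None]
        voxel_size = tuple(voxel_size) + (1.0,)
    nib.save(nib.Nifti1Image(arr.astype(np.float32), _affine(voxel_size)), str(path))
    return path


def save_mask_nifti(mask: np.ndarray, voxel_size, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size)), str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), voxel_size


def save_phantom(phantom: ActivityPhantom, out_dir: str | Path, stem: str = "phantom") -> dict:
    """SUV and label maps as NIfTI plus the spec as a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "suv": save_nifti(phantom.suv_map, phantom.spec.voxel_size, out / f"{stem}_suv.nii.gz"),
        "labels": save_mask_nifti(phantom.label_map, phantom.spec.voxel_size,
                                  out / f"{stem}_labels.nii.gz"),
    }
    spec_path = out / f"{stem}_spec.json"
    spec_path.write_text(json.dumps(phantom.spec.to_dict(), indent=1))
    paths["spec"] = spec_path
    return paths


def _stream_header(stream: EventStream) -> dict:
    return {"n_events": stream.n_events, "n_true": stream.n_true,
            "n_random": stream.n_random, "domain": stream.domain,
            "provenance": {k: v for k, v in stream.provenance.items()}}


def save_stream(stream: EventStream, path: str | Path, binary: bool = False) -> Path:
    """Write a stream as CSV (default) or fixed-width binary, plus JSON header."""
    path = Path(path)
    if binary:
        rec = np.empty(len(stream), dtype=_STREAM_DTYPE)
        rec["bin_index"] = stream.bin_index
        rec["is_random"] = stream.is_random
        rec.tofile(path)
    else:
        with open(path, "w") as fh:
            fh.write("bin_index,is_random\n")
            np.savetxt(fh, np.column_stack([stream.bin_index, stream.is_random.astype(int)]),
                       fmt="%d", delimiter=",")
    header = Path(str(path) + ".json")
    header.write_text(json.dumps(_stream_header(stream), indent=1))
    return path


def load_stream(path: str | Path, binary: bool = False) -> EventStream:
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    if binary:
        rec = np.fromfile(path, dtype=_STREAM_DTYPE)
        bin_index = rec["bin_index"].astype(np.int64)
        is_random = rec["is_random"].astype(bool)
    else:
        data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64, ndmin=2)
        if data.size == 0:
            data = data.reshape(0, 2)
        bin_index = data[:, 0]
        is_random = data[:, 1].astype(bool)
    return EventStream(bin_index=bin_index, is_random=is_random,
                       domain=header["domain"], provenance=header.get("provenance", {}))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
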