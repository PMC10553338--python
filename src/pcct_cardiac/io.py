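"""Format plumbing: array containers with JSON sidecars, NIfTI volumes.

Sinograms travel as ``.npz`` with a JSON header (angles/timestamps are data
arrays; thresholds, mode and scan metadata go in the header).  Reconstructed
volumes and material maps are NIfTI (phase/bin in the 4th/5th dimensions)
with a JSON sidecar; tables are CSV.  Round trips are lossless for data
arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import BinnedSinogram
from .recon import ReconVolume

__all__ = ["save_sinogram", "load_sinogram", "save_recon", "load_recon",
           "save_json", "load_json"]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def load_json(path):
    return json.loads(Path(path).read_text())


def save_sinogram(path, sino: BinnedSinogram) -> None:
    path = Path(path)
    header = {
        "thresholds": list(sino.thresholds),
        "mode": sino.mode,
        "meta": _jsonable(sino.meta),
    }
    np.savez_compressed(
        path, data=sino.data, timestamps=sino.timestamps, angles=sino.angles,
        air_counts=sino.air_counts if sino.air_counts is not None
        else np.array([]),
        header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))


def load_sinogram(path) -> BinnedSinogram:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        air = z["air_counts"]
        return BinnedSinogram(
            data=z["data"], timestamps=z["timestamps"], angles=z["angles"],
            thresholds=tuple(header["thresholds"]), mode=header["mode"],
            air_counts=air if air.size else None, meta=header["meta"])


def save_recon(path, recon: ReconVolume) -> None:
    """NIfTI with shape (n, n, 1, phases, bins) plus a JSON sidecar."""
    path = Path(path)
    p, b, n, _ = recon.data.shape
    arr = np.transpose(recon.data, (2, 3, 0, 1)).reshape(n, n, 1, p, b)
    affine = np.diag([recon.voxel_mm, recon.voxel_mm, recon.voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    save_json(path.with_suffix(".json"), {
        "voxel_mm": recon.voxel_mm, "thresholds": list(recon.thresholds),
        "units": recon.units, "provenance": recon.provenance,
        "n_phases": p, "n_bins": b,
    })


def load_recon(path) -> ReconVolume:
    path = Path(path)
    img = nib.load(str(path))
    side = load_json(path.with_suffix(".json"))
    arr = np.asarray(img.dataobj)
    n, _, _, p, b = arr.shape
    data = np.transpose(arr.reshape(n, n, p, b), (2, 3, 0, 1))
    return ReconVolume(data, side["voxel_mm"], tuple(side["thresholds"]),
                       side["units"], side.get("provenance", {}))
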