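"""Stack and mask I/O: multi-page grayscale TIFF plus a JSON metadata sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import ImageStack, RoiMask

__all__ = ["write_stack", "read_stack", "write_mask", "read_mask"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")
    meta = {
        "voxel_pitch_um": stack.voxel_pitch_um,
        "bit_depth": stack.bit_depth,
        "metadata": stack.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path) -> ImageStack:
    path = Path(path)
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        return ImageStack(
            voxels=voxels,
            voxel_pitch_um=float(meta.get("voxel_pitch_um", 1.46)),
            bit_depth=int(meta.get("bit_depth", 8 * voxels.dtype.itemsize)),
            metadata={k: str(v) for k, v in meta.get("metadata", {}).items()},
        )
    return ImageStack(voxels=voxels, bit_depth=8 * voxels.dtype.itemsize)


def write_mask(roi: RoiMask, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (roi.mask.astype(np.uint8) * 255), photometric="minisblack")
    meta = {
        "mode": roi.mode,
        "threshold_used": roi.threshold_used,
        "closing_radius_vox": roi.closing_radius_vox,
        "erosion_radius_vox": roi.erosion_radius_vox,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_mask(path) -> RoiMask:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    sc = _sidecar(path)
    kw = {}
    if sc.exists():
        meta = json.loads(sc.read_text())
        kw = {
            "mode": meta.get("mode", "automatic"),
            "threshold_used": meta.get("threshold_used"),
            "closing_radius_vox": int(meta.get("closing_radius_vox", 0)),
            "erosion_radius_vox": int(meta.get("erosion_radius_vox", 0)),
        }
    return RoiMask(mask=arr > 0, **kw)
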