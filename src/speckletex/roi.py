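"""Region-of-interest masking and in-ROI histogram equalization.

Automatic mode thresholds the preprocessed stack (Otsu unless an explicit
threshold is given), keeps the largest connected component, closes and fills
it into a single hole-free "globule", and erodes the boundary to shed residual
background.  Manual-seed mode refines user-supplied boxes the same way — the
workflow used for tissue explants where shadowing defeats global thresholding.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .types import ImageStack, RoiMask, ValidationError

__all__ = ["mask_roi_auto", "mask_roi_manual", "equalize_in_roi", "threshold_mask"]

Box = Tuple[int, int, int, int, int, int]  # z0, z1, y0, y1, x0, x1 half-open

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def threshold_mask(stack: ImageStack, threshold: Union[float, str] = "auto") -> Tuple[np.ndarray, float]:
    """Raw above-threshold mask (pre-closing stage); returns (mask, threshold)."""
    v = stack.voxels
    if threshold == "auto":
        if v.min() == v.max():
            raise ValidationError("cannot auto-threshold a constant stack")
        thr = float(threshold_otsu(v.ravel()))
    else:
        thr = float(threshold)
    return v > thr, thr


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        raise ValidationError("ROI vanished: nothing above threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def mask_roi_auto(
    stack: ImageStack,
    threshold: Union[float, str] = "auto",
    closing_radius_vox: int = 5,
    erosion_radius_vox: int = 2,
) -> RoiMask:
    """Threshold -> largest component -> ball closing -> hole fill -> erosion."""
    raw, thr = threshold_mask(stack, threshold)
    if not raw.any():
        raise ValidationError("ROI vanished: nothing above threshold")
    core = _largest_component(raw)
    if closing_radius_vox > 0:
        se = ball(closing_radius_vox)
        core = ndimage.binary_closing(core, structure=se, border_value=0)
    core = ndimage.binary_fill_holes(core)
    if erosion_radius_vox > 0:
        core = ndimage.binary_erosion(core, structure=ball(erosion_radius_vox))
    if not core.any():
        raise ValidationError(
            "ROI vanished after erosion; reduce erosion_radius_vox"
        )
    core = _largest_component(core)  # erosion can split; keep the main globule
    return RoiMask(
        mask=core,
        mode="automatic",
        threshold_used=thr,
        closing_radius_vox=closing_radius_vox,
        erosion_radius_vox=erosion_radius_vox,
    )


def mask_roi_manual(
    stack: ImageStack,
    seed_boxes: Sequence[Box],
    threshold: Union[float, str] = "auto",
    closing_radius_vox: int = 5,
    erosion_radius_vox: int = 2,
) -> List[RoiMask]:
    """Refine each seed box with the automatic procedure restricted to the box.

    Boxes are 0-based half-open (z0, z1, y0, y1, x0, x1); masks may overlap.
    """
    if not seed_boxes:
        raise ValidationError("seed_boxes must be nonempty")
    nz, ny, nx = stack.shape
    masks: List[RoiMask] = []
    for i, box in enumerate(seed_boxes):
        z0, z1, y0, y1, x0, x1 = (int(b) for b in box)
        if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValidationError(f"seed box {i} {box} out of bounds for shape {stack.shape}")
        sub = ImageStack(
            voxels=stack.voxels[z0:z1, y0:y1, x0:x1],
            voxel_pitch_um=stack.voxel_pitch_um,
            bit_depth=stack.bit_depth,
            metadata=dict(stack.metadata),
        )
        sub_mask = mask_roi_auto(
            sub,
            threshold=threshold,
            closing_radius_vox=closing_radius_vox,
            erosion_radius_vox=erosion_radius_vox,
        )
        full = np.zeros(stack.shape, dtype=bool)
        full[z0:z1, y0:y1, x0:x1] = sub_mask.mask
        masks.append(
            RoiMask(
                mask=full,
                mode="manual_seed",
                threshold_used=sub_mask.threshold_used,
                closing_radius_vox=closing_radius_vox,
                erosion_radius_vox=erosion_radius_vox,
            )
        )
    return masks


def equalize_in_roi(stack: ImageStack, roi: RoiMask) -> ImageStack:
    """Exact histogram equalization of the in-ROI voxels.

    Voxels are ranked (stable sort, ties broken by scan order) and the ranks
    mapped uniformly onto the quantization range, so the equalized in-ROI
    histogram is flat to within one voxel per level regardless of spikes in
    the input histogram.  A constant ROI maps to a single level.  Out-of-ROI
    voxels are untouched; re-application is a no-op.
    """
    if roi.mask.shape != stack.shape:
        raise ValidationError("ROI shape does not match stack shape")
    v = stack.voxels
    vmax = stack.max_level
    vals = v[roi.mask]
    out = v.copy()
    if vals.min() == vals.max():
        out[roi.mask] = vmax  # degenerate histogram: single level
        return stack.copy_with(out)
    n = vals.size
    order = np.argsort(vals, kind="stable")
    new = np.empty(n, dtype=v.dtype)
    new[order] = ((np.arange(n, dtype=np.int64) * (vmax + 1)) // n).astype(v.dtype)
    out[roi.mask] = new
    return stack.copy_with(out)
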