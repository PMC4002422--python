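"""Core containers shared across the pipeline.

An :class:`ImageStack` is a 3D reflectivity volume indexed ``(z, y, x)`` with z
the axial (depth) direction, quantized to an integer bit depth.  A
:class:`RoiMask` is a boolean volume of the same shape marking the cell-bearing
region that texture features are computed over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = ["ImageStack", "RoiMask", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class ImageStack:
    voxels: np.ndarray  # 3D, (z, y, x), unsigned integer dtype
    voxel_pitch_um: float = 1.46
    bit_depth: int = 8
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValidationError(f"voxels must be a 3D array, got shape {v.shape}")
        if self.bit_depth < 1:
            raise ValidationError(f"bit_depth must be positive, got {self.bit_depth}")
        vmax = (1 << self.bit_depth) - 1
        if v.size and (v.min() < 0 or v.max() > vmax):
            raise ValidationError(
                f"intensities must lie in [0, {vmax}] for bit_depth={self.bit_depth}"
            )
        self.voxels = v

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def max_level(self) -> int:
        return (1 << self.bit_depth) - 1

    def copy_with(self, voxels: np.ndarray, **meta: str) -> "ImageStack":
        md = dict(self.metadata)
        md.update(meta)
        return ImageStack(
            voxels=voxels,
            voxel_pitch_um=self.voxel_pitch_um,
            bit_depth=self.bit_depth,
            metadata=md,
        )


@dataclass
class RoiMask:
    mask: np.ndarray  # boolean, same shape as its stack
    mode: str = "automatic"  # "automatic" | "manual_seed"
    threshold_used: Optional[float] = None
    closing_radius_vox: int = 0
    erosion_radius_vox: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {m.shape}")
        if not m.any():
            raise ValidationError("ROI mask is empty")
        if self.mode not in ("automatic", "manual_seed"):
            raise ValidationError(f"unknown ROI mode {self.mode!r}")
        self.mask = m

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
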