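"""Raw-stack preprocessing: reflection clipping, coverslip detection, tilt
removal and FFT notch filtering of line-scan artifacts.

The pipeline order is fixed — saturation/reflection clean-up, then line
artifact removal, then coverslip detection and tilt removal — matching the
order these nuisances are physically layered into an OCT acquisition.

Coverslip detection operationalizes "high-frequency image component" as the
axial intensity gradient magnitude: the glass interface is the sharpest axial
transition in the stack, so per lateral column the depth of maximal |dI/dz| is
a noisy sample of the interface, and a least-squares plane through those
samples recovers the tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .types import ImageStack, ValidationError

__all__ = [
    "PlaneFit",
    "PreprocessReport",
    "detect_coverslip",
    "remove_tilt",
    "remove_line_artifacts",
    "remove_reflections",
    "preprocess_stack",
    "apply_crop",
]

MAX_TILT_DEG = 30.0


@dataclass
class PlaneFit:
    """z(y, x) = slope_y * (y - cy) + slope_x * (x - cx) + z0, slopes as dz/dvoxel."""

    slope_y: float
    slope_x: float
    z0: float
    center: Tuple[float, float]
    residual_rms: float

    @property
    def tilt_y_deg(self) -> float:
        return float(np.degrees(np.arctan(self.slope_y)))

    @property
    def tilt_x_deg(self) -> float:
        return float(np.degrees(np.arctan(self.slope_x)))


@dataclass
class PreprocessReport:
    coverslip_plane: Optional[PlaneFit] = None
    applied_tilts_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_artifact_frequencies_notched: int = 0
    n_reflection_voxels_replaced: int = 0
    crop_box: Optional[Tuple[int, int, int, int, int, int]] = None
    notes: list = field(default_factory=list)


def detect_coverslip(
    stack: ImageStack, energy_floor_frac: float = 0.05, window: int = 8
) -> PlaneFit:
    """Fit the coverslip plane from per-column axial-gradient-energy depths.

    The glass interface is located coarsely as the depth maximizing the
    laterally averaged squared axial gradient, then refined per column as the
    energy centroid inside ``window`` voxels of that depth — subvoxel and
    symmetric in the ridge's two flanks.  Columns whose in-window peak falls
    below ``energy_floor_frac`` of the global maximum are treated as
    coverslip-free and excluded from the plane fit.
    """
    v = stack.voxels.astype(float)
    grad2 = np.diff(v, axis=0) ** 2  # (nz-1, ny, nx)
    profile = grad2.mean(axis=(1, 2))
    if profile.max() <= 0:
        raise ValidationError("no coverslip found: axial high-frequency energy below floor")
    z_coarse = int(profile.argmax())
    z_lo = max(z_coarse - window, 0)
    z_hi = min(z_coarse + window + 1, grad2.shape[0])
    win = grad2[z_lo:z_hi]
    peak = win.max(axis=0)
    floor = energy_floor_frac**2 * grad2.max()
    good = peak > floor
    if good.sum() < 3:
        raise ValidationError("no coverslip found: axial high-frequency energy below floor")
    # subtract the per-column background (median over the window) so diffuse
    # speckle gradients do not pull the centroid toward the window center
    win = np.maximum(win - np.median(win, axis=0, keepdims=True), 0.0)
    zgrid = (np.arange(z_lo, z_hi) + 0.5)[:, None, None]
    denom = win.sum(axis=0)
    good &= denom > 0
    if good.sum() < 3:
        raise ValidationError("no coverslip found: axial high-frequency energy below floor")
    with np.errstate(invalid="ignore"):
        zidx = (win * zgrid).sum(axis=0) / np.where(denom > 0, denom, 1.0)
    ny, nx = peak.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    A = np.column_stack(
        [yy[good] - cy, xx[good] - cx, np.ones(int(good.sum()))]
    )
    b = zidx[good]
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ coef - b
    return PlaneFit(
        slope_y=float(coef[0]),
        slope_x=float(coef[1]),
        z0=float(coef[2]),
        center=(cy, cx),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def remove_tilt(stack: ImageStack, plane: PlaneFit) -> ImageStack:
    """Axially resample each lateral column so the fitted plane is flat.

    Column (y, x) is shifted by -(plane depth offset) with linear
    interpolation; out-of-domain voxels are zero-filled, dimensions and bit
    depth are unchanged.  Refused for tilts beyond 30 degrees, where a shear
    stops being a good stand-in for a rigid rotation.
    """
    for t in (plane.tilt_y_deg, plane.tilt_x_deg):
        if abs(t) > MAX_TILT_DEG:
            raise ValidationError(f"tilt {t:.1f} deg exceeds the {MAX_TILT_DEG} deg limit")
    nz, ny, nx = stack.shape
    cy, cx = plane.center
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    dz = plane.slope_y * (yy - cy) + plane.slope_x * (xx - cx)  # (ny, nx)
    if np.max(np.abs(dz)) < 0.25:
        # sub-quarter-voxel correction: resampling would only blur
        return stack.copy_with(stack.voxels.copy())
    zz = np.arange(nz, dtype=float)[:, None, None] + dz[None]
    coords = np.broadcast_to(zz, (nz, ny, nx)).reshape(1, -1)
    yyb = np.broadcast_to(yy[None], (nz, ny, nx)).reshape(1, -1)
    xxb = np.broadcast_to(xx[None], (nz, ny, nx)).reshape(1, -1)
    sampled = ndimage.map_coordinates(
        stack.voxels.astype(float),
        np.vstack([coords, yyb, xxb]),
        order=1,
        mode="constant",
        cval=0.0,
    ).reshape(nz, ny, nx)
    vmax = stack.max_level
    out = np.clip(np.rint(sampled), 0, vmax).astype(stack.voxels.dtype)
    return stack.copy_with(out)


def remove_line_artifacts(
    stack: ImageStack, mad_factor: float = 6.0, n_bands: int = 16, r_guard: float = 0.15
) -> Tuple[ImageStack, int]:
    """Per-slice 2D FFT notch filter for fixed-pattern row/column artifacts.

    For every en-face slice, frequency bins lying on the spectral axes (pure
    row- or column-direction frequencies) whose magnitude exceeds
    ``median + mad_factor * MAD`` of their radial band (computed over off-axis
    bins) are attenuated to the band median magnitude, keeping phase.  The DC
    bin and a low-frequency guard disc of normalized radius ``r_guard`` are
    preserved — genuine sample structure (e.g. the coverslip ridge) lives
    there, while line-scan artifacts sit at well-separated frequencies.
    Returns the filtered stack and the number of distinct notched bins.
    """
    v = stack.voxels.astype(float)
    nz, ny, nx = v.shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    r = np.hypot(ky / 0.5, kx / 0.5)  # normalized radius in [0, ~1.4]
    band = np.minimum((r * n_bands).astype(int), n_bands - 1)
    on_axis = ((np.abs(ky) < 1e-12) | (np.abs(kx) < 1e-12)) & (r > r_guard)
    off_axis = ~on_axis & (r > 1e-12)

    # Detect on the median spectrum over slices: the artifact is fixed-pattern
    # (present in every slice) so the median keeps it, while structure confined
    # to a few slices — e.g. resampling boundaries — cannot trigger a notch.
    F = np.fft.fft2(v, axes=(1, 2))
    mag_mean = np.median(np.abs(F), axis=0)
    notch = np.zeros((ny, nx), dtype=bool)
    target = np.ones((ny, nx), dtype=float)
    for b in range(n_bands):
        sel_off = off_axis & (band == b)
        sel_on = on_axis & (band == b)
        if sel_off.sum() < 8 or not sel_on.any():
            continue
        med = np.median(mag_mean[sel_off])
        mad = np.median(np.abs(mag_mean[sel_off] - med)) + 1e-30
        hit = sel_on & (mag_mean > med + mad_factor * mad)
        notch |= hit
        target[hit] = med
    n_notched = int(notch.sum())
    if n_notched == 0:
        return stack.copy_with(stack.voxels.copy()), 0
    scale = np.ones((ny, nx))
    mag = np.abs(F)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_slice_scale = np.where(
            mag > 0, np.minimum(1.0, target[None] / np.maximum(mag, 1e-30)), 1.0
        )
    scale3 = np.where(notch[None], per_slice_scale, 1.0)
    out = np.fft.ifft2(F * scale3, axes=(1, 2)).real
    vmaxq = stack.max_level
    return (
        stack.copy_with(np.clip(np.rint(out), 0, vmaxq).astype(stack.voxels.dtype)),
        n_notched,
    )


def remove_reflections(
    stack: ImageStack, run_length: int = 5
) -> Tuple[ImageStack, int]:
    """Replace saturated axial runs (specular reflections) by the local median.

    Voxels at the maximum quantization level in >= ``run_length`` consecutive
    axial positions are treated as reflection artifacts and replaced by a
    3x3x3 median of the surrounding data.
    """
    v = stack.voxels
    sat = v == stack.max_level
    if not sat.any():
        return stack.copy_with(v.copy()), 0
    # Axial run length at each voxel via cumulative trick
    runs = np.zeros(v.shape, dtype=np.int32)
    acc = np.zeros(v.shape[1:], dtype=np.int32)
    for z in range(v.shape[0]):
        acc = np.where(sat[z], acc + 1, 0)
        runs[z] = acc
    # propagate max run back down the column
    for z in range(v.shape[0] - 2, -1, -1):
        runs[z] = np.where(sat[z] & sat[z + 1], np.maximum(runs[z], runs[z + 1]), runs[z])
    bad = runs >= run_length
    if not bad.any():
        return stack.copy_with(v.copy()), 0
    med = ndimage.median_filter(v, size=3)
    out = np.where(bad, med, v)
    return stack.copy_with(out), int(bad.sum())


def preprocess_stack(
    stack: ImageStack,
    mad_factor: float = 6.0,
    reflection_run: int = 5,
    detect_tilt: bool = True,
) -> Tuple[ImageStack, PreprocessReport]:
    """Full pipeline: reflections -> line artifacts -> coverslip -> tilt."""
    report = PreprocessReport()
    out, n_refl = remove_reflections(stack, run_length=reflection_run)
    report.n_reflection_voxels_replaced = n_refl
    out, n_notched = remove_line_artifacts(out, mad_factor=mad_factor)
    report.n_artifact_frequencies_notched = n_notched
    if detect_tilt:
        try:
            plane = detect_coverslip(out)
        except ValidationError as exc:
            report.notes.append(str(exc))
        else:
            report.coverslip_plane = plane
            out = remove_tilt(out, plane)
            report.applied_tilts_deg = (plane.tilt_y_deg, plane.tilt_x_deg, 0.0)
    nz, ny, nx = out.shape
    # The sample sits below the coverslip interface; the suggested crop box
    # excludes the glass and its ringing so downstream masking sees tissue only.
    z_start = 0
    if report.coverslip_plane is not None:
        z_start = min(int(np.ceil(report.coverslip_plane.z0)) + 3, nz - 1)
    report.crop_box = (z_start, nz, 0, ny, 0, nx)
    return out, report


def apply_crop(stack: ImageStack, crop_box: Tuple[int, int, int, int, int, int]) -> ImageStack:
    z0, z1, y0, y1, x0, x1 = crop_box
    nz, ny, nx = stack.shape
    if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValidationError(f"crop box {crop_box} outside stack bounds {stack.shape}")
    return stack.copy_with(stack.voxels[z0:z1, y0:y1, x0:x1].copy())
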