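"""Synthetic OCT speckle phantoms with a controllable degeneration parameter.

The generator stands in for real OCT recordings of neuronal cultures.  It
produces fully developed speckle: Poisson-placed point scatterers carrying
independent complex phasors are convolved with an effective coherence kernel
(optical PSF broadened by the scatterer extent) and magnitude-detected.  With
many scatterers per resolution cell the real and imaginary parts of the field
are near-Gaussian, so the amplitude histogram is Rayleigh — the textbook
statistics of coherent imaging of unresolved scatterers.

``degeneration`` in [0, 1] drives a monotone texture drift that mimics the
break-up of filamentous organelles into small rounded fragments during early
apoptosis: as degeneration rises the scatterers shrink and densify, so the
speckle grain (and the binary particle-size distribution downstream) gets
finer.  On top of the speckle the generator injects the nuisance structure the
preprocessing stage exists to remove: a bright tilted coverslip plane,
fixed-row sinusoidal line-scan artifacts, and Gaussian background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .types import ImageStack, ValidationError

__all__ = ["PhantomSpec", "generate_phantom", "generate_timecourse"]

# Degeneration endpoints for the scatterer field: radius shrinks, density grows.
_RADIUS_SHRINK = 0.55  # radius at degeneration=1 as a fraction of the base radius
_DENSITY_BOOST = 3.0  # density multiplier at degeneration=1


@dataclass
class PhantomSpec:
    """Parameters of one synthetic stack.

    shape : (z, y, x) voxel counts, each >= 16.
    voxel_pitch_um : isotropic voxel pitch; default 1.46 um.
    scatterer_density : expected scatterer centers per voxel at degeneration 0.
    scatterer_radius_vox : scatterer sphere radius (voxels) at degeneration 0.
    degeneration : 0 = control texture, 1 = maximally fragmented texture.
    psf_sigma_vox : Gaussian PSF sigma per axis (z, y, x).
    coverslip_z_frac : depth of the coverslip plane as a fraction of z extent.
    tilt_deg : (tilt of the plane along y, along x, in-plane spare) in degrees.
    line_artifact_amp : amplitude of the fixed-row sinusoid (intensity units).
    line_artifact_freq : row-direction frequency in cycles per image height.
    background_sigma : Gaussian background noise sigma (intensity units).
    bit_depth : output quantization depth.
    seed : RNG seed; same spec + same seed reproduces the stack bit-for-bit.
    """

    shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_pitch_um: float = 1.46
    scatterer_density: float = 0.06
    scatterer_radius_vox: float = 3.0
    degeneration: float = 0.0
    psf_sigma_vox: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    coverslip_z_frac: float = 0.2
    coverslip_amp: float = 1.0
    coverslip_sigma_z: float = 1.5
    tilt_deg: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    line_artifact_amp: float = 0.0
    line_artifact_freq: int = 12
    background_sigma: float = 0.0
    bit_depth: int = 8
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise ValidationError(f"shape components must be >= 16, got {self.shape}")
        if not (0.0 <= self.degeneration <= 1.0):
            raise ValidationError(f"degeneration must lie in [0, 1], got {self.degeneration}")
        for name in ("scatterer_density", "scatterer_radius_vox", "voxel_pitch_um"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if any(s <= 0 for s in self.psf_sigma_vox):
            raise ValidationError(f"psf_sigma_vox must be positive, got {self.psf_sigma_vox}")
        for name in ("line_artifact_amp", "background_sigma", "coverslip_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.bit_depth < 1:
            raise ValidationError(f"bit_depth must be positive, got {self.bit_depth}")


def degeneration_kernel_sigma(spec: PhantomSpec) -> Tuple[float, float, float]:
    """Effective coherence-kernel sigma per axis at the spec's degeneration.

    The kernel combines the optical PSF with the scatterer extent in
    quadrature; shrinking scatterers shrink the speckle grain.
    """
    d = spec.degeneration
    radius = spec.scatterer_radius_vox * (1.0 - (1.0 - _RADIUS_SHRINK) * d)
    return tuple(
        float(np.sqrt(s**2 + (0.6 * radius) ** 2)) for s in spec.psf_sigma_vox
    )


def _speckle_amplitude(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Fully developed speckle amplitude.

    Poisson-placed point scatterers carry independent complex Gaussian
    phasors; convolution with the effective coherence kernel sums many
    scatterers per resolution cell, so the field's real and imaginary parts
    are near-Gaussian and the amplitude is Rayleigh.  Degeneration shrinks
    the kernel (finer grain) and raises the scatterer density.
    """
    d = spec.degeneration
    density = spec.scatterer_density * (1.0 + (_DENSITY_BOOST - 1.0) * d)
    nz, ny, nx = spec.shape
    n = rng.poisson(density * nz * ny * nx)
    if n == 0:
        return np.zeros(spec.shape, dtype=float)
    centers = (
        rng.integers(0, nz, n),
        rng.integers(0, ny, n),
        rng.integers(0, nx, n),
    )
    re_src = np.zeros(spec.shape, dtype=float)
    im_src = np.zeros(spec.shape, dtype=float)
    amps = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    np.add.at(re_src, centers, amps.real)
    np.add.at(im_src, centers, amps.imag)
    sigma = degeneration_kernel_sigma(spec)
    re = ndimage.gaussian_filter(re_src, sigma, mode="wrap")
    im = ndimage.gaussian_filter(im_src, sigma, mode="wrap")
    return np.hypot(re, im)


def _coverslip(spec: PhantomSpec) -> np.ndarray:
    """Bright one-voxel-thick plane at coverslip depth, tilted by tilt_deg.

    tilt_deg[0] tilts the plane along y (depth increases with y), tilt_deg[1]
    along x.  The third entry would rotate the plane about the axial direction,
    which leaves a plane invariant; it is accepted for interface symmetry.
    """
    nz, ny, nx = spec.shape
    ty, tx = np.tan(np.radians(spec.tilt_deg[0])), np.tan(np.radians(spec.tilt_deg[1]))
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    z0 = spec.coverslip_z_frac * nz
    zplane = z0 + ty * (yy - ny / 2.0) + tx * (xx - nx / 2.0)
    out = np.zeros(spec.shape, dtype=float)
    zz = np.arange(nz)[:, None, None]
    # Gaussian axial profile (coverslip_sigma_z voxels) keeps the plane band-limited.
    out += spec.coverslip_amp * np.exp(
        -0.5 * ((zz - zplane[None]) / spec.coverslip_sigma_z) ** 2
    )
    return out


def coverslip_plane_truth(spec: PhantomSpec) -> Tuple[float, float, float]:
    """Ground-truth plane coefficients (dz/dy, dz/dx, z at field center)."""
    ty = np.tan(np.radians(spec.tilt_deg[0]))
    tx = np.tan(np.radians(spec.tilt_deg[1]))
    return float(ty), float(tx), float(spec.coverslip_z_frac * spec.shape[0])


def generate_phantom(spec: PhantomSpec) -> ImageStack:
    """Render one phantom stack from its spec (deterministic in spec.seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    amp = _speckle_amplitude(spec, rng)
    # Scale speckle into the upper half of the dynamic range, leaving headroom
    # for the coverslip to saturate above it.
    if amp.max() > 0:
        amp = amp / np.percentile(amp[amp > 0], 99.5)
    img = 0.55 * amp + _coverslip(spec)
    if spec.line_artifact_amp > 0:
        ny = spec.shape[1]
        rows = np.sin(2 * np.pi * spec.line_artifact_freq * np.arange(ny) / ny)
        img = img + (spec.line_artifact_amp * rows)[None, :, None]
    if spec.background_sigma > 0:
        img = img + rng.normal(0.0, spec.background_sigma, spec.shape)
    vmax = (1 << spec.bit_depth) - 1
    q = np.clip(np.rint(img * vmax), 0, vmax)
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    meta = {k: str(v) for k, v in spec.metadata.items()}
    meta.setdefault("degeneration", f"{spec.degeneration:.4f}")
    meta.setdefault("seed", str(spec.seed))
    return ImageStack(
        voxels=q.astype(dtype),
        voxel_pitch_um=spec.voxel_pitch_um,
        bit_depth=spec.bit_depth,
        metadata=meta,
    )


def generate_timecourse(
    base: PhantomSpec,
    degeneration_schedule: Sequence[float],
    n_per_point: int,
) -> List[ImageStack]:
    """One batch of ``n_per_point`` stacks per schedule entry.

    Seeds derive deterministically from ``base.seed``; each stack records its
    timepoint index, schedule value and replicate id in metadata.
    """
    if len(degeneration_schedule) == 0:
        raise ValidationError("degeneration_schedule must be nonempty")
    if n_per_point < 1:
        raise ValidationError(f"n_per_point must be >= 1, got {n_per_point}")
    for d in degeneration_schedule:
        if not (0.0 <= d <= 1.0):
            raise ValidationError(f"schedule values must lie in [0, 1], got {d}")
    ss = np.random.SeedSequence(base.seed)
    child_seeds = [int(s) for s in ss.generate_state(len(degeneration_schedule) * n_per_point)]
    stacks: List[ImageStack] = []
    i = 0
    for t, d in enumerate(degeneration_schedule):
        for r in range(n_per_point):
            spec = replace(
                base,
                degeneration=float(d),
                seed=child_seeds[i] % (2**31 - 1),
                metadata={
                    **base.metadata,
                    "timepoint": str(t),
                    "replicate": str(r),
                },
            )
            stacks.append(generate_phantom(spec))
            i += 1
    return stacks
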