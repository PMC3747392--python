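"""Synthetic head-like 3D phantoms and the degradation protocol.

The study data this package targets -- a 3T SPGR brain scan at
256x256x120, 1x1x1.3 mm voxels -- is emulated by a multi-tissue phantom
of nested ellipsoids: a skull shell around a brain compartment holding
two ventricles and an off-centre lesion (the asymmetry gives rotations
an observable signature).  Tissue intensities are fixed documented
constants so class counts are assertable; a low-amplitude smoothed
texture (SD ~2 intensity units) keeps histograms and variance-based
costs non-degenerate without merging the tissue modes.

The degradation chain applied to a reference volume, in order:

1. decimation by an integer factor along one axis (keep every k-th
   slice; no anti-aliasing, reproducing jagged-edge artifacts);
2. rotation about the x-axis (degrees);
3. translation in mm;
4. Gaussian blur of a given radius along the first in-plane axis
   (sigma = radius/2, kernel truncated at +-radius voxels); optionally
   isotropic 2D in-plane instead of 1D;
5. additive Gaussian noise of a given SD (seeded).

The reference study conditions: factor-2 subsampling, 5 degree
x-rotation, (+2, +3, 0) mm translation, noise SD 10, blur radius 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .interpolation import resample_to_grid
from .kernels import KernelSpec
from .transforms import params_to_matrix, DOFParams
from .volume import Volume

#: documented tissue intensity constants (arbitrary units, range 0-250)
TISSUE_INTENSITIES = {
    "background": 0.0,
    "skull": 250.0,
    "brain": 130.0,
    "ventricle": 60.0,
    "lesion": 190.0,
}

#: SD of the smoothed within-tissue texture, in intensity units
TEXTURE_SD = 2.0

_AXES = {"x": 0, "y": 1, "z": 2}


def generate_phantom(shape, spacing=(1.0, 1.0, 1.3), seed: int = 0) -> Volume:
    """Generate a deterministic multi-tissue head-like phantom.

    Parameters
    ----------
    shape
        Grid size per axis, each >= 8.
    spacing
        Voxel size in mm; the ellipsoids are defined in physical
        coordinates so anisotropic grids stay head-shaped.
    seed
        Seed for the within-tissue texture; the same seed reproduces the
        volume bit for bit.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 8 for n in shape):
        raise ValueError(f"each shape component must be >= 8, got {shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive values, got {spacing}")

    idx = np.indices(shape, dtype=np.float64)
    centre = (np.asarray(shape) - 1.0) / 2.0
    half_extent = centre * np.asarray(spacing)  # mm from centre to edge
    # normalized coordinates in [-1, 1] along each axis, in physical units
    u = [(idx[a] - centre[a]) * spacing[a] / half_extent[a] for a in range(3)]

    def ellipsoid(cx, cy, cz, ax, ay, az):
        return ((u[0] - cx) / ax) ** 2 + ((u[1] - cy) / ay) ** 2 + (
            (u[2] - cz) / az
        ) ** 2 <= 1.0

    data = np.full(shape, TISSUE_INTENSITIES["background"])
    head = ellipsoid(0, 0, 0, 0.88, 0.92, 0.90)
    brain = ellipsoid(0, 0, 0, 0.72, 0.76, 0.74)
    data[head] = TISSUE_INTENSITIES["skull"]
    data[brain] = TISSUE_INTENSITIES["brain"]
    for cy in (-0.18, 0.18):
        vent = ellipsoid(0.05, cy, 0.08, 0.16, 0.12, 0.30)
        data[vent & brain] = TISSUE_INTENSITIES["ventricle"]
    lesion = ellipsoid(-0.34, 0.22, -0.25, 0.14, 0.14, 0.16)
    data[lesion & brain] = TISSUE_INTENSITIES["lesion"]

    rng = np.random.default_rng(seed)
    texture = rng.standard_normal(shape)
    for a in range(3):
        texture = gaussian_filter1d(texture, sigma=1.5, axis=a)
    texture *= TEXTURE_SD / texture.std()
    data = data + texture * (data > 0)  # background stays exactly zero

    return Volume(data, spacing)


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the degradation chain (see module docstring)."""

    subsample_axis: str = "z"
    subsample_factor: int = 2
    rotation_deg: float = 5.0
    translation_mm: tuple[float, float, float] = (2.0, 3.0, 0.0)
    noise_sd: float = 10.0
    blur_radius: float = 5.0
    blur_mode: str = "1d"  # "1d": first in-plane axis only; "2d": both
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample_axis not in _AXES:
            raise ValueError(f"subsample_axis must be x, y or z, got {self.subsample_axis!r}")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")
        if self.noise_sd < 0 or self.blur_radius < 0:
            raise ValueError("noise_sd and blur_radius must be >= 0")
        if self.blur_mode not in ("1d", "2d"):
            raise ValueError("blur_mode must be '1d' or '2d'")


def motion_transform(spec: DegradationSpec, v: Volume):
    """The rigid motion of the chain as a world-space affine (forward map),
    rotating about the volume centre then translating."""
    p = DOFParams(
        tx=spec.translation_mm[0], ty=spec.translation_mm[1],
        tz=spec.translation_mm[2], rx=spec.rotation_deg, dof=6,
    )
    return params_to_matrix(p, center=tuple(v.world_center()))


def degrade(v: Volume, spec: DegradationSpec,
            kernel: KernelSpec = KernelSpec("trilinear")) -> Volume:
    """Apply the degradation chain to ``v``; deterministic for a fixed seed."""
    axis = _AXES[spec.subsample_axis]
    k = spec.subsample_factor
    if k > v.shape[axis]:
        raise ValueError(
            f"subsample factor {k} exceeds axis length {v.shape[axis]}"
        )
    # 1. decimation: keep every k-th slice (floor(L/k) of them), spacing
    # multiplied by the factor
    slicer = [slice(None)] * 3
    slicer[axis] = slice(0, (v.shape[axis] // k) * k, k)
    spacing = list(v.spacing)
    spacing[axis] *= k
    out = Volume(v.data[tuple(slicer)].copy(), tuple(spacing), v.origin)

    # 2+3. rigid motion through the shared transform/resampling machinery
    if spec.rotation_deg != 0.0 or any(t != 0.0 for t in spec.translation_mm):
        out = resample_to_grid(out, out, world_map=motion_transform(spec, out),
                               spec=kernel)

    # 4. Gaussian blur, radius given in voxels along the first in-plane axis
    if spec.blur_radius > 0:
        sigma = spec.blur_radius / 2.0
        truncate = spec.blur_radius / sigma  # kernel cut at +-radius voxels
        blur_axes = (0,) if spec.blur_mode == "1d" else (0, 1)
        data = out.data
        for a in blur_axes:
            data = gaussian_filter1d(data, sigma=sigma, axis=a, truncate=truncate)
        out = Volume(data, out.spacing, out.origin)

    # 5. additive Gaussian noise
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out = Volume(out.data + rng.normal(0.0, spec.noise_sd, out.shape),
                     out.spacing, out.origin)
    return out
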