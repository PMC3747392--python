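"""Separable 3D resampling engine.

Sampling a volume at a continuous voxel coordinate ``(x, y, z)`` is the
separable sum over the kernel footprint

    I(x, y, z) = sum_X sum_Y sum_Z I(X, Y, Z) kappa(x-X) kappa(y-Y) kappa(z-Z)

with out-of-volume grid points handled by the kernel spec's boundary
policy.  The inner loop is JIT-compiled with numba; a pure-Python naive
triple-loop reference lives in the test-suite as the independent oracle.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .kernels import KernelSpec
from .transforms import AffineTransform, identity
from .volume import Volume


@njit(cache=True)
def _kval(kid: int, x: float, radius: float) -> float:
    ax = abs(x)
    if kid == 0:  # nearest
        return 1.0 if -0.5 <= x < 0.5 else 0.0
    if kid == 1:  # trilinear 1D factor
        return 1.0 - ax if ax < 1.0 else 0.0
    if kid == 2 or kid == 3 or kid == 4:  # central Lagrange N = 4, 6, 8
        N = 4 if kid == 2 else (6 if kid == 3 else 8)
        half = N // 2
        if ax >= half:
            return 0.0
        u = x - math.floor(x)
        g = -int(math.floor(x))
        w = 1.0
        for j in range(-half + 1, half + 1):
            if j != g:
                w *= (u - j) / (g - j)
        return w
    if kid == 5:  # cubic cardinal B-spline
        if ax < 1.0:
            return 2.0 / 3.0 - ax * ax + 0.5 * ax * ax * ax
        if ax < 2.0:
            c = 2.0 - ax
            return c * c * c / 6.0
        return 0.0
    if kid == 6:  # quartic cardinal B-spline
        if ax < 0.5:
            t2 = ax * ax
            return 115.0 / 192.0 - 5.0 / 8.0 * t2 + 0.25 * t2 * t2
        if ax < 1.5:
            return (
                55.0 + 4.0 * ax * (5.0 + 2.0 * ax * (-15.0 + 2.0 * ax * (5.0 - ax)))
            ) / 96.0
        if ax < 2.5:
            c = 5.0 - 2.0 * ax
            return c * c * c * c / 384.0
        return 0.0
    # Hann-windowed sinc
    if ax >= radius:
        return 0.0
    if x == round(x):  # exact zeros at integer offsets (sin(pi k) != 0 in fp)
        return 1.0 if x == 0.0 else 0.0
    px = math.pi * x
    return math.sin(px) / px * 0.5 * (1.0 + math.cos(math.pi * x / radius))


@njit(cache=True)
def _bidx(i: int, n: int, bid: int) -> int:
    """Map an out-of-range index per boundary policy; -1 means 'reads 0'."""
    if 0 <= i < n:
        return i
    if bid == 0:  # zero
        return -1
    if bid == 1:  # clamp
        return 0 if i < 0 else n - 1
    while i < 0 or i >= n:  # mirror about the edge voxels
        if i < 0:
            i = -i
        if i >= n:
            i = 2 * n - 2 - i
    return i


@njit(cache=True)
def _sample_points(data, pts, kid, radius, bid):
    n0, n1, n2 = data.shape
    M = pts.shape[0]
    out = np.zeros(M)
    hw = int(math.ceil(radius))
    F = 2 * hw
    w0 = np.empty(F)
    w1 = np.empty(F)
    w2 = np.empty(F)
    i0 = np.empty(F, np.int64)
    i1 = np.empty(F, np.int64)
    i2 = np.empty(F, np.int64)
    for m in range(M):
        x = pts[m, 0]
        y = pts[m, 1]
        z = pts[m, 2]
        b0 = int(math.floor(x)) - hw + 1
        b1 = int(math.floor(y)) - hw + 1
        b2 = int(math.floor(z)) - hw + 1
        for a in range(F):
            w0[a] = _kval(kid, x - (b0 + a), radius)
            i0[a] = _bidx(b0 + a, n0, bid)
            w1[a] = _kval(kid, y - (b1 + a), radius)
            i1[a] = _bidx(b1 + a, n1, bid)
            w2[a] = _kval(kid, z - (b2 + a), radius)
            i2[a] = _bidx(b2 + a, n2, bid)
        acc = 0.0
        for a in range(F):
            wa = w0[a]
            if wa == 0.0 or i0[a] < 0:
                continue
            ia = i0[a]
            for b in range(F):
                wab = wa * w1[b]
                if wab == 0.0 or i1[b] < 0:
                    continue
                ib = i1[b]
                for c in range(F):
                    wc = w2[c]
                    if wc == 0.0 or i2[c] < 0:
                        continue
                    acc += wab * wc * data[ia, ib, i2[c]]
        out[m] = acc
    return out


def sample_points(v: Volume, pts: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Sample ``v`` at continuous voxel coordinates ``pts`` of shape (M, 3)."""
    pts = np.ascontiguousarray(pts, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("pts must have shape (M, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("sample points must be finite")
    return _sample_points(
        np.ascontiguousarray(v.data),
        pts,
        spec.kernel_id,
        float(spec.support_radius),
        spec.boundary_id,
    )


def sample(v: Volume, point, spec: KernelSpec) -> float:
    """Sample ``v`` at one continuous voxel coordinate triple."""
    return float(sample_points(v, np.asarray(point, dtype=float).reshape(1, 3), spec)[0])


def inside_mask(v: Volume, pts: np.ndarray, margin: float = 0.0) -> np.ndarray:
    """True where a continuous voxel coordinate lies on the grid proper."""
    pts = np.asarray(pts, dtype=float)
    n = np.asarray(v.shape, dtype=float)
    return np.all((pts >= margin) & (pts <= n - 1 - margin), axis=1)


def _output_grid_world(out_shape, out_spacing, out_origin) -> np.ndarray:
    idx = np.indices(out_shape, dtype=np.float64).reshape(3, -1).T
    return np.asarray(out_origin) + idx * np.asarray(out_spacing)


def resample(
    v: Volume,
    out_shape,
    out_spacing,
    world_map: AffineTransform | None = None,
    spec: KernelSpec = KernelSpec("trilinear"),
    out_origin=None,
) -> Volume:
    """Resample ``v`` onto a new grid through an affine world-space map.

    ``world_map`` maps the *input* volume's world coordinates onto the
    output world frame (identity by default); each output voxel centre is
    pulled back through its inverse and sampled.  The output grid keeps
    the input origin unless ``out_origin`` is given.
    """
    out_shape = tuple(int(n) for n in out_shape)
    out_spacing = tuple(float(s) for s in out_spacing)
    if out_origin is None:
        out_origin = v.origin
    if world_map is None:
        world_map = identity()
    pull_back = np.linalg.inv(world_map.matrix)  # raises LinAlgError if singular
    world = _output_grid_world(out_shape, out_spacing, out_origin)
    world_in = world @ pull_back[:3, :3].T + pull_back[:3, 3]
    vox = v.world_to_voxel(world_in)
    values = sample_points(v, vox, spec)
    return Volume(values.reshape(out_shape), out_spacing, tuple(out_origin))


def resample_to_grid(
    v: Volume,
    like: Volume,
    world_map: AffineTransform | None = None,
    spec: KernelSpec = KernelSpec("trilinear"),
) -> Volume:
    """Resample ``v`` onto the grid of ``like`` (shape, spacing, origin)."""
    return resample(
        v, like.shape, like.spacing, world_map=world_map, spec=spec, out_origin=like.origin
    )
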