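"""Interpolation kernels: central Lagrange, B-spline, windowed sinc.

Every kernel is a 1D weighting function ``kappa(x)`` of the signed offset
(in voxels) between the sample position and a grid point; 3D sampling is
the separable product ``kappa(x - X) * kappa(y - Y) * kappa(z - Z)``.

The eight kernels exposed through :class:`KernelSpec`:

===============  =====================================  ==============
name             description                            support radius
===============  =====================================  ==============
nearest          box kernel (1-point Lagrange)          0.5
trilinear        tent kernel (2-point Lagrange)         1
lagrange4        cubic central Lagrange (4 points)      2
lagrange6        quintic central Lagrange (6 points)    3
lagrange8        heptic central Lagrange (8 points)     4
bspline3         cubic cardinal B-spline                2
bspline4         quartic cardinal B-spline              2.5
windowed_sinc    Hann-windowed sinc                     window radius
===============  =====================================  ==============

The Lagrange kernels are generated from the central Lagrange product
formula (nodes at integers ``-N/2+1 ... N/2``) rather than transcribed
piecewise polynomials; the N=4 kernel is validated against the classical
printed cubic branches in the test-suite.  The B-spline kernels are the
cardinal (uniform-knot) B-splines evaluated by the Cox-de Boor recursion;
closed-form piecewise polynomials are used on the fast path and checked
against the recursion.  B-spline sampling is direct convolution with the
basis (no coefficient prefilter), so it smooths rather than interpolates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

KERNEL_NAMES = (
    "nearest",
    "trilinear",
    "lagrange4",
    "lagrange6",
    "lagrange8",
    "bspline3",
    "bspline4",
    "windowed_sinc",
)

#: kernel name -> integer id used by the compiled sampling core
KERNEL_IDS = {name: i for i, name in enumerate(KERNEL_NAMES)}

_SUPPORT = {
    "nearest": 0.5,
    "trilinear": 1.0,
    "lagrange4": 2.0,
    "lagrange6": 3.0,
    "lagrange8": 4.0,
    "bspline3": 2.0,
    "bspline4": 2.5,
}

BOUNDARY_NAMES = ("zero", "clamp", "mirror")
BOUNDARY_IDS = {name: i for i, name in enumerate(BOUNDARY_NAMES)}


@dataclass(frozen=True)
class KernelSpec:
    """Which interpolation kernel to use, its support and boundary policy.

    ``boundary`` controls off-volume reads: ``clamp`` replicates the edge
    (default, avoids injecting zeros into border costs), ``zero`` pads
    with 0, ``mirror`` reflects about the edge voxel.
    """

    name: str = "trilinear"
    boundary: str = "clamp"
    window_radius: float = 4.0

    def __post_init__(self) -> None:
        if self.name not in KERNEL_IDS:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.boundary not in BOUNDARY_IDS:
            raise ValueError(
                f"unknown boundary {self.boundary!r}; choose from {BOUNDARY_NAMES}"
            )
        if self.name == "windowed_sinc" and self.window_radius < 1:
            raise ValueError("windowed_sinc needs window_radius >= 1")

    @property
    def support_radius(self) -> float:
        if self.name == "windowed_sinc":
            return float(self.window_radius)
        return _SUPPORT[self.name]

    @property
    def kernel_id(self) -> int:
        return KERNEL_IDS[self.name]

    @property
    def boundary_id(self) -> int:
        return BOUNDARY_IDS[self.boundary]

    def __call__(self, x: float) -> float:
        return kernel_value(self, x)


# ------------------------------------------------------------- Lagrange

_LAGRANGE_NS = (1, 2, 4, 6, 8)


def lagrange_kernel(N: int, x: float) -> float:
    """Central Lagrange kernel with ``N`` supporting points at offset ``x``.

    ``N = 1`` is the nearest-neighbour box, ``N = 2`` the linear tent;
    even ``N >= 4`` gives the degree ``N - 1`` piecewise-polynomial kernel
    built from the Lagrange basis on the integer nodes ``-N/2+1 ... N/2``.
    Zero outside ``|x| >= N/2`` (``|x| >= 0.5`` for ``N = 1``).
    """
    if N not in _LAGRANGE_NS:
        raise ValueError(f"unsupported N={N}; choose from {_LAGRANGE_NS}")
    x = float(x)
    if not math.isfinite(x):
        raise ValueError("offset must be finite")
    if N == 1:
        return 1.0 if -0.5 <= x < 0.5 else 0.0
    half = N // 2
    if abs(x) >= half:
        return 0.0
    # decompose the offset as x = u - g with u in [0, 1) the fractional
    # sample position and g the integer node the weight belongs to
    u = x - math.floor(x)
    g = -int(math.floor(x))
    w = 1.0
    for j in range(-half + 1, half + 1):
        if j != g:
            w *= (u - j) / (g - j)
    return w


# ------------------------------------------------------------- B-spline


@dataclass(frozen=True)
class BSplineBasis:
    """An order-``k`` B-spline basis over an open-uniform knot vector.

    Open uniform: the first ``k`` and last ``k`` knots coincide and the
    interior knots are uniformly spaced, so the curve passes through the
    end control points.  The basis is valid on ``[t_k, t_{n+2})`` (1-based
    knot indices), i.e. ``knots[k-1] <= t < knots[n_control]``.
    """

    order: int
    n_control: int
    knots: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("B-spline order k must be >= 2")
        if self.n_control < self.order:
            raise ValueError("need at least k control points")
        if not self.knots:
            object.__setattr__(
                self, "knots", open_uniform_knots(self.order, self.n_control)
            )
        if len(self.knots) != self.order + self.n_control:
            raise ValueError(
                f"knot vector needs k + n_control = {self.order + self.n_control} "
                f"entries, got {len(self.knots)}"
            )
        if any(b < a for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be non-decreasing")

    @property
    def t_min(self) -> float:
        return self.knots[self.order - 1]

    @property
    def t_max(self) -> float:
        return self.knots[self.n_control]


def open_uniform_knots(k: int, n_control: int) -> tuple[float, ...]:
    """Open-uniform knot vector with ``k``-fold end knots, e.g.
    ``(0,0,0,1,2,3,4,4,4)`` for ``k=3, n_control=6``."""
    n_interior = n_control - k
    inner = list(range(1, n_interior + 1))
    last = n_interior + 1
    return tuple([0.0] * k + [float(v) for v in inner] + [float(last)] * k)


def _cox_de_boor(i: int, k: int, t: float, knots) -> float:
    """Two-term Cox-de Boor recursion with the 0/0 := 0 convention.

    ``i`` is the 0-based basis index into ``knots``.
    """
    if k == 1:
        return 1.0 if knots[i] <= t < knots[i + 1] else 0.0
    w = 0.0
    d1 = knots[i + k - 1] - knots[i]
    if d1 > 0.0:
        w += (t - knots[i]) / d1 * _cox_de_boor(i, k - 1, t, knots)
    d2 = knots[i + k] - knots[i + 1]
    if d2 > 0.0:
        w += (knots[i + k] - t) / d2 * _cox_de_boor(i + 1, k - 1, t, knots)
    return w


def bspline_basis(i: int, k: int, t: float, basis: BSplineBasis) -> float:
    """Weight of control point ``i`` (0-based) of order-``k`` basis at ``t``."""
    if k != basis.order:
        raise ValueError(f"order mismatch: {k} vs basis order {basis.order}")
    if not 0 <= i < basis.n_control:
        raise IndexError(f"basis index {i} outside 0..{basis.n_control - 1}")
    if not (basis.t_min <= t < basis.t_max):
        raise ValueError(
            f"t={t} outside the valid range [{basis.t_min}, {basis.t_max})"
        )
    return _cox_de_boor(i, k, t, basis.knots)


def cardinal_bspline(k: int, x: float) -> float:
    """Centred cardinal B-spline of order ``k`` (degree ``k-1``) at offset
    ``x``, evaluated by the Cox-de Boor recursion on uniform integer knots.

    Support ``|x| < k/2``; ``cardinal_bspline(4, 0) == 2/3``.
    """
    if k < 2:
        raise ValueError("order must be >= 2")
    t = x + k / 2.0
    if not (0.0 <= t < k):
        return 0.0
    knots = tuple(float(v) for v in range(k + 1))
    return _cox_de_boor(0, k, t, knots)


def bspline3_kernel(x: float) -> float:
    """Cubic cardinal B-spline, closed form (equals ``cardinal_bspline(4, x)``)."""
    t = abs(float(x))
    if t < 1.0:
        return 2.0 / 3.0 - t * t + 0.5 * t * t * t
    if t < 2.0:
        c = 2.0 - t
        return c * c * c / 6.0
    return 0.0


def bspline4_kernel(x: float) -> float:
    """Quartic cardinal B-spline, closed form (equals ``cardinal_bspline(5, x)``)."""
    t = abs(float(x))
    if t < 0.5:
        t2 = t * t
        return 115.0 / 192.0 - 5.0 / 8.0 * t2 + 0.25 * t2 * t2
    if t < 1.5:
        return (55.0 + 4.0 * t * (5.0 + 2.0 * t * (-15.0 + 2.0 * t * (5.0 - t)))) / 96.0
    if t < 2.5:
        c = 5.0 - 2.0 * t
        return c * c * c * c / 384.0
    return 0.0


# -------------------------------------------------------- windowed sinc


def windowed_sinc_kernel(x: float, radius: float = 4.0) -> float:
    """Hann-windowed sinc: ``sinc(pi x) * 0.5 (1 + cos(pi x / radius))``
    for ``|x| < radius``, zero outside, one at ``x = 0``.

    The window damps the infinite sinc tail; the weights over a footprint
    then sum to 1 only approximately (within 1e-2 for radius >= 4).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    x = float(x)
    if abs(x) >= radius:
        return 0.0
    if x == round(x):  # exact zeros at integer offsets (sin(pi k) != 0 in fp)
        return 1.0 if x == 0.0 else 0.0
    px = math.pi * x
    return math.sin(px) / px * 0.5 * (1.0 + math.cos(math.pi * x / radius))


# ------------------------------------------------------------- dispatch


def kernel_value(spec: KernelSpec, x) -> float | np.ndarray:
    """Evaluate the 1D kernel of ``spec`` at offset(s) ``x`` (voxels)."""
    scalar_fn = _SCALAR_FNS[spec.name]
    if np.ndim(x) == 0:
        return scalar_fn(spec, float(x))
    xs = np.asarray(x, dtype=float)
    return np.array([scalar_fn(spec, float(v)) for v in xs.ravel()]).reshape(xs.shape)


_SCALAR_FNS = {
    "nearest": lambda s, x: lagrange_kernel(1, x),
    "trilinear": lambda s, x: lagrange_kernel(2, x),
    "lagrange4": lambda s, x: lagrange_kernel(4, x),
    "lagrange6": lambda s, x: lagrange_kernel(6, x),
    "lagrange8": lambda s, x: lagrange_kernel(8, x),
    "bspline3": lambda s, x: bspline3_kernel(x),
    "bspline4": lambda s, x: bspline4_kernel(x),
    "windowed_sinc": lambda s, x: windowed_sinc_kernel(x, s.window_radius),
}
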