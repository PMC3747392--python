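"""Multi-resolution 12-DOF affine registration (OAIR).

The optimizer follows the FLIRT-style schedule: both volumes are first
resampled to isotropic voxels, centres of mass are aligned by a pure
translation, and the transform is then refined through pyramid levels
subsampled by factors 8, 4, 2, 1:

* level 8 - exhaustive coarse rotation search over the 5^3 = 125 grid
  {-30, -15, 0, 15, 30} degrees per axis, a 4-DOF (translation + global
  scale) local optimization per configuration, retention of the best 20%
  (125 -> 25), a narrow-range angle refinement, a 7-DOF optimization per
  survivor, and a second 20% retention (25 -> 5);
* level 4 - 7-DOF optimization of each survivor plus rotation (+-6 deg)
  and global-scale (0.8 ... 1.2) perturbations, retaining the top 20%;
* level 2 - the best candidate refined through 7 -> 9 -> 12 DOF (capped
  at the caller's ``max_dof``);
* level 1 - one full-resolution optimization at ``max_dof``.

The local optimizer is a deterministic derivative-free coordinate
descent with step halving; each move is accepted only if it strictly
lowers the cost, so candidate costs are non-increasing along the
surviving lineage.  Cost evaluations use a strided subgrid of the
reference level capped at ``max_cost_samples`` points.

The transform searched, ``A``, maps target world coordinates onto the
reference world frame; the registered image is ``target(A^-1 x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .costs import INFEASIBLE_COST, CostSpec, cost_value
from .interpolation import resample, sample_points
from .kernels import KernelSpec
from .transforms import AffineTransform, DOFParams, params_to_matrix, translation_matrix
from .volume import Volume


class RegistrationError(RuntimeError):
    """Raised when no feasible transform is found at the coarse stage."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class EmptyObjectError(ValueError):
    """No voxel exceeds the centre-of-mass threshold."""


# ---------------------------------------------------------------- COM


def center_of_mass(v: Volume, threshold: float | None = None) -> np.ndarray:
    """World-mm centre of mass of the thresholded binary object.

    The characteristic function is ``data > threshold``; by default the
    threshold sits 10% of the way up the intensity range, which separates
    a head from an (approximately) zero background.
    """
    if threshold is None:
        lo, hi = float(v.data.min()), float(v.data.max())
        threshold = lo + 0.1 * (hi - lo)
    mask = v.data > threshold
    total = mask.sum()
    if total == 0:
        raise EmptyObjectError(f"no voxel above threshold {threshold}")
    idx = np.nonzero(mask)
    com_idx = np.array([idx[a].mean() for a in range(3)])
    return v.voxel_to_world(com_idx)


def com_align(ref: Volume, target: Volume, threshold: float | None = None) -> AffineTransform:
    """Pure translation mapping the target COM onto the reference COM."""
    return translation_matrix(center_of_mass(ref, threshold) - center_of_mass(target, threshold))


# ------------------------------------------------------ grid utilities


def make_isotropic(v: Volume, spec: KernelSpec = KernelSpec("trilinear")) -> Volume:
    """Resample to cubic voxels at the minimum input spacing.

    Axis lengths become ``round(n * spacing / iso)`` so the world extent
    is preserved to within one voxel; an already isotropic volume is
    returned unchanged.
    """
    iso = min(v.spacing)
    if all(s == iso for s in v.spacing):
        return v
    out_shape = tuple(max(2, round(n * s / iso)) for n, s in zip(v.shape, v.spacing))
    return resample(v, out_shape, (iso, iso, iso), spec=spec)


def build_pyramid(
    v: Volume,
    factors: Sequence[int] = (8, 4, 2, 1),
    spec: KernelSpec = KernelSpec("trilinear"),
    min_axis: int = 4,
) -> list[Volume]:
    """One volume per subsampling factor (coarse to fine).

    Levels with factor > 1 are Gaussian-prefiltered (sigma = factor/2
    voxels) before decimation; without the prefilter the coarse levels
    alias and the rotation search destabilizes.  A level whose axes would
    collapse below ``min_axis`` voxels is dropped.
    """
    out: list[Volume] = []
    for f in factors:
        if f == 1:
            out.append(v)
            continue
        shape = tuple(round(n / f) for n in v.shape)
        if min(shape) < min_axis:
            continue  # pyramid too deep for this volume; drop the level
        smoothed = Volume(gaussian_filter(v.data, sigma=f / 2.0), v.spacing, v.origin)
        spacing = tuple(s * f for s in v.spacing)
        out.append(resample(smoothed, shape, spacing, spec=spec))
    return out


def coarse_rotation_grid(values: Sequence[float] = (-30.0, -15.0, 0.0, 15.0, 30.0)):
    """The level-8 rotation search grid: the Cartesian product of
    ``values`` per axis in lexicographic (rx, ry, rz) order."""
    return [(rx, ry, rz) for rx in values for ry in values for rz in values]


# ------------------------------------------------------ candidate sets


@dataclass
class CandidateSet:
    """Ranked (params, cost) minima carried between pyramid levels."""

    entries: list[tuple[DOFParams, float]]
    retained_fraction: float = 0.2

    def __post_init__(self) -> None:
        # stable sort: ties keep insertion order
        self.entries = sorted(self.entries, key=lambda e: e[1])

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def best(self) -> tuple[DOFParams, float]:
        return self.entries[0]


def retain_top_fraction(c: CandidateSet) -> CandidateSet:
    """Keep the best ``ceil(fraction * n)`` entries (at least one)."""
    if not c.entries:
        raise ValueError("cannot retain from an empty candidate set")
    keep = max(1, math.ceil(c.retained_fraction * len(c.entries)))
    return CandidateSet(c.entries[:keep], c.retained_fraction)


# ------------------------------------------------------ local optimizer


@dataclass(frozen=True)
class StepSchedule:
    """Coordinate-descent step sizes (start and floor) per parameter kind.

    Translations in mm, rotations in degrees, scales and shears
    dimensionless.  Steps are halved once no parameter move improves the
    cost, until every step reaches its floor.
    """

    translation: float = 4.0
    rotation: float = 4.0
    scale: float = 0.1
    shear: float = 0.05
    min_translation: float = 0.1
    min_rotation: float = 0.1
    min_scale: float = 0.005
    min_shear: float = 0.005
    max_sweeps_per_tier: int = 2


_PARAM_KIND = {
    "tx": "translation", "ty": "translation", "tz": "translation",
    "rx": "rotation", "ry": "rotation", "rz": "rotation",
    "sx": "scale", "sy": "scale", "sz": "scale",
    "hxy": "shear", "hxz": "shear", "hyz": "shear",
}

#: which parameters each DOF tier varies ("sg" = coupled global scale)
_ACTIVE = {
    3: ("tx", "ty", "tz"),
    4: ("tx", "ty", "tz", "sg"),
    6: ("tx", "ty", "tz", "rx", "ry", "rz"),
    7: ("tx", "ty", "tz", "rx", "ry", "rz", "sg"),
    9: ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz"),
    12: ("tx", "ty", "tz", "rx", "ry", "rz", "sx", "sy", "sz", "hxy", "hxz", "hyz"),
}

_MIN_SCALE = 0.05


def _perturb(p: DOFParams, name: str, delta: float) -> DOFParams:
    if name == "sg":
        s = max(_MIN_SCALE, p.sx + delta)
        f = s / p.sx
        return replace(p, sx=s, sy=max(_MIN_SCALE, p.sy * f), sz=max(_MIN_SCALE, p.sz * f))
    if name.startswith("s"):
        return replace(p, **{name: max(_MIN_SCALE, getattr(p, name) + delta)})
    return replace(p, **{name: getattr(p, name) + delta})


def local_optimize(
    cost_fn: Callable[[DOFParams], float],
    init: DOFParams,
    dof: int,
    steps: StepSchedule = StepSchedule(),
) -> tuple[DOFParams, float, int]:
    """Derivative-free coordinate descent over the ``dof`` parameter tier.

    Only strictly improving moves are accepted, so the cost trace is
    non-increasing; the search is fully deterministic.  Returns the
    optimized params, their cost and the number of cost evaluations.
    """
    if dof not in _ACTIVE:
        raise ValueError(f"dof must be one of {tuple(_ACTIVE)}, got {dof}")
    best_p = init
    best_c = cost_fn(init)
    n_evals = 1
    if not np.isfinite(best_c):
        raise ValueError("cost is not finite at the initial parameters")
    active = _ACTIVE[dof]
    cur = {
        "translation": steps.translation,
        "rotation": steps.rotation,
        "scale": steps.scale,
        "shear": steps.shear,
    }
    floor = {
        "translation": steps.min_translation,
        "rotation": steps.min_rotation,
        "scale": steps.min_scale,
        "shear": steps.min_shear,
    }
    while True:
        for _ in range(steps.max_sweeps_per_tier):
            improved = False
            for name in active:
                kind = "scale" if name == "sg" else _PARAM_KIND[name]
                step = cur[kind]
                for delta in (step, -step):
                    cand = _perturb(best_p, name, delta)
                    c = cost_fn(cand)
                    n_evals += 1
                    if c < best_c:
                        best_p, best_c = cand, c
                        improved = True
                        break
            if not improved:
                break
        if all(cur[k] <= floor[k] * (1 + 1e-9) for k in cur):
            break
        for k in cur:
            cur[k] = max(floor[k], cur[k] / 2.0)
    return best_p, best_c, n_evals


# ------------------------------------------------------ cost evaluation


class _LevelContext:
    """Strided reference-grid cost evaluation at one pyramid level."""

    def __init__(
        self,
        ref: Volume,
        target: Volume,
        cost: CostSpec,
        kernel: KernelSpec,
        center,
        max_samples: int = 20000,
        min_overlap: float = 0.25,
        exclude_above: float | None = None,
    ):
        self.target = target
        self.kernel = kernel
        self.center = tuple(center)
        self.min_overlap = min_overlap
        stride = 1
        while math.prod(math.ceil(n / stride) for n in ref.shape) > max_samples:
            stride += 1
        sub = ref.data[::stride, ::stride, ::stride]
        idx = np.indices(sub.shape, dtype=np.float64).reshape(3, -1).T * stride
        world = ref.voxel_to_world(idx)
        if kernel.name.startswith("bspline"):
            # smoothing kernels blur the target at every evaluation; view
            # the reference through the same kernel so the comparison is
            # symmetric and the cost minimum is not displaced (identical
            # to the raw grid values for interpolating kernels)
            vals = sample_points(ref, idx, kernel)
        else:
            vals = sub.ravel()
        if exclude_above is not None:
            keep = vals <= exclude_above
            world, vals = world[keep], vals[keep]
        self.ref_world = np.ascontiguousarray(world)
        self.ref_values = np.ascontiguousarray(vals)
        self.stride = stride
        self.n_samples = vals.size
        # histogram costs overfit sparse coarse grids (64^2 cells vs a few
        # hundred samples makes any warp look informative), so the bin
        # count shrinks with the sample count: ~sqrt(N/8), floor 8
        eff_bins = min(cost.bins, max(8, round(math.sqrt(self.n_samples / 8.0))))
        self.cost_spec = CostSpec(cost.name, eff_bins) if eff_bins != cost.bins else cost
        self._tshape = np.asarray(target.shape, dtype=float)
        self._torigin = np.asarray(target.origin)
        self._tspacing = np.asarray(target.spacing)
        # freeze histogram ranges so bin edges cannot jitter between
        # transform candidates (per-evaluation min/max would roughen the
        # cost surface and displace its minimum)
        self._range_a = (float(vals.min()), float(vals.max()))
        self._range_b = (float(target.data.min()), float(target.data.max()))
        self.n_evals = 0

    def cost(self, p: DOFParams) -> float:
        self.n_evals += 1
        A = params_to_matrix(p, self.center)
        pull = np.linalg.inv(A.matrix)
        world_t = self.ref_world @ pull[:3, :3].T + pull[:3, 3]
        vox = (world_t - self._torigin) / self._tspacing
        inside = np.all((vox >= 0.0) & (vox <= self._tshape - 1.0), axis=1)
        frac = inside.mean()
        if frac < self.min_overlap:
            return INFEASIBLE_COST
        vals = sample_points(self.target, vox[inside], self.kernel)
        return cost_value(self.cost_spec, self.ref_values[inside], vals,
                          self._range_a, self._range_b)


def evaluate_cost(
    ref: Volume,
    target: Volume,
    params: DOFParams,
    cost: CostSpec = CostSpec("LS"),
    kernel: KernelSpec = KernelSpec("trilinear"),
    max_cost_samples: int = 50000,
    center=None,
) -> float:
    """Cost of ``params`` at full (level-1, isotropic) resolution —
    exactly the objective the final optimization stage minimized."""
    iso_ref = make_isotropic(ref, kernel)
    iso_tgt = make_isotropic(target, kernel)
    if center is None:
        center = iso_ref.world_center()
    ctx = _LevelContext(iso_ref, iso_tgt, cost, kernel, center, max_cost_samples)
    return ctx.cost(params)


# ------------------------------------------------------------ register


@dataclass
class RegistrationResult:
    """Outcome of :func:`register`."""

    final_transform: AffineTransform
    final_params: DOFParams
    final_cost: float
    center: tuple[float, float, float]
    level_traces: list[dict] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return sum(t["n_evaluations"] for t in self.level_traces)


def _level_steps(level: int) -> StepSchedule:
    """Per-level coordinate-descent schedule.

    Translation starts shrink with the level because the incoming
    initialization improves, but rotation starts stay wide (4 deg) down
    to level 2: small rotations are nearly invisible at coarse levels, so
    the fine levels must still be able to hop between nearby orientation
    basins before homing in.
    """
    if level >= 8:
        return StepSchedule(4.0, 4.0, 0.1, 0.05, 1.0, 1.0, 0.025, 0.0125)
    if level == 4:
        return StepSchedule(2.0, 4.0, 0.05, 0.025, 0.5, 0.5, 0.0125, 0.00625)
    if level == 2:
        return StepSchedule(1.0, 4.0, 0.025, 0.0125, 0.1, 0.1, 0.005, 0.005)
    return StepSchedule(0.5, 2.0, 0.01, 0.01, 0.1, 0.1, 0.005, 0.005)


def register(
    ref: Volume,
    target: Volume,
    cost: CostSpec = CostSpec("LS"),
    kernel: KernelSpec = KernelSpec("trilinear"),
    max_dof: int = 12,
    levels: Sequence[int] = (8, 4, 2, 1),
    max_cost_samples: int = 50000,
    coarse_cost_samples: int = 12000,
    min_overlap: float = 0.25,
    com_threshold: float | None = None,
    coarse_values: Sequence[float] = (-30.0, -15.0, 0.0, 15.0, 30.0),
    angle_refine_step: float = 7.5,
    retained_fraction: float = 0.2,
    level4_rot_perturb: float = 6.0,
    level4_scales: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2),
    exclude_above: float | None = None,
) -> RegistrationResult:
    """Run the full multi-resolution affine registration.

    Returns the transform ``A`` (target world -> reference world), its
    parameter vector, and the final cost at level 1, together with
    per-level traces recording evaluation counts and candidate sets.
    Fully deterministic given its inputs.
    """
    if max_dof not in (6, 7, 9, 12):
        raise ValueError(f"max_dof must be 6, 7, 9 or 12, got {max_dof}")
    kern_iso = kernel if kernel.name != "nearest" else KernelSpec("trilinear", kernel.boundary)
    iso_ref = make_isotropic(ref, kern_iso)
    iso_tgt = make_isotropic(target, kern_iso)
    center = tuple(iso_ref.world_center())
    a0 = com_align(iso_ref, iso_tgt, com_threshold)
    t0 = a0.matrix[:3, 3]

    # the coarse rotation search needs enough structure to rank candidate
    # orientations; below ~8 voxels per axis a level carries none, so the
    # registration pyramid drops such levels and starts finer
    pyr_ref = build_pyramid(iso_ref, levels, kern_iso, min_axis=8)
    pyr_tgt = build_pyramid(iso_tgt, levels, kern_iso, min_axis=8)
    # build_pyramid may drop collapsed coarse levels; recover actual factors
    factors = [round(p.spacing[0] / iso_ref.spacing[0]) for p in pyr_ref]
    traces: list[dict] = []

    def ctx_for(i: int) -> _LevelContext:
        # the final level gets a denser cost grid (accuracy limit); the
        # coarse levels only need to rank candidates
        cap = max_cost_samples if factors[i] == 1 else min(coarse_cost_samples, max_cost_samples)
        return _LevelContext(
            pyr_ref[i], pyr_tgt[i], cost, kernel, center,
            cap, min_overlap, exclude_above,
        )

    def optimize_many(ctx, cands, dof, steps):
        out = []
        for p, _ in cands:
            try:
                p2, c2, _ = local_optimize(ctx.cost, p, dof, steps)
            except ValueError:
                continue  # infeasible start (no overlap)
            out.append((p2, c2))
        return out

    # ---------------------------------------------------------- level 8
    i = 0
    f = factors[i]
    ctx = ctx_for(i)
    steps = _level_steps(f)
    base = DOFParams(tx=float(t0[0]), ty=float(t0[1]), tz=float(t0[2]))
    coarse_entries = []
    grid = coarse_rotation_grid(coarse_values)
    for rx, ry, rz in grid:
        init = replace(base, rx=rx, ry=ry, rz=rz)
        try:
            p, c, _ = local_optimize(ctx.cost, init, 4, steps)
        except ValueError:
            coarse_entries.append((init, INFEASIBLE_COST))
            continue
        coarse_entries.append((p, c))
    cs = CandidateSet(coarse_entries, retained_fraction)
    if not np.isfinite(cs.best[1]):
        raise RegistrationError("no feasible transform at the coarse search", traces)
    retained1 = retain_top_fraction(cs)

    # narrow-range angle refinement around each survivor, then 7-DOF
    offsets = (-angle_refine_step, 0.0, angle_refine_step)
    refined = []
    for p, c in retained1.entries:
        best_p, best_c = p, c
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    if dx == dy == dz == 0.0:
                        continue
                    q = replace(p, rx=p.rx + dx, ry=p.ry + dy, rz=p.rz + dz)
                    cq = ctx.cost(q)
                    if cq < best_c:
                        best_p, best_c = q, cq
        refined.append((best_p, best_c))
    seven = CandidateSet(optimize_many(ctx, refined, 7, steps), retained_fraction)
    retained2 = retain_top_fraction(seven)
    traces.append({
        "level": f, "n_evaluations": ctx.n_evals, "n_cost_samples": ctx.n_samples,
        "stage_sizes": (len(cs), len(retained1), len(seven), len(retained2)),
        "candidates": cs.entries, "retained": retained2.entries,
    })
    cands = retained2

    # ---------------------------------------------------------- level 4
    i += 1
    if i < len(factors) and factors[i] != 1:
        f = factors[i]
        ctx = ctx_for(i)
        steps = _level_steps(f)
        optimized = optimize_many(ctx, cands.entries, 7, steps)
        pool = list(optimized)
        for p, _ in optimized:
            for axis in ("rx", "ry", "rz"):
                for sgn in (1.0, -1.0):
                    q = replace(p, **{axis: getattr(p, axis) + sgn * level4_rot_perturb})
                    pool.append((q, ctx.cost(q)))
            for s in level4_scales:
                if s == 1.0:
                    continue
                q = replace(p, sx=p.sx * s, sy=p.sy * s, sz=p.sz * s)
                pool.append((q, ctx.cost(q)))
        cs4 = CandidateSet(pool, retained_fraction)
        cands = retain_top_fraction(cs4)
        traces.append({
            "level": f, "n_evaluations": ctx.n_evals, "n_cost_samples": ctx.n_samples,
            "stage_sizes": (len(cs4), len(cands)),
            "retained": cands.entries,
        })
        i += 1

    # ---------------------------------------------------------- level 2
    dof_chain = [d for d in (7, 9, 12) if d <= max_dof] or [max_dof]
    if i < len(factors) and factors[i] != 1:
        f = factors[i]
        ctx = ctx_for(i)
        steps = _level_steps(f)
        p, c = cands.best
        for d in dof_chain:
            p, c, _ = local_optimize(ctx.cost, p, d, steps)
        cands = CandidateSet([(p, c)], retained_fraction)
        traces.append({
            "level": f, "n_evaluations": ctx.n_evals, "n_cost_samples": ctx.n_samples,
            "stage_sizes": (1,), "retained": cands.entries,
        })
        i += 1

    # ---------------------------------------------------------- level 1
    ctx = ctx_for(len(factors) - 1)
    steps = _level_steps(1)
    p, c = cands.best
    p, c, _ = local_optimize(ctx.cost, p, max_dof, steps)
    traces.append({
        "level": 1, "n_evaluations": ctx.n_evals, "n_cost_samples": ctx.n_samples,
        "stage_sizes": (1,), "retained": [(p, c)],
    })

    return RegistrationResult(
        final_transform=params_to_matrix(p, center),
        final_params=p,
        final_cost=c,
        center=center,
        level_traces=traces,
    )
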