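# Methods

`oair` implements a multi-resolution 12-DOF affine registration stack
for 3D scalar volumes (optimized automatic image registration, the
FLIRT family of schedules), together with the interpolation kernels and
intensity cost functions whose interaction it is designed to study, a
synthetic head phantom with a controlled degradation protocol, and the
statistics used to score upsampling and registration quality.

## Coordinate and transform conventions

Voxel indices are 0-based with samples at voxel centres; the continuous
voxel coordinate equals the index at grid points; world coordinates are
`origin + index * spacing` in mm, axes aligned with the array axes
(x = axis 0, y = axis 1, z = axis 2, the slice direction).  An affine
transform is a 4x4 homogeneous matrix acting on world mm.  The
parameterized family is

    A(p) = T(t) · C · Rz(rz) Ry(ry) Rx(rx) · S(s) · H(h) · C^-1

with `C` recentring rotation/scale/shear on the reference volume's
geometric centre.  Angles are degrees everywhere.  DOF tiers: 3
(translation), 4 (+ global scale), 6 (rigid), 7 (rigid + global scale),
9 (+ per-axis scales), 12 (+ shears).  Rotation composition order and
the centre-of-volume pivot are conventions the registration literature
does not fix uniquely; both are configurable, and `matrix_to_params`
inverts the composition by a sign-fixed QR factorization (valid while
`|ry| < 90°` and scales are positive, always true near alignment).
Reflections are excluded from the family.

## Interpolation kernels

All sampling is the separable product of a 1D kernel kappa(x) over the
footprint.  The Lagrange kernels (N = 4, 6, 8 supporting points, plus
the N = 1 box and N = 2 tent) are generated from the central Lagrange
product formula on integer nodes rather than transcribed as piecewise
polynomials; the N = 4 kernel is verified against the classical printed
cubic branches to 1e-12 in the test-suite.  The B-spline kernels are
cardinal (uniform-knot) B-splines of order 4 and 5; closed-form
piecewise polynomials serve the fast path and are verified against the
Cox–de Boor recursion.  B-spline sampling is direct convolution with
the basis — no coefficient prefilter — so those two kernels smooth
rather than interpolate; this matches the control-point formulation of
the scheme this package studies and reproduces its characteristic
oversmoothing.  The windowed sinc uses a Hann window (default radius 4,
configurable): the window is a design choice, made once, that realizes
the expected ripple behaviour near edges; its footprint weights sum to
1 only within ~1e-2 at radius >= 4, a documented approximation.  Sinc
weights are snapped to exact 0/1 at integer offsets, where floating
`sin(pi k)` would otherwise leak ~1e-16 per tap.

Boundary policies: `clamp` (default, replicates the edge so border
costs are not polluted with zeros), `zero`, `mirror`.  The compiled
(numba) sampling loop is checked against a literal triple-loop Python
oracle to 1e-12 on random volumes, and against scipy's
`map_coordinates` for the trilinear case.

## Cost functions

All four similarity measures are exposed as costs minimized at
alignment:

* **LS** — mean squared intensity difference.
* **NCC** — `1 - rho`, Pearson correlation at zero offset (the raw
  un-normalized cross-correlation sum is exposed separately; it is not
  scale-invariant and is not used as a cost).
* **CR** — `1 - eta^2`, where `eta^2` is the fraction of the moving
  image's variance explained by conditioning on the reference intensity
  class (Roche's correlation ratio); this is the only form bounded in
  [0, 1].  Note a CR of an identical continuous-valued pair retains the
  within-bin quantization variance, so its floor is small but nonzero.
* **NMI** — `1 - MI/max(H_A, H_B)`.  The plain mutual information sum
  (nats) is reported separately; the normalized form is what is bounded
  in [0, 1].

Histogram-based measures default to 64 equal-width bins, a standard
compromise for 1e5–1e7 voxel volumes.  Inside the optimizer two further
choices matter and were the subject of explicit debugging:

* **Frozen bin edges.**  Bin edges are fixed per pyramid level from the
  reference samples and the whole moving volume.  Recomputing edges from
  the per-evaluation overlap min/max (the naive reading of "rescale one
  range onto the other") makes every histogram cost rough — kernel
  overshoot jitters the extrema, shifting all edges — and measurably
  displaces the NMI minimum by ~0.5 degrees on the phantom.
* **Sample-adaptive bin count.**  At a coarse level a few hundred
  samples spread over 64^2 cells make any warp look informative; the
  bin count therefore shrinks as ~sqrt(N/8) (floor 8) with the number
  of cost samples.

Cost evaluation is restricted to reference voxels whose pull-back lands
inside the moving volume; if the overlap fraction drops below 0.25 the
cost is an infinite sentinel, rejecting degenerate transforms.  For the
B-spline (smoothing) kernels the reference samples are themselves viewed
through the kernel, since otherwise the moving image is blurred once
more than the reference at every evaluation and the cost minimum is
displaced (for interpolating kernels this is an exact no-op).

## Registration schedule

1. Both volumes are resampled to cubic voxels at their minimum spacing
   (`make_isotropic`; axis lengths `round(n * spacing / iso)`).
2. Centres of mass (intensity threshold, default 10% of the range) are
   aligned by a pure translation.
3. A Gaussian-prefiltered pyramid (sigma = factor/2 voxels before
   decimation) is built at factors 8, 4, 2, 1.  The prefilter is a
   deliberate addition: plain decimation aliases and destabilizes the
   coarse rotation ranking.  Levels whose axes would fall below 8
   voxels are dropped from the *registration* pyramid (below ~8^3 a
   blurred level cannot rank candidate orientations at all; the
   standalone `build_pyramid` keeps the documented floor of 4).
4. Coarsest level: the cost is evaluated over the 125-point rotation
   grid {-30, -15, 0, 15, 30}^3 with a 4-DOF (translation + global
   scale) local optimization per configuration; the best 20% (125 → 25)
   are kept; each survivor's angles are refined over a +-7.5 degree,
   7.5-degree-step neighbourhood (the narrow-range second pass; its
   extent is a documented guess, configurable) and optimized at 7-DOF;
   the best 20% (25 → 5) move on.
5. Next level: each survivor is optimized at 7-DOF, then perturbed by
   +-6 degrees per rotation axis and global scales {0.8, 0.9, 1.0, 1.1,
   1.2} ("+-6 degrees" is one of two possible readings of the published
   perturbation; the offsets reading was chosen and is configurable);
   the pooled set is pruned to its top 20%.
6. Half resolution: the single best candidate is refined through
   7 → 9 → 12 DOF, capped at the caller's `max_dof`.
7. Full resolution: one optimization at `max_dof`; the result and its
   level-1 cost are returned with per-level traces.

The local optimizer is deterministic derivative-free coordinate descent
with step halving, accepting only strict improvements (so candidate
costs are non-increasing along the surviving lineage).  Step schedule:
translations start at 4 mm at the coarsest level, shrinking to 0.5 mm
at level 1 with a 0.1 mm floor; scales 0.1 → 0.005; shears 0.05 →
0.005.  Rotation steps stay wide (4 degrees) down to level 2 with a
2-degree start at level 1: small rotations are nearly invisible at
blurred coarse levels, so the fine levels must still be able to hop
between nearby orientation basins before homing in — with fine-level
rotation starts of 1 degree or less the search can lock onto a
neighbouring basin a few degrees away.

Costs during optimization are evaluated on a strided subgrid of the
reference level capped at `max_cost_samples` points (50 000 at level 1,
12 000 at coarser levels by default) — the standard subsampled-cost
device; the stride is the smallest integer bringing the grid under the
cap.  Registration contains no randomness: results are bit-reproducible
given inputs.  An optional intensity-threshold mask (`exclude_above`)
reproduces skull masking; it is off by default for phantoms.  The
kernel used during optimization and the kernel used for the final
reformat are independently selectable.

## Phantom and degradation protocol

The phantom emulates the study's scan geometry (default 1 x 1 x 1.3 mm
voxels) with nested ellipsoids in physical coordinates: background 0,
skull shell 250, brain 130, two ventricles 60, and an off-centre lesion
190 (fixed documented constants, so class counts are assertable).  The
lesion and ventricles break the symmetry that would otherwise make
rotations unobservable.  A low-amplitude smoothed Gaussian texture
(SD 2, correlation length ~1.5 voxels, seeded) keeps histograms and
variance-based costs non-degenerate without merging tissue modes; the
background stays exactly zero.

The degradation chain applies, in order: factor-k decimation along one
axis (keep every k-th slice, `floor(L/k)` of them, spacing times k — no
anti-aliasing, reproducing the jagged-edge artifacts of plain
subsampling), rotation about x and translation through the shared
transform/resampling machinery (trilinear by default), a Gaussian blur
of radius r voxels along the first in-plane axis (sigma = r/2, kernel
truncated at +-r; the radius-to-sigma convention is a documented choice,
and a `blur_mode="2d"` switch covers the isotropic in-plane reading),
and additive Gaussian noise (seeded).  Reference study conditions:
factor 2, 5 degrees, (2, 3, 0) mm, noise SD 10, blur radius 5.

What the phantom does *not* emulate: MR acquisition physics (bias
fields, coil profiles, k-space artifacts), realistic anatomy, partial
volume effects at acquisition, or intensity non-stationarity.  Passing
tests therefore demonstrate the correctness and internal behaviour of
the algorithms under controlled geometry, not clinical performance.

## Evaluation statistics

MSE is the voxel mean of squared differences on a shared grid; PSNR is
`20 log10(MAX/RMSE)` with MAX the reference maximum by default
(configurable to a fixed dynamic range); identical volumes return a
positive-infinity sentinel with a warning.  Entropies are in bits.
Shannon entropy bins each volume over its own range by default; for
comparisons between processed variants of one image (the
blur-reduces-entropy check) a fixed common range must be passed,
because blurring shrinks the range and per-volume binning would hide
the histogram sharpening the comparison is after.  A constant volume
has entropy exactly 0.  Joint entropy comes from the shared joint
histogram; it equals the marginal entropy for identical images and
grows with misregistration.

## Experiment drivers and problem sizes

`run_upsampling_experiment` uses decimation-only degradation so the
measured error is pure interpolation error (motion and noise belong to
the registration experiment; the restoration step that would precede a
fair noisy comparison is out of scope).  `run_registration_experiment`
uses the full chain.  Desk-scale defaults are 64^3 phantoms, for which
the full 7-kernel x 4-cost registration grid completes in minutes; the
256 x 256 x 120 study-scale geometry runs through the same code but is
not part of the routine suite.  Statistical comparisons are reported as
descriptive spreads and rankings, not significance tests — the
replicate structure a P-value would need is not part of the design.

## Known limitations

* Coordinate descent is a local method; the coarse search makes it
  robust to the study's motion range (+-30 degrees), but pathological
  cases (near-symmetric objects, very small volumes) can still converge
  to a neighbouring basin.
* B-spline sampling without prefilter is intentionally non-interpolating;
  an optional prefilter flag is provided but excluded from the standard
  comparisons.
* The windowed-sinc partition-of-unity defect (~1e-2) slightly biases
  constant regions at small radii.
* Histogram costs on very small overlaps (coarse levels of small
  volumes) remain noisy even with adaptive binning; the retention
  mechanism, not any single coarse cost value, carries the information.
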