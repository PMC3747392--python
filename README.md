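# oair

Multi-resolution 3D affine registration for volumetric (MRI-style)
images, built to study a specific question: **how much do the choice of
interpolation kernel and the choice of intensity cost function each
matter to registration and upsampling quality?**

Anisotropic clinical 3D acquisitions (e.g. 1 x 1 x 1.3 mm voxels) must
be resampled — during upsampling to an isotropic grid, and repeatedly
inside any intensity-based registration loop.  This package implements
the full stack needed to quantify the effect of that resampling:

* **Eight interpolation kernels** — nearest neighbour, trilinear,
  central Lagrange with N = 4/6/8 supporting points (cubic, quintic,
  heptic), cubic and quartic cardinal B-splines (direct convolution,
  no prefilter), and Hann-windowed sinc — behind one separable,
  numba-compiled 3D sampling engine.
* **Four cost functions**, all exposed as minimized costs: least
  squares (LS), correlation ratio (CR = 1 − η²), normalized
  cross-correlation (NCC = 1 − ρ), and normalized mutual information
  (NMI = 1 − MI/max(H_A, H_B)), with the joint-histogram machinery they
  share.
* **The OAIR optimizer** (FLIRT-style): isotropic resampling,
  centre-of-mass initialization, then pyramid levels subsampled by
  8/4/2/1 — an exhaustive 125-configuration coarse rotation search
  ({−30, −15, 0, 15, 30}° per axis) with 4-DOF local optimization per
  configuration, best-20% candidate retention (125 → 25 → 5),
  perturbation-guarded 7-DOF refinement, and a progressive 7 → 9 → 12
  DOF finish.
* **A synthetic head phantom** (nested ellipsoids, five fixed tissue
  intensities, seeded texture) and the degradation protocol used by the
  experiments: factor-2 decimation along a chosen axis, 5° x-rotation,
  (2, 3, 0) mm translation, Gaussian blur (radius 5) and Gaussian noise
  (SD 10).
* **Evaluation statistics**: 3D MSE, PSNR, Shannon entropy, joint
  entropy, subtraction images, and tidy experiment reports.

See `docs/methods.md` for conventions, numerical choices and
limitations.

## Worked example

Recover a known rigid motion from a degraded phantom:

```python
from oair import (CostSpec, DegradationSpec, KernelSpec, degrade,
                  generate_phantom, matrix_to_params, register)

ref = generate_phantom((64, 64, 64), spacing=(1, 1, 1.3), seed=1)
moved = degrade(ref, DegradationSpec("z", 1, rotation_deg=5.0,
                                     translation_mm=(2.0, 3.0, 0.0),
                                     noise_sd=0.0, blur_radius=0.0))
res = register(ref, moved, cost=CostSpec("NMI"),
               kernel=KernelSpec("windowed_sinc"))
rec = matrix_to_params(res.final_transform.inverse(), res.center)
print(f"rotation x: {rec.rx:.3f} deg   translation: "
      f"({rec.tx:.3f}, {rec.ty:.3f}, {rec.tz:.3f}) mm")
```

```
rotation x: 4.900 deg   translation: (2.002, 3.000, -0.019) mm
```

The 5° rotation and (2, 3, 0) mm translation are recovered to 0.1° and
~0.02 mm.  `res.level_traces` records the candidate sets: 125 coarse
configurations pruned to 25 and then 5 before the fine levels refine
the single survivor.

The numbered drivers under `analysis/` run the two experiments end to
end and write CSV tables under `results/`:

```sh
python analysis/01_make_phantom.py            # reference + degraded volumes
python analysis/02_upsampling_comparison.py   # 8 kernels x 3 axes x 3 sizes
python analysis/03_registration_comparison.py # 7 kernels x 4 costs
```

On a 64³ phantom (seed 1) the upsampling table ranks trilinear best
(MSE 349.6, about half of nearest neighbour's 703.6) with the B-splines
between them, and the registration table shows the MSE spread across
the four costs (44.6 at fixed kernel) is about half the spread across
kernels (97.2 at fixed cost): the interpolation choice matters, the
cost choice much less.

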