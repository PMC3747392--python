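"""The two phantom experiments: upsampling comparison and the
interpolation x cost-function registration comparison.

``run_upsampling_experiment`` mirrors the classic low-resolution
protocol: the reference phantom is decimated by a factor along each of
the three axes in turn, upsampled back onto the reference grid with each
kernel, and scored by MSE/PSNR against the reference.  Decimation-only
degradation is used here so the measured error is interpolation error
(motion, noise and blur belong to the registration experiment, whose
restoration step is out of scope).

``run_registration_experiment`` degrades the phantom with the full
chain (subsampling, rotation, translation, blur, noise), registers it
back with every requested (kernel, cost) pair, reformats with the same
kernel, and records MSE, PSNR, joint entropy, all four cross-evaluated
similarity values and the recovered DOF parameters.

Reports are byte-reproducible given an identical config: every source of
randomness is derived from the config seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .costs import (
    CostSpec,
    correlation_ratio,
    joint_histogram,
    mutual_information,
    nmi,
    normalized_cross_correlation,
)
from .evaluation import EvaluationReport, joint_entropy, mse_3d, psnr
from .interpolation import resample_to_grid
from .kernels import KERNEL_NAMES, KernelSpec
from .phantom import DegradationSpec, degrade, generate_phantom
from .registration import RegistrationError, register
from .transforms import matrix_to_params

#: the seven kernels compared during registration (nearest excluded)
REGISTRATION_KERNELS = tuple(k for k in KERNEL_NAMES if k != "nearest")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration shared by both experiments."""

    phantom_shape: tuple[int, int, int] = (64, 64, 64)
    phantom_spacing: tuple[float, float, float] = (1.0, 1.0, 1.3)
    phantom_seed: int = 0
    subsample_axes: tuple[str, ...] = ("z", "x", "y")
    subsample_factor: int = 2
    rotation_deg: float = 5.0
    translation_mm: tuple[float, float, float] = (2.0, 3.0, 0.0)
    noise_sd: float = 10.0
    blur_radius: float = 5.0
    kernels: tuple[str, ...] = KERNEL_NAMES
    costs: tuple[str, ...] = ("CR", "LS", "NCC", "NMI")
    max_dof: int = 12
    bins: int = 64
    max_cost_samples: int = 50000

    def degradation(self, axis: str, motion: bool = True, noise: bool = True) -> DegradationSpec:
        return DegradationSpec(
            subsample_axis=axis,
            subsample_factor=self.subsample_factor,
            rotation_deg=self.rotation_deg if motion else 0.0,
            translation_mm=self.translation_mm if motion else (0.0, 0.0, 0.0),
            noise_sd=self.noise_sd if noise else 0.0,
            blur_radius=self.blur_radius if noise else 0.0,
            seed=self.phantom_seed + 1,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("phantom_shape", "phantom_spacing", "translation_mm",
                    "subsample_axes", "kernels", "costs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def run_upsampling_experiment(cfg: ExperimentConfig) -> EvaluationReport:
    """Decimate along each axis, upsample back with each kernel, score.

    One row per (axis, kernel) pair with MSE and PSNR against the
    reference phantom.
    """
    ref = generate_phantom(cfg.phantom_shape, cfg.phantom_spacing, cfg.phantom_seed)
    report = EvaluationReport(metadata={"experiment": "upsampling", **asdict(cfg)})
    for axis in cfg.subsample_axes:
        spec = cfg.degradation(axis, motion=False, noise=False)
        low = degrade(ref, spec)
        for kname in cfg.kernels:
            kernel = KernelSpec(kname)
            up = resample_to_grid(low, ref, spec=kernel)
            m = mse_3d(ref, up)
            report.add(
                axis=axis,
                kernel=kname,
                low_shape=low.shape,
                mse=m,
                psnr_db=psnr(ref, up),
                psnr_max=float(ref.data.max()),
            )
    return report


def run_registration_experiment(cfg: ExperimentConfig) -> EvaluationReport:
    """Register the degraded-and-moved phantom back for every
    (kernel, cost) pair and score the reformatted result."""
    ref = generate_phantom(cfg.phantom_shape, cfg.phantom_spacing, cfg.phantom_seed)
    axis = cfg.subsample_axes[0]
    spec = cfg.degradation(axis)
    target = degrade(ref, spec)
    unregistered = resample_to_grid(target, ref, spec=KernelSpec("trilinear"))
    je_unreg = joint_entropy(ref, unregistered, cfg.bins)
    report = EvaluationReport(metadata={
        "experiment": "registration", "joint_entropy_unregistered": je_unreg,
        **asdict(cfg),
    })
    kernels = [k for k in cfg.kernels if k != "nearest"]
    for kname in kernels:
        kernel = KernelSpec(kname)
        for cname in cfg.costs:
            cost = CostSpec(cname, cfg.bins)
            row = {"kernel": kname, "cost": cname, "axis": axis}
            try:
                result = register(
                    ref, target, cost=cost, kernel=kernel,
                    max_dof=cfg.max_dof, max_cost_samples=cfg.max_cost_samples,
                )
            except RegistrationError as err:
                row["failed"] = str(err)
                report.add(**row)
                continue
            registered = resample_to_grid(target, ref, result.final_transform, kernel)
            rec = matrix_to_params(result.final_transform.inverse(), result.center)
            m = mse_3d(ref, registered)
            row.update(
                mse=m,
                psnr_db=psnr(ref, registered),
                psnr_max=float(ref.data.max()),
                joint_entropy=joint_entropy(ref, registered, cfg.bins),
                cr=correlation_ratio(ref, registered, cfg.bins),
                mi=mutual_information(joint_histogram(ref, registered, cfg.bins)),
                nmi=nmi(ref, registered, cfg.bins),
                ncc=1.0 - normalized_cross_correlation(ref, registered),
                final_cost=result.final_cost,
                recovered_rx=rec.rx, recovered_ry=rec.ry, recovered_rz=rec.rz,
                recovered_tx=rec.tx, recovered_ty=rec.ty, recovered_tz=rec.tz,
                n_evaluations=result.n_evaluations,
            )
            report.add(**row)
    return report
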