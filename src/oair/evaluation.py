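"""Registration / upsampling quality statistics.

MSE and PSNR quantify intensity agreement on a shared grid; Shannon and
joint entropy quantify the information content and dispersion of the
(joint) intensity histogram.  Entropies are reported in bits (log base
2) so a volume with 2^k equally populated intensity classes has entropy
exactly k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .costs import DEFAULT_BINS, joint_histogram
from .volume import Volume, require_same_grid


def mse_3d(R: Volume, I: Volume) -> float:
    """Mean squared error sum (R - I)^2 / (n m l) over the shared grid."""
    require_same_grid(R, I)
    d = R.data - I.data
    return float(np.mean(d * d))


def psnr(R: Volume, I: Volume, max_value: float | None = None) -> float:
    """Peak signal-to-noise ratio 20 log10(MAX / RMSE) in dB.

    ``MAX`` defaults to the reference volume's maximum intensity; pass a
    fixed dynamic range (e.g. 255) to override.  Identical volumes give
    +inf with a warning.
    """
    m = mse_3d(R, I)
    if max_value is None:
        max_value = float(R.data.max())
    if m == 0.0:
        warnings.warn("PSNR of identical volumes is unbounded", RuntimeWarning)
        return math.inf
    return 20.0 * math.log10(max_value / math.sqrt(m))


def shannon_entropy(v: Volume, bins: int = DEFAULT_BINS,
                    range_: tuple[float, float] | None = None) -> float:
    """Shannon entropy -sum p log2 p of the binned intensity histogram.

    A constant volume carries no information and returns exactly 0.  By
    default the bins span the volume's own (min, max); pass ``range_`` to
    bin on a fixed dynamic range instead — required when entropies of
    processed variants of one image are compared (blurring, for example,
    shrinks the range, and letting the bins shrink with it would hide the
    histogram sharpening the comparison is after).  Values outside a
    fixed range are clipped into the edge bins.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = v.data.ravel()
    lo, hi = (float(x.min()), float(x.max())) if range_ is None else map(float, range_)
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def joint_entropy(R: Volume, I: Volume, bins: int = DEFAULT_BINS) -> float:
    """Joint Shannon entropy (bits) of the two volumes' joint histogram.

    Dispersion of the joint histogram grows with misregistration, so this
    value increases as alignment degrades.
    """
    h = joint_histogram(R, I, bins, on_degenerate="single-bin")
    p = h.joint_prob
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def subtraction_image(R: Volume, I: Volume) -> Volume:
    """Voxel-wise difference R - I with the reference metadata."""
    require_same_grid(R, I)
    return Volume(R.data - I.data, R.spacing, R.origin)


@dataclass
class EvaluationReport:
    """Tidy per-condition rows plus the experiment metadata to re-run them."""

    rows: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def add(self, **row: Any) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        import json

        payload = {"metadata": self.metadata, "rows": self.rows}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    def check_psnr_consistency(self, tol_db: float = 1e-9) -> bool:
        """Each PSNR row must match its MSE row through the PSNR formula."""
        for row in self.rows:
            if "mse" in row and "psnr_db" in row and "psnr_max" in row:
                if not math.isfinite(row["psnr_db"]):
                    if row["mse"] != 0.0:
                        return False
                    continue
                expect = 20.0 * math.log10(row["psnr_max"] / math.sqrt(row["mse"]))
                if abs(expect - row["psnr_db"]) > tol_db:
                    return False
        return True
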