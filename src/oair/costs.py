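"""Intensity cost functions: LS, CR, NCC, NMI, and joint histograms.

All four similarity measures are exposed as *costs*, constructed so that
lower is better and the minimum sits at perfect alignment:

* ``LS``  - mean squared intensity difference;
* ``CR``  - 1 - eta^2, the correlation-ratio cost (eta^2 is the fraction
  of the input image's variance explained by conditioning on the
  reference intensity class);
* ``NCC`` - 1 - rho, with rho the zero-mean unit-variance Pearson
  correlation at zero offset;
* ``NMI`` - 1 - MI/max(H_A, H_B); the mutual information itself
  (in nats) and the raw cross-correlation sum are exposed separately.

The histogram-based measures (CR, NMI) bin each image's intensity range
linearly into ``bins`` equal-width classes (default 64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume, require_same_grid

DEFAULT_BINS = 64

COST_NAMES = ("LS", "CR", "NCC", "NMI")

#: sentinel returned when the overlap between images is too small to trust
INFEASIBLE_COST = np.inf


class DegenerateRangeError(ValueError):
    """An image has zero intensity range where a spread is required."""


@dataclass(frozen=True)
class CostSpec:
    """Which cost to minimize and how to bin the histogram-based ones."""

    name: str = "LS"
    bins: int = DEFAULT_BINS

    def __post_init__(self) -> None:
        if self.name not in COST_NAMES:
            raise ValueError(f"unknown cost {self.name!r}; choose from {COST_NAMES}")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass(frozen=True)
class JointHistogram:
    """2D binned co-occurrence counts of two images' intensities."""

    counts: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    n_voxels: int

    @property
    def joint_prob(self) -> np.ndarray:
        return self.counts / self.n_voxels

    @property
    def marginal_a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "JointHistogram":
        return JointHistogram(self.counts.T.copy(), self.edges_b, self.edges_a,
                              self.n_voxels)


def _as_values(v) -> np.ndarray:
    return v.data.ravel() if isinstance(v, Volume) else np.asarray(v, dtype=float).ravel()


def _paired_values(R, I) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(R, Volume) and isinstance(I, Volume):
        require_same_grid(R, I)
    a, b = _as_values(R), _as_values(I)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty sample")
    return a, b


def _bin_edges(x: np.ndarray, bins: int, on_degenerate: str,
               range_: tuple[float, float] | None = None) -> np.ndarray:
    lo, hi = (float(x.min()), float(x.max())) if range_ is None else map(float, range_)
    if hi <= lo:
        if on_degenerate == "single-bin":
            # documented fallback: a constant image occupies one bin
            hi = lo + 1.0
        else:
            raise DegenerateRangeError("constant image: zero intensity range")
    return np.linspace(lo, hi, bins + 1)


# ----------------------------------------------------------- measures


def least_squares(R, I) -> float:
    """Mean of the squared intensity difference over the shared grid."""
    a, b = _paired_values(R, I)
    d = a - b
    return float(np.mean(d * d))


def joint_histogram(R, I, bins: int = DEFAULT_BINS,
                    on_degenerate: str = "error",
                    range_a: tuple[float, float] | None = None,
                    range_b: tuple[float, float] | None = None) -> JointHistogram:
    """Joint co-occurrence histogram after rescaling each intensity range
    linearly onto the ``bins`` equal-width classes.

    By default each image's own (min, max) spans the bins; pass
    ``range_a``/``range_b`` to freeze the edges instead (values outside a
    fixed range are clipped into the edge bins) — required when the same
    binning must be comparable across repeated evaluations.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a, b = _paired_values(R, I)
    ea = _bin_edges(a, bins, on_degenerate, range_a)
    eb = _bin_edges(b, bins, on_degenerate, range_b)
    if range_a is not None:
        a = np.clip(a, ea[0], ea[-1])
    if range_b is not None:
        b = np.clip(b, eb[0], eb[-1])
    counts, _, _ = np.histogram2d(a, b, bins=[ea, eb])
    return JointHistogram(counts.astype(np.int64), ea, eb, a.size)


def mutual_information(h: JointHistogram) -> float:
    """MI in nats: sum P_ij log(P_ij / (p_i p_j)) over non-empty cells."""
    if h.n_voxels <= 0 or h.counts.sum() == 0:
        raise ValueError("empty joint histogram")
    p = h.joint_prob
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pa @ pb)[nz])))


def _marginal_entropy_nats(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def nmi(R, I, bins: int = DEFAULT_BINS,
        range_a=None, range_b=None) -> float:
    """Normalized mutual information MI/max(H_A, H_B), in [0, 1]."""
    h = joint_histogram(R, I, bins, range_a=range_a, range_b=range_b)
    mi = mutual_information(h)
    ha = _marginal_entropy_nats(h.marginal_a / h.n_voxels)
    hb = _marginal_entropy_nats(h.marginal_b / h.n_voxels)
    denom = max(ha, hb)
    if denom == 0.0:
        return 1.0  # both images constant within binning: trivially aligned
    return mi / denom


def normalized_mutual_information(R, I, bins: int = DEFAULT_BINS,
                                  range_a=None, range_b=None) -> float:
    """NMI as a cost: 1 - MI/max(H_A, H_B), minimized at alignment."""
    return 1.0 - nmi(R, I, bins, range_a, range_b)


def cross_correlation(R, I) -> float:
    """Raw (un-normalized) cross-correlation sum at zero offset."""
    a, b = _paired_values(R, I)
    return float(np.dot(a, b))


def normalized_cross_correlation(R, I) -> float:
    """NCC as a cost: 1 - rho with rho the Pearson correlation."""
    a, b = _paired_values(R, I)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateRangeError("constant image: correlation undefined")
    return 1.0 - float(np.dot(a, b) / (na * nb))


def correlation_ratio(R, I, bins: int = DEFAULT_BINS, range_a=None) -> float:
    """CR as a cost: 1 - eta^2 = E[Var(I | bin(R))] / Var(I), in [0, 1]."""
    a, b = _paired_values(R, I)
    var_b = float(np.var(b))
    if var_b == 0.0:
        raise DegenerateRangeError("constant input image: variance undefined")
    edges = _bin_edges(a, bins, "single-bin", range_a)
    cls = np.clip(np.digitize(a, edges[1:-1]), 0, bins - 1)
    n_k = np.bincount(cls, minlength=bins).astype(float)
    sum_k = np.bincount(cls, weights=b, minlength=bins)
    sumsq_k = np.bincount(cls, weights=b * b, minlength=bins)
    nz = n_k > 0
    within = sumsq_k[nz] - sum_k[nz] ** 2 / n_k[nz]  # n_k * Var(I | class k)
    cost = float(within.sum() / (a.size * var_b))
    return min(max(cost, 0.0), 1.0)


# ----------------------------------------------------------- dispatch


def cost_value(spec: CostSpec, ref_values: np.ndarray, mov_values: np.ndarray,
               range_a=None, range_b=None) -> float:
    """Evaluate the named cost on paired 1D intensity samples.

    ``range_a``/``range_b`` freeze the histogram edges of the reference /
    moving samples — essential inside an optimization loop, where
    per-evaluation min/max would make the binning (and hence the cost
    surface) jitter between transform candidates.
    """
    if spec.name == "LS":
        return least_squares(ref_values, mov_values)
    if spec.name == "NCC":
        try:
            return normalized_cross_correlation(ref_values, mov_values)
        except DegenerateRangeError:
            return INFEASIBLE_COST
    if spec.name == "CR":
        try:
            return correlation_ratio(ref_values, mov_values, spec.bins, range_a)
        except DegenerateRangeError:
            return INFEASIBLE_COST
    # NMI
    try:
        return normalized_mutual_information(ref_values, mov_values, spec.bins,
                                             range_a, range_b)
    except (DegenerateRangeError, ValueError):
        return INFEASIBLE_COST
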