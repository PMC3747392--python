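"""Cost functions: hand-computed values, identities, and alignment
monotonicity on phantom volumes."""

import numpy as np
import pytest

from oair import (
    CostSpec,
    Volume,
    correlation_ratio,
    joint_histogram,
    least_squares,
    mutual_information,
    nmi,
    normalized_cross_correlation,
    normalized_mutual_information,
)
from oair.costs import DegenerateRangeError, cost_value
from oair.interpolation import resample_to_grid
from oair.kernels import KernelSpec
from oair.transforms import translation_matrix


def vol(arr):
    a = np.asarray(arr, dtype=float)
    while a.ndim < 3:
        a = a[..., None]
    if any(n < 2 for n in a.shape):
        reps = [2 if n < 2 else 1 for n in a.shape]
        a = np.tile(a, reps)
    return Volume(a)


@pytest.fixture(scope="module")
def noise_pair():
    r = np.random.default_rng(11)
    a = Volume(r.uniform(0, 1, (32, 32, 32)))
    b = Volume(r.uniform(0, 1, (32, 32, 32)))
    return a, b


class TestLeastSquares:
    def test_identical_zero(self, phantom32):
        assert least_squares(phantom32, phantom32) == 0.0

    def test_hand_value(self):
        # two paired samples: (0-1)^2 and (2-1)^2 average to 1
        assert least_squares(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == 1.0

    def test_constant_offset(self, phantom32):
        shifted = Volume(phantom32.data + 3.0, phantom32.spacing, phantom32.origin)
        assert least_squares(phantom32, shifted) == pytest.approx(9.0, rel=1e-12)

    def test_grid_mismatch_rejected(self, phantom32, phantom48):
        with pytest.raises(ValueError):
            least_squares(phantom32, phantom48)


class TestJointHistogram:
    def test_identical_images_diagonal(self, phantom32):
        h = joint_histogram(phantom32, phantom32, bins=32)
        off_diag = h.counts.sum() - np.trace(h.counts)
        assert off_diag == 0

    def test_counts_conserved(self, noise_pair):
        a, b = noise_pair
        h = joint_histogram(a, b, bins=16)
        assert h.counts.sum() == a.data.size == h.n_voxels

    def test_marginals_match_image_histograms(self, noise_pair):
        a, b = noise_pair
        h = joint_histogram(a, b, bins=16)
        ha, _ = np.histogram(a.data.ravel(), bins=h.edges_a)
        np.testing.assert_array_equal(h.marginal_a, ha)

    def test_independent_noise_disperses(self, noise_pair):
        a, b = noise_pair
        h = joint_histogram(a, b, bins=16)
        off_diag_frac = 1.0 - np.trace(h.counts) / h.n_voxels
        assert off_diag_frac > 0.8

    def test_constant_image_raises_with_fallback(self):
        c = vol(np.full((4, 4, 4), 3.0))
        r = vol(np.arange(64, dtype=float).reshape(4, 4, 4))
        with pytest.raises(DegenerateRangeError):
            joint_histogram(r, c, bins=8)
        h = joint_histogram(r, c, bins=8, on_degenerate="single-bin")
        assert h.counts.sum() == 64

    def test_frozen_range_clips(self):
        r = vol(np.linspace(0, 10, 64).reshape(4, 4, 4))
        h = joint_histogram(r, r, bins=8, range_a=(2.0, 8.0), range_b=(2.0, 8.0))
        assert h.counts.sum() == 64  # clipped into edge bins, not dropped
        assert h.edges_a[0] == 2.0 and h.edges_a[-1] == 8.0


class TestMutualInformation:
    def test_product_form_is_zero(self):
        from oair.costs import JointHistogram

        pa = np.array([0.5, 0.3, 0.2])
        pb = np.array([0.25, 0.25, 0.5])
        counts = np.round(np.outer(pa, pb) * 4000).astype(np.int64)
        h = JointHistogram(counts, np.arange(4.0), np.arange(4.0), counts.sum())
        assert mutual_information(h) == pytest.approx(0.0, abs=1e-12)

    def test_self_information_equals_entropy(self, phantom32):
        h = joint_histogram(phantom32, phantom32, bins=32)
        mi = mutual_information(h)
        p = h.marginal_a / h.n_voxels
        p = p[p > 0]
        entropy = -np.sum(p * np.log(p))
        assert mi == pytest.approx(entropy, rel=1e-12)

    def test_symmetry_under_transpose(self, noise_pair):
        a, b = noise_pair
        h = joint_histogram(a, b, bins=16)
        assert mutual_information(h) == pytest.approx(
            mutual_information(h.transpose()), rel=1e-12
        )

    def test_double_loop_oracle(self, noise_pair):
        a, b = noise_pair
        h = joint_histogram(a, b, bins=16)
        p = h.counts / h.n_voxels
        pa = p.sum(axis=1)
        pb = p.sum(axis=0)
        expect = 0.0
        for i in range(16):
            for j in range(16):
                if p[i, j] > 0:
                    expect += p[i, j] * np.log(p[i, j] / (pa[i] * pb[j]))
        assert mutual_information(h) == pytest.approx(expect, abs=1e-12)

    def test_nonnegative(self, noise_pair):
        a, b = noise_pair
        assert mutual_information(joint_histogram(a, b, bins=16)) >= 0.0


class TestNMI:
    def test_identical_images(self, phantom32):
        assert nmi(phantom32, phantom32, bins=32) == pytest.approx(1.0, rel=1e-12)
        assert normalized_mutual_information(phantom32, phantom32, bins=32) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_independent_noise_near_zero(self, noise_pair):
        a, b = noise_pair
        val = nmi(a, b, bins=16)
        assert val < 0.05
        assert normalized_mutual_information(a, b, bins=16) > 0.95

    def test_invariant_to_bin_preserving_relabel(self, phantom32):
        # strictly monotone affine intensity map keeps bin assignment
        rescaled = Volume(phantom32.data * 3.0 + 17.0, phantom32.spacing)
        assert nmi(phantom32, rescaled, bins=32) == pytest.approx(
            nmi(phantom32, phantom32, bins=32), rel=1e-12
        )


class TestNCC:
    def test_identical(self, phantom32):
        assert normalized_cross_correlation(phantom32, phantom32) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_sign_flip(self, phantom32):
        zero_mean = phantom32.data - phantom32.data.mean()
        r = Volume(zero_mean + 100.0)
        i = Volume(-zero_mean + 100.0)
        assert normalized_cross_correlation(r, i) == pytest.approx(2.0, rel=1e-12)

    def test_affine_invariance(self, phantom32):
        scaled = Volume(phantom32.data * 2.5 + 40.0, phantom32.spacing)
        assert normalized_cross_correlation(phantom32, scaled) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_constant_rejected(self, phantom32):
        with pytest.raises(DegenerateRangeError):
            normalized_cross_correlation(phantom32, Volume(np.full((32, 32, 32), 5.0)))


class TestCorrelationRatio:
    def test_functional_dependence_zero(self):
        r = np.random.default_rng(0)
        a = Volume(r.integers(0, 8, size=(16, 16, 16)).astype(float))
        b = Volume(a.data ** 2 + 3.0)  # deterministic function of a's classes
        assert correlation_ratio(a, b, bins=8) == pytest.approx(0.0, abs=1e-12)

    def test_independent_noise_near_one(self, noise_pair):
        a, b = noise_pair
        assert correlation_ratio(a, b, bins=16) > 0.9

    def test_bounds_on_random_pairs(self):
        r = np.random.default_rng(99)
        for _ in range(100):
            a = Volume(r.uniform(0, 10, (8, 8, 8)))
            b = Volume(r.uniform(0, 10, (8, 8, 8)))
            c = correlation_ratio(a, b, bins=8)
            assert 0.0 <= c <= 1.0

    def test_constant_input_rejected(self, phantom32):
        with pytest.raises(DegenerateRangeError):
            correlation_ratio(phantom32, Volume(np.full((32, 32, 32), 1.0)))


class TestAlignmentBehaviour:
    @pytest.mark.parametrize("cname", ["LS", "CR", "NCC", "NMI"])
    def test_minimized_at_alignment_and_monotone_in_shift(self, cname, phantom48):
        spec = CostSpec(cname, bins=32)
        costs = []
        for shift in (0, 1, 2, 4):
            t = translation_matrix((shift * phantom48.spacing[0], 0.0, 0.0))
            moved = resample_to_grid(phantom48, phantom48, world_map=t,
                                     spec=KernelSpec("trilinear"))
            costs.append(cost_value(spec, phantom48.data.ravel(), moved.data.ravel()))
        assert costs[0] == min(costs)
        # CR of an identical continuous-valued pair retains the within-bin
        # quantization variance; the other costs vanish exactly
        tol = 0.01 if cname == "CR" else 1e-9
        assert costs[0] == pytest.approx(0.0, abs=tol)
        assert all(c2 >= c1 for c1, c2 in zip(costs, costs[1:]))
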