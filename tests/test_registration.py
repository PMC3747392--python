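"""COM initialization, pyramid construction, the candidate-retention
logic, the local optimizer, and end-to-end motion recovery."""

import numpy as np
import pytest

from oair import (
    CandidateSet,
    CostSpec,
    DegradationSpec,
    KernelSpec,
    Volume,
    build_pyramid,
    center_of_mass,
    coarse_rotation_grid,
    com_align,
    degrade,
    evaluate_cost,
    generate_phantom,
    local_optimize,
    make_isotropic,
    matrix_to_params,
    register,
    retain_top_fraction,
)
from oair.registration import EmptyObjectError, StepSchedule
from oair.transforms import DOFParams


class TestCenterOfMass:
    def test_centered_cube(self):
        data = np.zeros((21, 21, 21))
        data[8:13, 8:13, 8:13] = 100.0
        v = Volume(data, spacing=(1, 1, 2))
        com = center_of_mass(v, threshold=50.0)
        np.testing.assert_allclose(com, [10.0, 10.0, 20.0], atol=0.5)

    def test_single_voxel(self):
        data = np.zeros((8, 8, 8))
        data[2, 5, 3] = 10.0
        com = center_of_mass(Volume(data, spacing=(1, 1, 1.3)), threshold=1.0)
        np.testing.assert_allclose(com, [2.0, 5.0, 3.9], atol=1e-12)

    def test_two_voxel_midpoint(self):
        data = np.zeros((8, 8, 8))
        data[1, 1, 1] = 10.0
        data[5, 1, 1] = 10.0
        com = center_of_mass(Volume(data), threshold=1.0)
        np.testing.assert_allclose(com, [3.0, 1.0, 1.0], atol=1e-12)

    def test_empty_object_raises(self):
        with pytest.raises(EmptyObjectError):
            center_of_mass(Volume(np.zeros((8, 8, 8))), threshold=5.0)


class TestComAlign:
    def test_self_alignment_identity(self, phantom32):
        t = com_align(phantom32, phantom32)
        np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_known_shift_recovery(self, phantom32):
        shifted = Volume(np.roll(phantom32.data, 2, axis=0),
                         phantom32.spacing, phantom32.origin)
        t = com_align(phantom32, shifted)
        # target moved +2 voxels in x, so the aligning translation is -2 mm
        assert t.matrix[0, 3] == pytest.approx(-2.0, abs=0.5)
        assert abs(t.matrix[1, 3]) < 0.5 and abs(t.matrix[2, 3]) < 0.5

    def test_rotation_of_symmetric_object_small_translation(self):
        data = np.zeros((32, 32, 32))
        xx, yy, zz = np.indices(data.shape)
        r2 = (xx - 15.5) ** 2 + (yy - 15.5) ** 2 + (zz - 15.5) ** 2
        data[r2 < 100] = 50.0
        v = Volume(data)
        spec = DegradationSpec("z", 1, 10.0, (0, 0, 0), 0.0, 0.0)
        rotated = degrade(v, spec)
        t = com_align(v, rotated)
        assert np.abs(t.matrix[:3, 3]).max() < 1.0


class TestMakeIsotropic:
    def test_anisotropic_z_expanded(self):
        v = generate_phantom((16, 16, 120), (1, 1, 1.3), seed=0)
        iso = make_isotropic(v)
        assert iso.spacing == (1.0, 1.0, 1.0)
        assert iso.shape == (16, 16, 156)

    def test_isotropic_returned_unchanged(self, phantom32):
        assert make_isotropic(phantom32) is phantom32

    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((16, 16, 24), 3.5), spacing=(1, 1, 1.5))
        iso = make_isotropic(v)
        np.testing.assert_allclose(iso.data, 3.5, atol=1e-9)


class TestBuildPyramid:
    def test_level_shapes(self):
        v = Volume(np.zeros((128, 128, 128)) + 1.0)
        pyr = build_pyramid(v)
        assert [p.shape for p in pyr] == [
            (16, 16, 16), (32, 32, 32), (64, 64, 64), (128, 128, 128)
        ]
        assert pyr[0].spacing == (8.0, 8.0, 8.0)

    def test_factor_one_is_input(self, phantom32):
        pyr = build_pyramid(phantom32)
        assert pyr[-1] is phantom32

    def test_constant_preserved_at_all_levels(self):
        v = Volume(np.full((64, 64, 64), 2.5))
        for p in build_pyramid(v):
            np.testing.assert_allclose(p.data, 2.5, atol=1e-9)

    def test_collapsing_level_dropped(self):
        v = Volume(np.zeros((16, 16, 16)) + 1.0)
        pyr = build_pyramid(v)  # factor 8 would give 2 voxels -> dropped
        assert len(pyr) == 3
        assert pyr[0].shape == (4, 4, 4)


class TestCoarseGrid:
    def test_combinatorics(self):
        grid = coarse_rotation_grid()
        assert len(grid) == 125
        assert grid[0] == (-30.0, -30.0, -30.0)
        assert grid[-1] == (30.0, 30.0, 30.0)
        for axis in range(3):
            assert sorted({g[axis] for g in grid}) == [-30, -15, 0, 15, 30]


class TestCandidateRetention:
    def test_125_to_25(self):
        entries = [(DOFParams(), float(i)) for i in range(125)]
        kept = retain_top_fraction(CandidateSet(entries))
        assert len(kept) == 25
        assert retain_top_fraction(kept).entries[0][1] == 0.0

    def test_single_entry_kept(self):
        kept = retain_top_fraction(CandidateSet([(DOFParams(), 1.0)]))
        assert len(kept) == 1

    def test_tie_break_insertion_order(self):
        ps = [DOFParams(tx=float(i)) for i in range(10)]
        kept = retain_top_fraction(CandidateSet([(p, 5.0) for p in ps]))
        assert [e[0].tx for e in kept.entries] == [0.0, 1.0]

    def test_sorted_ascending(self):
        cs = CandidateSet([(DOFParams(), 3.0), (DOFParams(), 1.0), (DOFParams(), 2.0)])
        assert [c for _, c in cs.entries] == [1.0, 2.0, 3.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            retain_top_fraction(CandidateSet([]))


class TestLocalOptimizer:
    def test_parabola_minimum(self):
        fn = lambda p: (p.tx - 3.0) ** 2
        steps = StepSchedule(translation=4.0, min_translation=1e-4)
        p, c, n = local_optimize(fn, DOFParams(), dof=3, steps=steps)
        assert p.tx == pytest.approx(3.0, abs=1e-3)
        assert c <= fn(DOFParams())

    def test_local_minimum_returns_init(self):
        fn = lambda p: p.tx ** 2 + p.ty ** 2 + p.tz ** 2
        p, c, _ = local_optimize(fn, DOFParams(), dof=3)
        assert (p.tx, p.ty, p.tz) == (0.0, 0.0, 0.0)
        assert c == 0.0

    def test_monotone_improvement_trace(self):
        trace = []

        def fn(p):
            c = (p.tx - 2.0) ** 2 + 0.5 * (p.rx - 3.0) ** 2
            trace.append(c)
            return c

        best_seen = np.inf
        accepted = []
        p, c, _ = local_optimize(fn, DOFParams(), dof=6)
        # reconstruct the accepted-cost sequence: it must be non-increasing
        for v in trace:
            if v < best_seen:
                best_seen = v
                accepted.append(v)
        assert accepted == sorted(accepted, reverse=True)
        assert c == min(trace)

    def test_only_declared_dof_varied(self):
        fn = lambda p: (p.tx - 1.0) ** 2 + (p.sx - 1.0) ** 2
        p, _, _ = local_optimize(fn, DOFParams(), dof=3)
        assert p.sx == 1.0 and p.rx == 0.0 and p.hxy == 0.0

    def test_nonfinite_init_rejected(self):
        with pytest.raises(ValueError):
            local_optimize(lambda p: np.inf, DOFParams(), dof=3)

    def test_deterministic(self):
        fn = lambda p: np.sin(p.tx) + (p.ty - 1.0) ** 2
        a = local_optimize(fn, DOFParams(), dof=3)
        b = local_optimize(fn, DOFParams(), dof=3)
        assert a == b


class TestRegister:
    def test_self_registration(self, phantom48):
        res = register(phantom48, phantom48, cost=CostSpec("LS"),
                       kernel=KernelSpec("trilinear"))
        np.testing.assert_allclose(res.final_transform.matrix, np.eye(4), atol=1e-3)
        assert res.final_cost < 1.0  # LS noise floor of exact data

    def test_motion_recovery_and_trace_law(self):
        ref = generate_phantom((48, 48, 48), (1.0, 1.0, 1.3), seed=2)
        spec = DegradationSpec("z", 1, 5.0, (2.0, 3.0, 0.0), 0.0, 0.0)
        target = degrade(ref, spec)
        res = register(ref, target, cost=CostSpec("LS"), kernel=KernelSpec("trilinear"))
        rec = matrix_to_params(res.final_transform.inverse(), res.center)
        assert rec.rx == pytest.approx(5.0, abs=0.5)
        assert rec.tx == pytest.approx(2.0, abs=0.5)
        assert rec.ty == pytest.approx(3.0, abs=0.5)
        assert abs(rec.tz) < 0.5
        # the 20% retention law at the coarse level: 125 -> 25 -> 5
        sizes = res.level_traces[0]["stage_sizes"]
        assert sizes[0] == 125 and sizes[1] == 25 and sizes[3] == 5

    def test_final_cost_is_level1_cost(self, phantom48):
        spec = DegradationSpec("z", 1, 3.0, (1.0, -2.0, 0.0), 0.0, 0.0)
        target = degrade(phantom48, spec)
        res = register(phantom48, target, cost=CostSpec("LS"),
                       kernel=KernelSpec("trilinear"))
        recomputed = evaluate_cost(phantom48, target, res.final_params,
                                   CostSpec("LS"), KernelSpec("trilinear"),
                                   center=res.center)
        assert recomputed == pytest.approx(res.final_cost, rel=1e-9)

    def test_max_dof_honored(self, phantom48):
        spec = DegradationSpec("z", 1, 3.0, (1.0, 0.0, 0.0), 0.0, 0.0)
        target = degrade(phantom48, spec)
        res = register(phantom48, target, cost=CostSpec("LS"),
                       kernel=KernelSpec("trilinear"), max_dof=7)
        p = res.final_params
        assert p.sx == p.sy == p.sz  # global scale only
        assert p.hxy == p.hxz == p.hyz == 0.0

    def test_invalid_max_dof(self, phantom48):
        with pytest.raises(ValueError):
            register(phantom48, phantom48, max_dof=5)

    def test_deterministic(self, phantom48):
        spec = DegradationSpec("z", 1, 4.0, (1.5, 0.5, 0.0), 0.0, 0.0)
        target = degrade(phantom48, spec)
        a = register(phantom48, target)
        b = register(phantom48, target)
        np.testing.assert_array_equal(a.final_transform.matrix,
                                      b.final_transform.matrix)
        assert a.final_cost == b.final_cost

    def test_forward_backward_consistency(self):
        ref = generate_phantom((48, 48, 48), (1.0, 1.0, 1.0), seed=6)
        spec = DegradationSpec("z", 1, 4.0, (2.0, 1.0, 0.0), 0.0, 0.0)
        target = degrade(ref, spec)
        fwd = register(ref, target).final_transform
        bwd = register(target, ref).final_transform
        comp = (fwd @ bwd).matrix
        corners = np.array([[0, 0, 0], [47, 0, 0], [0, 47, 0], [0, 0, 47],
                            [47, 47, 47]], dtype=float)
        moved = corners @ comp[:3, :3].T + comp[:3, 3]
        assert np.abs(moved - corners).max() < 1.0  # within one voxel
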