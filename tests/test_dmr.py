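"""DMR operator: patch oracles, recovery ranking, separability, tools."""

import numpy as np
import pytest

from doseshape import (
    DMRRequest,
    InfeasibleModification,
    IsodoseDragGesture,
    SphereGesture,
    VoxelGesture,
    apply_dmr,
    execute_tool,
    fluence_patch,
    identify_recovery,
    init_plan,
    tool_requests,
)

from conftest import ToyState, make_influence


class TestFluencePatch:
    def test_zero_request_zero_patch(self):
        D = make_influence([[0.5, 0.3]])
        p = fluence_patch(D, np.array([1.0, 1.0]), 0, 0.0)
        assert p.bixels.size == 0 and p.achieved_dd_gy == 0.0

    def test_single_bixel_closed_form(self):
        """One bixel with influence 0.5 Gy/unit; +2 Gy needs 4 units."""
        D = make_influence([[0.5]])
        p = fluence_patch(D, np.array([1.0]), 0, 2.0)
        assert p.deltas[0] == pytest.approx(4.0)
        assert p.achieved_dd_gy == pytest.approx(2.0)

    def test_minimum_norm_matches_independent_solvers(self):
        """3-bixel toy: the patch equals the lstsq minimum-norm solution
        (to 1e-6) and no grid-search candidate satisfying a.P = dd has a
        smaller norm."""
        a = np.array([0.6, 0.3, 0.1])
        dd = 2.0
        D = make_influence(a.reshape(1, 3))
        p = fluence_patch(D, np.full(3, 10.0), 0, dd)
        patch = np.zeros(3)
        patch[p.bixels] = p.deltas

        # oracle 1: LAPACK minimum-norm solution of the 1x3 system
        lstsq = np.linalg.lstsq(a.reshape(1, 3), np.array([dd]), rcond=None)[0]
        assert np.max(np.abs(patch - lstsq)) < 1e-6

        # oracle 2: brute-force grid search over the constraint plane
        grid = np.linspace(-5, 8, 81)
        best, best_norm = None, np.inf
        for p1 in grid:
            for p2 in grid:
                p3 = (dd - a[0] * p1 - a[1] * p2) / a[2]
                n = p1 * p1 + p2 * p2 + p3 * p3
                if n < best_norm:
                    best_norm = n
                    best = (p1, p2, p3)
        assert float(patch @ patch) <= best_norm + 1e-9
        assert a @ patch == pytest.approx(dd)

    def test_clamping_preserves_nonnegative_weights(self):
        """A large decrease clamps at w=0 and redistributes."""
        a = np.array([0.5, 0.5, 0.05])
        w = np.array([1.0, 10.0, 10.0])
        D = make_influence(a.reshape(1, 3))
        p = fluence_patch(D, w, 0, -4.0)
        patch = np.zeros(3)
        patch[p.bixels] = p.deltas
        assert np.all(w + patch >= -1e-12)
        assert p.achieved_dd_gy == pytest.approx(-4.0)

    def test_unreachable_decrease_clamps_to_best_achievable(self):
        """Requesting more decrease than the weights allow bottoms out at
        dose zero for that voxel's bixels."""
        a = np.array([0.5, 0.5])
        w = np.array([1.0, 1.0])
        D = make_influence(a.reshape(1, 2))
        p = fluence_patch(D, w, 0, -3.0)
        patch = np.zeros(2)
        patch[p.bixels] = p.deltas
        assert np.allclose(w + patch, 0.0)
        assert p.achieved_dd_gy == pytest.approx(-1.0)  # all dose removed

    def test_zero_row_is_infeasible(self):
        D = make_influence(np.array([[0.0, 0.0], [0.5, 0.5]]))
        with pytest.raises(InfeasibleModification):
            fluence_patch(D, np.ones(2), 0, 1.0)


class TestIdentifyRecovery:
    def test_no_deviation_empty_plan(self):
        ref = np.zeros((4, 4, 4))
        plan = identify_recovery(ref, ref.copy(), np.array([0]), 0.1, 15)
        assert plan.voxels.size == 0

    def test_budget_keeps_largest_deviations(self):
        """40 candidate deviations, budget 15 → the 15 largest survive."""
        rng = np.random.default_rng(0)
        ref = np.zeros(64)
        new = ref.copy()
        cand = rng.choice(64, size=40, replace=False)
        new[cand] = rng.uniform(0.5, 5.0, size=40) * rng.choice([-1, 1], size=40)
        plan = identify_recovery(ref.reshape(4, 4, 4), new.reshape(4, 4, 4), np.array([]), 0.2, 15)
        assert plan.voxels.size == 15
        expected = set(np.argsort(np.abs(new))[::-1][:15])
        assert set(plan.voxels) == expected

    def test_ordering_matches_exhaustive_sort(self):
        """Constructed deviation field: rank order equals a full sort with
        ascending-index tie-break."""
        ref = np.zeros(27)
        new = ref.copy()
        new[[3, 5, 7, 11, 13]] = [2.0, -3.0, 2.0, 1.0, -1.0]
        plan = identify_recovery(ref.reshape(3, 3, 3), new.reshape(3, 3, 3), np.array([]), 0.5, 10)
        assert list(plan.voxels) == [5, 3, 7, 11, 13]  # |dev| desc, index asc on ties

    def test_modification_region_excluded(self):
        ref = np.zeros(8)
        new = ref.copy()
        new[[1, 2]] = 5.0
        plan = identify_recovery(ref.reshape(2, 2, 2), new.reshape(2, 2, 2), np.array([1]), 0.5, 10)
        assert list(plan.voxels) == [2]


class TestApplyDMR:
    def separable_toy(self):
        """v(row {b0}) modified; r(row {b0, b1}) deviates; b0 carries 100%
        of the modification so recovery must use b1 alone — the recovery
        support is disjoint from the modification support."""
        mat = np.array(
            [
                [1.0, 0.0],  # v
                [0.8, 0.5],  # r
                [0.0, 0.0],  # padding voxel
            ]
        )
        D = make_influence(mat)
        state = ToyState(D, np.array([2.0, 5.0]))
        return D, state

    def test_separable_exactness(self):
        """Requested change achieved exactly at v; r restored exactly."""
        D, state = self.separable_toy()
        d0 = state.dose.copy().ravel()
        res = apply_dmr(state, DMRRequest.single(0, 1.5), tau_gy=0.01, n_r=15)
        d1 = state.dose.ravel()
        assert res.achieved_dd_gy == pytest.approx(1.5)
        assert d1[0] - d0[0] == pytest.approx(1.5)  # exact at v
        assert d1[1] == pytest.approx(d0[1])  # r exactly restored
        assert res.n_recovered == 1

    def test_zero_request_is_noop(self):
        D, state = self.separable_toy()
        w0, d0 = state.fluence_flat.copy(), state.dose.copy()
        res = apply_dmr(state, DMRRequest.single(0, 0.0), tau_gy=0.01, n_r=15)
        assert np.array_equal(state.fluence_flat, w0)
        assert np.array_equal(state.dose, d0)
        assert res.n_recovered == 0 and not res.patches

    def test_zero_budget_pure_modification(self):
        D, state = self.separable_toy()
        res = apply_dmr(state, DMRRequest.single(0, 1.0), tau_gy=0.01, n_r=0)
        assert res.n_recovered == 0
        assert len(res.patches) == 1

    def test_infeasible_leaves_state_unchanged(self):
        D, state = self.separable_toy()
        w0, d0 = state.fluence_flat.copy(), state.dose.copy()
        with pytest.raises(InfeasibleModification):
            apply_dmr(state, DMRRequest.single(2, 1.0), tau_gy=0.01, n_r=5)
        assert np.array_equal(state.fluence_flat, w0)
        assert np.array_equal(state.dose, d0)

    def test_achieved_sign_matches_request(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        rect = np.flatnonzero(small_phantom["vois"]["rectum"].mask.ravel())
        v = int(rect[np.argmax(state.dose.ravel()[rect])])
        for dd in (-5.0, 3.0):
            res = apply_dmr(state, DMRRequest.single(v, dd), tau_gy=0.38, n_r=15)
            assert res.achieved_dd_gy * dd >= 0

    def test_fluence_stays_nonnegative_through_instances(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        rng = np.random.default_rng(5)
        body = np.flatnonzero(small_phantom["vois"]["body"].mask.ravel())
        hot = body[state.dose.ravel()[body] > 20.0]
        for v in rng.choice(hot, size=8, replace=False):
            apply_dmr(state, DMRRequest.single(int(v), float(rng.uniform(-8, 8))), 0.38, 10)
            assert state.fluence_flat.min() >= 0.0

    def test_recovery_reduces_offtarget_deviation_count(self, small_phantom):
        """On the identified candidate set, recovery does not increase the
        number of voxels whose deviation exceeds the tolerance."""
        from doseshape.dmr import fluence_patch as fp

        tau = 0.38
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        rect = np.flatnonzero(small_phantom["vois"]["rectum"].mask.ravel())
        v = int(rect[np.argmax(state.dose.ravel()[rect])])
        ref = state.dose.copy()

        # post-modification-only state for comparison
        patch = fp(state.influence, state.fluence_flat, v, -6.0)
        mod_only = state.dose.ravel() + 0.0
        tmp = state.dose.copy()
        from doseshape.dose import incremental_dose

        incremental_dose(state.influence, tmp, patch.bixels, patch.deltas, out=tmp)
        plan = identify_recovery(ref, tmp, np.array([v]), tau, 15)
        before = np.abs((tmp - ref).ravel()[plan.voxels])

        apply_dmr(state, DMRRequest.single(v, -6.0), tau, 15)
        after = np.abs((state.dose - ref).ravel()[plan.voxels])
        assert (after > tau).sum() <= (before > tau).sum()

    def test_patch_count_linear_in_budget(self):
        """Patches per instance = 1 modification + at most N_R recoveries."""
        rng = np.random.default_rng(6)
        mat = rng.random((30, 12)) * (rng.random((30, 12)) > 0.5)
        mat[0, :6] = [1.0, 0.8, 0.6, 0.0, 0.0, 0.0]
        for n_r in (0, 3, 7, 15):
            D = make_influence(mat)
            state = ToyState(D, np.full(12, 5.0))
            res = apply_dmr(state, DMRRequest.single(0, 2.0), tau_gy=0.05, n_r=n_r)
            assert len(res.patches) <= 1 + n_r
            assert res.n_recovered <= n_r


class TestTools:
    def test_voxel_gesture_single_request(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        reqs = tool_requests(state, VoxelGesture(voxel=(16, 16, 12), dd_gy=2.0))
        assert len(reqs) == 1
        assert reqs[0].dd_gy == 2.0
        assert list(reqs[0].vm_flat) == [reqs[0].voxel]

    def test_tiny_sphere_hits_center_voxel_only(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        c = tuple(int(i) for i in np.round(small_phantom["vois"]["ptv"].centroid_index()))
        reqs = tool_requests(state, SphereGesture(center=c, radius_mm=1.0, dd_gy=3.0))
        assert len(reqs) == 1
        assert reqs[0].voxel == state.grid.flat_index(c)

    def test_sphere_request_count_matches_exhaustive_scan(self, small_phantom):
        """|requests| = brute-force count of body voxels within the radius
        (minus any with zero falloff)."""
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        grid = state.grid
        c = tuple(int(i) for i in np.round(small_phantom["vois"]["ptv"].centroid_index()))
        radius = 20.0
        reqs = tool_requests(state, SphereGesture(center=c, radius_mm=radius, dd_gy=-4.0))
        c_mm = np.asarray(grid.origin) + (np.asarray(c) + 0.5) * np.asarray(grid.spacing)
        count = 0
        body = state.vois["body"].mask
        for idx in zip(*np.nonzero(body)):
            p = np.asarray(grid.origin) + (np.asarray(idx) + 0.5) * np.asarray(grid.spacing)
            d = float(np.linalg.norm(p - c_mm))
            if d <= radius and 0.5 * (1 + np.cos(np.pi * d / radius)) > 0:
                count += 1
        assert len(reqs) == count

    def test_sphere_outside_body_rejected(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        with pytest.raises(ValueError):
            tool_requests(state, SphereGesture(center=(0, 0, 0), radius_mm=10.0, dd_gy=1.0))

    def test_identity_isodose_drag_empty(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        p = (16, 16, 12)
        reqs = tool_requests(state, IsodoseDragGesture(level_gy=40.0, p_from=p, p_to=p))
        assert reqs == []

    def test_isodose_level_outside_range_rejected(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        with pytest.raises(ValueError):
            tool_requests(
                state,
                IsodoseDragGesture(level_gy=1e4, p_from=(16, 16, 12), p_to=(16, 20, 12)),
            )

    def test_outward_drag_raises_segment_voxels_to_level(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        c = tuple(int(i) for i in np.round(small_phantom["vois"]["ptv"].centroid_index()))
        level = float(state.dose[c]) * 0.6
        target = (c[0], c[1] + 8, c[2])
        reqs = tool_requests(state, IsodoseDragGesture(level_gy=level, p_from=c, p_to=target))
        assert reqs  # the dose falls below the level along the segment
        for r in reqs:
            assert r.dd_gy > 0
            assert state.dose.ravel()[r.voxel] + r.dd_gy == pytest.approx(level)

    def test_execute_tool_equals_sequential_apply(self, small_phantom):
        """Tool execution is exactly consecutive single-instance DMR."""
        mk = lambda: init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        s1, s2 = mk(), mk()
        c = tuple(int(i) for i in np.round(small_phantom["vois"]["rectum"].centroid_index()))
        g = SphereGesture(center=c, radius_mm=17.0, dd_gy=-5.0)
        execute_tool(s1, g, tau_gy=0.38, n_r=10)
        for req in tool_requests(s2, g):
            apply_dmr(s2, req, 0.38, 10)
        assert np.max(np.abs(s1.dose - s2.dose)) < 1e-12

    def test_sphere_decrease_lowers_mean_dose_inside(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        rect = np.flatnonzero(small_phantom["vois"]["rectum"].mask.ravel())
        v = int(rect[np.argmax(state.dose.ravel()[rect])])
        c = tuple(int(i) for i in np.unravel_index(v, state.grid.dims))
        g = SphereGesture(center=c, radius_mm=17.0, dd_gy=-6.0)
        reqs = tool_requests(state, g)
        sphere = reqs[0].vm_flat
        before = state.dose.ravel()[sphere].mean()
        execute_tool(state, g, tau_gy=0.38, n_r=10)
        after = state.dose.ravel()[sphere].mean()
        assert after < before

    def test_gesture_script_matches_manual_execution(self, small_phantom):
        """A YAML-style script of gestures reproduces the same dose as
        running the tools by hand, honoring per-entry overrides."""
        from doseshape import gesture_from_dict, run_gesture_script

        mk = lambda: init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        c = tuple(int(i) for i in np.round(small_phantom["vois"]["rectum"].centroid_index()))
        script = [
            {"tool": "sphere", "center": list(c), "radius_mm": 17.0, "dd_gy": -4.0, "n_r": 5},
            {"tool": "voxel", "voxel": list(c), "dd_gy": 1.0},
        ]
        s1, s2 = mk(), mk()
        run_gesture_script(s1, script, tau_gy=0.38, n_r=10)
        execute_tool(s2, gesture_from_dict(script[0]), tau_gy=0.38, n_r=5)
        execute_tool(s2, gesture_from_dict(script[1]), tau_gy=0.38, n_r=10)
        assert np.array_equal(s1.dose, s2.dose)

    def test_unknown_tool_rejected(self):
        from doseshape import gesture_from_dict

        with pytest.raises(ValueError):
            gesture_from_dict({"tool": "laser", "dd_gy": 1.0})

    def test_empty_gesture_is_noop(self, small_phantom):
        state = init_plan(
            small_phantom["grid"], small_phantom["vois"], small_phantom["rx"],
            small_phantom["influence"],
        )
        d0 = state.dose.copy()
        p = (16, 16, 12)
        out = execute_tool(state, IsodoseDragGesture(40.0, p, p), 0.38, 10)
        assert out == []
        assert np.array_equal(state.dose, d0)
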