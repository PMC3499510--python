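"""Knot engine: operations, passes, convergence, determinism."""

import numpy as np
import pytest
from conftest import oracle_fit_constrained, random_signal
from scipy.optimize import minimize_scalar

from ppctrack import (
    MethodConfig,
    PpcSegment,
    RleSignal,
    build_knots,
    fit_poly,
    local_error,
    smooth,
    smooth_multi,
    try_continuity_adjust,
    try_move,
    try_remove,
)


def cfg(**kw):
    return MethodConfig(**{"method": "relative", "alpha": 0.05, "order": 0, "seed": 1, **kw})


def two_segment_store(sig, config, knot):
    """Store with a single interior knot whose two segments are fresh
    unconstrained fits of the given order."""
    store = build_knots(sig, config)
    for t in range(1, sig.n_runs):
        if t != knot:
            store.remove(t)
    pos = int(sig.run_bounds[knot])
    store.nodes[0][2] = fit_poly(sig, sig.origin, pos, config.order)
    store.nodes[knot][2] = fit_poly(sig, pos, sig.end, config.order, origin=pos)
    return store


class TestBuildKnots:
    def test_single_run_has_no_interior_knots(self):
        store = build_knots(RleSignal("c", 0, [10], [1.0]), cfg())
        assert store.interior_knots() == []
        assert 0 in store and store.n in store  # sentinels

    def test_five_runs_have_four_interior_knots(self, rng):
        sig = random_signal(rng, 5)
        store = build_knots(sig, cfg())
        assert len(store.interior_knots()) == 4

    def test_knot_positions_are_cumulative_run_starts(self, rng):
        sig = random_signal(rng, 6)
        store = build_knots(sig, cfg())
        for t in store.interior_knots():
            assert store.bounds[t] == sig.run_bounds[t]
            assert store.index_of(int(sig.run_bounds[t])) == t


class TestTryRemove:
    def test_zero_error_merge_accepted(self):
        sig = RleSignal("c", 0, [5, 5], [2.0, 2.0])
        store = build_knots(sig, cfg())
        assert try_remove(store, 1, sig, cfg())
        assert store.interior_knots() == []
        assert store.nodes[0][2] == pytest.approx((2.0,))

    def test_large_step_rejected_by_relative(self):
        sig = RleSignal("c", 0, [5, 5], [0.0, 10.0])
        config = cfg(alpha=0.01)
        store = build_knots(sig, config)
        assert not try_remove(store, 1, sig, config)
        assert store.interior_knots() == [1]  # no state change

    def test_poisson_merge_acceptance_rate_on_constant_rate_track(self, rng):
        """Two runs summarizing a constant-rate Poisson track merge nearly
        always at alpha=2 (deviations ~1 Poisson sd, band is 2 sd)."""
        accepted = 0
        config = cfg(method="poisson", alpha=2.0)
        for _ in range(200):
            counts = rng.poisson(10.0, size=(2, 20)).mean(axis=1)
            sig = RleSignal("c", 0, [20, 20], counts.astype(float))
            store = build_knots(sig, config)
            accepted += try_remove(store, 1, sig, config)
        assert accepted >= 0.95 * 200

    def test_ttest_merges_same_mean_blocks_shifted(self, rng):
        config = cfg(method="ttest", alpha=0.01)
        same = RleSignal("c", 0, np.ones(40, int), rng.normal(0, 1, 40))
        store = two_segment_store(same, config, 20)
        assert try_remove(store, 20, same, config)
        shifted = RleSignal(
            "c", 0, np.ones(40, int),
            np.concatenate([rng.normal(0, 1, 20), rng.normal(4, 1, 20)]),
        )
        store = two_segment_store(shifted, config, 20)
        assert not try_remove(store, 20, shifted, config)


class TestTryContinuityAdjust:
    def test_skipped_in_order0_mode(self):
        sig = RleSignal("c", 0, [5, 5], [1.0, 2.0])
        config = cfg(order=0)
        store = build_knots(sig, config)
        assert not try_continuity_adjust(store, 1, sig, config)

    def test_already_continuous_data_accepted_without_error_increase(self):
        # constant data: both sides fit the same line, so the joint value
        # equals both endpoint values and the error cannot increase
        sig = RleSignal("c", 0, np.ones(20, int), np.full(20, 5.0))
        config = cfg(order=1, alpha=0.9)
        store = two_segment_store(sig, config, 10)
        before = local_error(store.to_model(), sig, 0, 20)
        assert try_continuity_adjust(store, 10, sig, config)
        model = store.to_model()
        after = local_error(model, sig, 0, 20)
        assert after <= before + 1e-10
        assert model.segments[1].continuous_left
        left, right = model.segments
        assert left.value_at_end() == pytest.approx(right.coefficients[0], abs=1e-9)

    def test_step_data_keeps_discontinuity(self):
        sig = RleSignal("c", 0, [5, 5], [0.0, 10.0])
        config = cfg(order=1, alpha=0.01)
        store = two_segment_store(sig, config, 1)
        assert not try_continuity_adjust(store, 1, sig, config)

    def test_joint_knot_value_matches_numeric_minimization(self, rng):
        noise = rng.normal(0, 0.3, 20)
        sig = RleSignal("c", 0, np.ones(20, int), 5.0 + 0.7 * np.arange(20) + noise)
        config = cfg(order=1, alpha=10.0)
        store = two_segment_store(sig, config, 10)
        # pre-adjustment state: crude order-0 side means, as after build_knots
        # merges; the constrained linear refit then strictly reduces error
        store.nodes[0][2] = fit_poly(sig, 0, 10, 0)
        store.nodes[10][2] = fit_poly(sig, 10, 20, 0, origin=10)
        assert try_continuity_adjust(store, 10, sig, config)
        fitted_y = store.to_model().segments[1].coefficients[0]

        def joint_error(y):
            total = 0.0
            for (a, b, at), origin in (((0, 10, (10, y)), 0), ((10, 20, (10, y)), 10)):
                c = oracle_fit_constrained(sig, a, b, 1, [at])
                # oracle coefficients are about a; re-origin for the segment
                seg = PpcSegment(a, b - a, 1, tuple(c))
                total += local_error([seg], sig, a, b)
            return total

        opt = minimize_scalar(joint_error, bounds=(-20, 40), method="bounded",
                              options={"xatol": 1e-10})
        assert fitted_y == pytest.approx(opt.x, abs=1e-6)


class TestTryMove:
    def test_knot_on_true_step_does_not_move(self):
        sig = RleSignal("c", 0, [3, 3, 3, 3], [0.0, 0.0, 10.0, 10.0])
        config = cfg(alpha=0.5)
        store = build_knots(sig, config)
        store.remove(1)
        store.remove(3)
        assert not try_move(store, 2, sig, config)

    def test_knot_one_run_off_moves_onto_step(self):
        sig = RleSignal("c", 0, [3, 3, 3], [0.0, 10.0, 10.0])
        config = cfg(alpha=0.5)
        store = build_knots(sig, config)
        store.remove(2)
        # left segment covers runs 0; right covers the mixed runs 1..2
        store.nodes[1][2] = fit_poly(sig, 3, 9, 0, origin=3)
        store.nodes[0][2] = (0.0,)
        # put the knot in the wrong place: merge left instead
        store.remove(1)
        store.insert(1, 0, 3)
        store.nodes[0][2] = (0.0,)
        store.nodes[1][2] = (10.0,)
        # now shift the knot off the step on purpose
        store.remove(1)
        store.insert(2, 0, 3)
        store.nodes[0][2] = fit_poly(sig, 0, 6, 0)
        store.nodes[2][2] = (10.0,)
        assert try_move(store, 2, sig, config)
        assert store.interior_knots() == [1]
        model = store.to_model()
        assert local_error(model, sig, 0, 9) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("order", [0, 1])
    def test_adopted_position_matches_exhaustive_oracle(self, rng, order):
        """The move picks the split minimizing combined integral error among
        all run boundaries in the union span."""
        values = np.concatenate([rng.normal(0, 0.5, 8), rng.normal(5, 0.5, 8)])
        sig = RleSignal("c", 0, rng.integers(1, 4, 16), values)
        config = cfg(alpha=100.0, order=order)
        store = build_knots(sig, config)
        for t in range(1, 16):
            if t != 4:
                store.remove(t)
        b4 = int(sig.run_bounds[4])
        store.nodes[0][2] = fit_poly(sig, 0, b4, order)
        store.nodes[4][2] = fit_poly(sig, b4, sig.end, order, origin=b4)
        best_err, best_c = np.inf, None
        for c in range(1, 16):
            if c == 4:
                continue
            bc = int(sig.run_bounds[c])
            cl = fit_poly(sig, 0, bc, order)
            cr = fit_poly(sig, bc, sig.end, order, origin=bc)
            err = local_error([PpcSegment(0, bc, len(cl) - 1, cl)], sig, 0, bc)
            err += local_error(
                [PpcSegment(bc, sig.end - bc, len(cr) - 1, cr)], sig, bc, sig.end
            )
            if err < best_err:
                best_err, best_c = err, c
        moved = try_move(store, 4, sig, config)
        if moved:
            assert store.interior_knots() == [best_c]
        else:
            # only valid if staying put is at least as good
            cur = local_error(store.to_model(), sig, 0, sig.end)
            assert cur <= best_err + 1e-9


class TestSmooth:
    def test_strict_limit_returns_input_bit_exact(self, rng):
        sig = random_signal(rng, 40)
        res = smooth(sig, cfg(alpha=0.0))
        model = res.model
        assert model.n_segments == sig.n_runs
        for seg, l, v in zip(model.segments, sig.lengths, sig.values):
            assert seg.order == 0 and seg.length == l and seg.coefficients[0] == v

    def test_loose_limit_collapses_to_one_segment(self, rng):
        sig = random_signal(rng, 40)
        res = smooth(sig, cfg(alpha=1e9))
        assert res.model.n_segments == 1
        assert res.knots_removed == 39

    def test_identical_config_gives_identical_result(self, rng):
        sig = random_signal(rng, 120, value_sampler=lambda r, n: r.poisson(6, n).astype(float))
        r1 = smooth(sig, cfg(method="poisson", alpha=1.5, seed=7))
        r2 = smooth(sig, cfg(method="poisson", alpha=1.5, seed=7))
        assert r1.model == r2.model
        assert r1.passes_used == r2.passes_used

    def test_model_tiles_extent_and_count_never_increases(self, rng):
        sig = random_signal(rng, 80, origin=500)
        res = smooth(sig, cfg(alpha=0.3))
        model = res.model
        model.validate()
        assert model.start == 500 and model.end == 500 + sig.length
        assert model.n_segments <= sig.n_runs

    def test_pass_cap_exhaustion_flagged_but_model_valid(self, rng):
        sig = random_signal(rng, 60, value_sampler=lambda r, n: r.normal(0, 1, n))
        res = smooth(sig, cfg(alpha=1e9, pass_cap=1))
        res.model.validate()
        assert res.passes_used == 1

    def test_different_seeds_may_differ_but_both_satisfy_criterion(self, rng):
        from ppctrack import area_pairs

        sig = random_signal(rng, 150, value_sampler=lambda r, n: r.poisson(8, n).astype(float))
        config = cfg(method="poisson", alpha=2.0)
        for seed in (1, 2):
            res = smooth(sig, cfg(method="poisson", alpha=2.0, seed=seed))
            for p in area_pairs(sig, res.model, sig.origin, sig.end):
                assert abs(p.A - p.P) <= config.alpha * np.sqrt(max(p.A, 1.0)) + 1e-9

    def test_poisson_on_negative_signal_raises(self):
        sig = RleSignal("c", 0, [5, 5], [-1.0, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            smooth(sig, cfg(method="poisson"))


class TestSmoothMulti:
    def test_k1_equals_single_run(self, rng):
        sig = random_signal(rng, 50)
        assert smooth_multi(sig, cfg(seed=3), 1)[0].model == smooth(sig, cfg(seed=3)).model

    def test_repeat_runs_are_deterministic(self, rng):
        sig = random_signal(rng, 60)
        a = smooth_multi(sig, cfg(seed=5), 4)
        b = smooth_multi(sig, cfg(seed=5), 4)
        assert all(x.model == y.model for x, y in zip(a, b))
        assert [r.seed for r in a] == [5, 6, 7, 8]

    def test_noise_free_step_gives_identical_models_across_seeds(self):
        values = np.repeat([0.0, 8.0, 3.0], 10)
        sig = RleSignal("c", 0, np.full(30, 2, dtype=int), values)
        results = smooth_multi(sig, cfg(alpha=0.05), 5)
        first = results[0].model
        assert all(r.model == first for r in results[1:])
        assert list(first.breakpoints) == [20, 40]
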