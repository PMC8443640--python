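"""Two-lineage structured coalescent: rate matrix, exact IICR, Gillespie T2
simulation and their analytic identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demoscope import (
    CoalescenceUnreachableError,
    DivergentExpectationError,
    EpochSchedule,
    IslandModel,
    PanmicticModel,
    empirical_iicr,
    iicr_exact,
    island_generator,
    mean_t2,
    simulate_t2,
)
from demoscope.models import (
    exact_windowed_iicr,
    iicr_plateau,
    model_from_dict,
    model_to_dict,
)


class TestIslandGenerator:
    @pytest.mark.parametrize(
        "n,M,lam,checks",
        [
            (2, 1.0, 1.0, {"diff_to_same": 1.0}),
            (10, 0.0, 1.0, {"diff_row_zero": True}),
            (5, 0.5, 2.0, {"same_diag": -1.0}),
        ],
    )
    def test_stated_entries(self, n, M, lam, checks):
        Q = island_generator(n, M, lam)
        assert np.allclose(Q.sum(axis=1), 0.0)
        if "diff_to_same" in checks:
            assert Q[1, 0] == pytest.approx(checks["diff_to_same"])
        if checks.get("diff_row_zero"):
            assert np.all(Q[1] == 0.0)
        if "same_diag" in checks:
            assert Q[0, 0] == pytest.approx(checks["same_diag"])
        assert np.all(Q[2] == 0.0)

    @pytest.mark.parametrize("n,M,lam", [(1, 1.0, 1.0), (5, -0.1, 1.0), (5, 1.0, 0.0)])
    def test_invalid_parameters(self, n, M, lam):
        with pytest.raises(ValueError):
            island_generator(n, M, lam)


class TestSchedule:
    def test_breakpoint_invariants(self):
        with pytest.raises(ValueError):
            EpochSchedule((1.0,), (0.0,), (1.0,))  # first breakpoint not 0
        with pytest.raises(ValueError):
            EpochSchedule((0.0, 2.0, 1.0), (0.0,) * 3, (1.0,) * 3)
        with pytest.raises(ValueError):
            EpochSchedule((0.0,), (-1.0,), (1.0,))
        with pytest.raises(ValueError):
            EpochSchedule((0.0,), (0.0,), (0.0,))

    @given(
        st.lists(st.floats(0.01, 10.0), min_size=1, max_size=4),
        st.lists(st.floats(0.0, 50.0), min_size=5, max_size=5),
    )
    @settings(max_examples=25, deadline=None)
    def test_epoch_lookup_consistency(self, gaps, Ms):
        bps = tuple(np.concatenate(([0.0], np.cumsum(gaps))))
        k = len(bps)
        sched = EpochSchedule(bps, tuple(Ms[:k]), (1.0,) * k)
        t = np.asarray(bps[1:]) - 1e-9
        assert np.all(sched.epoch_index(t) == np.arange(k - 1))
        t = np.asarray(bps[1:]) + 1e-9
        assert np.all(sched.epoch_index(t) == np.arange(1, k))


class TestExactIICR:
    def test_panmictic_equals_size_function(self, panmictic_step, grid_log):
        curve = iicr_exact(panmictic_step, grid_log)
        expected = np.where(grid_log < 2.0, 1.0, 5.0)
        assert np.array_equal(curve.values, expected)

    def test_iicr_starts_at_one_for_unit_size(self, island_multi):
        curve = iicr_exact(island_multi, np.array([1e-6]))
        assert curve.values[0] == pytest.approx(1.0, rel=1e-4)

    def test_strong_migration_limit_approaches_n(self):
        # with M >> 1 the island model mixes instantly: IICR ~ n
        m = IslandModel(10, EpochSchedule.constant(M=1000.0))
        curve = iicr_exact(m, np.array([5.0]))
        assert curve.values[0] == pytest.approx(10.0, rel=0.01)

    def test_survival_integral_matches_mean(self, island_const):
        # E[T2 | same deme] = n regardless of M: integrate the survival
        # function implied by the exact state propagation
        from demoscope.models import _propagate

        t = np.linspace(1e-6, 400.0, 400_001)
        surv = _propagate(island_const, t).sum(axis=1)
        integral = np.trapezoid(surv, t)
        assert integral == pytest.approx(5.0, abs=1e-3)

    def test_plateau_matches_eigenvector(self, island_const):
        curve = iicr_exact(island_const, np.array([200.0, 300.0]))
        assert curve.values[-1] == pytest.approx(iicr_plateau(island_const), rel=1e-6)
        assert curve.values[0] == pytest.approx(curve.values[1], rel=1e-4)

    def test_grid_validation(self, island_const):
        with pytest.raises(ValueError):
            iicr_exact(island_const, np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            iicr_exact(island_const, np.array([-1.0, 1.0]))


class TestMeanT2:
    def test_single_epoch_closed_forms(self):
        same = IslandModel(7, EpochSchedule.constant(M=2.0))
        diff = IslandModel(7, EpochSchedule.constant(M=2.0), sampling="different_demes")
        assert mean_t2(same) == pytest.approx(7.0)
        assert mean_t2(diff) == pytest.approx(10.0)

    def test_panmictic_constant(self):
        m = PanmicticModel(EpochSchedule.constant(lam=3.0))
        assert mean_t2(m) == pytest.approx(3.0)

    def test_multi_epoch_matches_numeric_survival(self):
        sched = EpochSchedule((0.0, 1.0, 3.0), (1.0, 0.2, 2.0), (1.0, 2.0, 0.5))
        m = IslandModel(4, sched)
        from demoscope.models import _propagate

        t = np.linspace(1e-6, 500.0, 500_001)
        surv = _propagate(m, t).sum(axis=1)
        assert mean_t2(m) == pytest.approx(np.trapezoid(surv, t), rel=1e-4)

    def test_divergence_signalled(self):
        m = IslandModel(5, EpochSchedule.constant(M=0.0), sampling="different_demes")
        with pytest.raises(DivergentExpectationError):
            mean_t2(m)


class TestSimulateT2:
    def test_panmictic_exponential_mean(self):
        m = PanmicticModel(EpochSchedule.constant())
        s = simulate_t2(m, 1_000_000, seed=7)
        assert s.draws.mean() == pytest.approx(1.0, abs=0.005)

    @pytest.mark.parametrize("sampling,expected", [("same_deme", 5.0), ("different_demes", 13.0)])
    def test_island_mean_identities(self, sampling, expected):
        m = IslandModel(5, EpochSchedule.constant(M=0.5), sampling=sampling)
        s = simulate_t2(m, 1_000_000, seed=11)
        tol = 0.05 if sampling == "same_deme" else 0.1
        assert s.draws.mean() == pytest.approx(expected, abs=3 * tol)

    def test_deterministic_given_seed(self, island_const):
        a = simulate_t2(island_const, 5_000, seed=3)
        b = simulate_t2(island_const, 5_000, seed=3)
        assert np.array_equal(a.draws, b.draws)

    def test_unreachable_coalescence_raises(self):
        m = IslandModel(5, EpochSchedule.constant(M=0.0), sampling="different_demes")
        with pytest.raises(CoalescenceUnreachableError):
            simulate_t2(m, 10, seed=0)

    def test_multi_epoch_mean_matches_exact(self):
        sched = EpochSchedule((0.0, 1.0, 3.0), (1.0, 0.2, 2.0), (1.0, 2.0, 0.5))
        m = IslandModel(4, sched)
        s = simulate_t2(m, 400_000, seed=13)
        assert s.draws.mean() == pytest.approx(mean_t2(m), rel=0.02)


class TestEmpiricalIICR:
    def test_exponential_draws_give_flat_curve(self):
        # the windowed estimator carries a discretization bias of
        # dt / (1 - exp(-dt)) per window under constant truth, so the 5%
        # check applies where windows are narrow in linear time
        m = PanmicticModel(EpochSchedule.constant())
        s = simulate_t2(m, 1_000_000, seed=21)
        curve = empirical_iicr(s, np.geomspace(1e-3, 0.6, 50))
        draws = np.sort(s.draws)
        counts = np.diff(np.searchsorted(draws, curve.times))
        well = counts >= 5_000
        assert well.sum() >= 20
        assert np.all(np.abs(curve.values[well] - 1.0) < 0.05)

    def test_windowed_estimator_converges_to_exact(self):
        m = IslandModel(10, EpochSchedule.constant(M=1.0))
        s = simulate_t2(m, 1_000_000, seed=5)
        grid = np.geomspace(1e-2, 50.0, 60)
        emp = empirical_iicr(s, grid)
        exact = exact_windowed_iicr(m, emp.times)
        draws = np.sort(s.draws)
        counts = np.diff(np.searchsorted(draws, emp.times))
        well = counts >= 10_000
        assert well.sum() >= 10
        rel = np.abs(emp.values[well] - exact[well]) / exact[well]
        assert rel.max() < 0.02

    def test_zero_event_windows_merged(self, island_const):
        s = simulate_t2(island_const, 10, seed=2)
        curve = empirical_iicr(s, np.geomspace(1e-3, 50.0, 100))
        assert len(curve.values) <= 10
        assert len(curve.times) == len(curve.values) + 1

    def test_empty_curve_error(self, island_const):
        s = simulate_t2(island_const, 100, seed=2)
        with pytest.raises(ValueError, match="empty"):
            empirical_iicr(s, np.geomspace(1e3, 1e4, 5))


def test_model_descriptor_round_trip(island_multi, panmictic_step):
    for m in (island_multi, panmictic_step):
        assert model_from_dict(model_to_dict(m)) == m
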