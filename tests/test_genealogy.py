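"""Gillespie genealogy simulator: analytic means, event handling, agreement
with the two-lineage structured-coalescent module and with msprime."""

import numpy as np
import pytest
from scipy import stats

from demoscope import (
    EpochSchedule,
    Event,
    IslandModel,
    Scenario,
    branch_length_spectrum,
    expected_sfs,
    simulate_pairwise_tmrca,
    simulate_t2,
)

N = 1000.0


def island_scenario(n_demes: int, G: float, samples=(0,)) -> Scenario:
    return Scenario((N,) * n_demes, migration=G, samples=samples)


class TestAnalyticMeans:
    def test_single_deme_pair(self):
        tm = simulate_pairwise_tmrca(Scenario((N,)), (2,), 200_000, seed=1)
        assert tm.mean() == pytest.approx(N, rel=0.01)

    def test_single_deme_many_lineages(self):
        # E[TMRCA] = 2N(1 - 1/k) generations for k lineages
        tm = simulate_pairwise_tmrca(Scenario((N,)), (10,), 100_000, seed=2)
        assert tm.mean() == pytest.approx(2 * N * (1 - 0.1), rel=0.015)

    @pytest.mark.parametrize("G", [0.5, 5.0])
    def test_island_same_deme_mean_independent_of_migration(self, G):
        # E[T2 | same deme] = n_demes * N for any positive migration rate
        tm = simulate_pairwise_tmrca(island_scenario(3, G), (2,), 150_000, seed=4)
        assert tm.mean() == pytest.approx(3 * N, rel=0.015)

    def test_size_change_mean(self):
        # N1 until T, N2 older: E[T2] = N1(1-e^{-T/N1}) + N2 e^{-T/N1}
        sc = Scenario((N,), events=(Event(1000.0, "resize", deme=0, value=5000.0),))
        tm = simulate_pairwise_tmrca(sc, (2,), 150_000, seed=5)
        expected = N * (1 - np.exp(-1.0)) + 5000.0 * np.exp(-1.0)
        assert tm.mean() == pytest.approx(expected, rel=0.015)

    def test_merge_forces_minimum_tmrca(self):
        # isolated demes merging at T: coalescence only after T
        sc = Scenario(
            (N, N),
            migration=0.0,
            samples=(0, 1),
            events=(Event(500.0, "merge", deme=1, dest=0),),
        )
        tm = simulate_pairwise_tmrca(sc, (1, 1), 100_000, seed=6)
        assert tm.min() >= 500.0
        assert tm.mean() == pytest.approx(500.0 + N, rel=0.015)


class TestCrossModuleAgreement:
    """The event-based simulator and the two-lineage structured-coalescent
    chain describe the same island process: with haploid deme size N and
    present-day migration parameter G = 2NM0, the chain with lambda = 1 and
    M = 2 G reproduces TMRCA/N in distribution."""

    def test_distribution_matches_t2_chain(self):
        G = 1.0
        sc = island_scenario(2, G, samples=(0, 1))
        tm = simulate_pairwise_tmrca(sc, (1, 1), 30_000, seed=7) / N
        model = IslandModel(2, EpochSchedule.constant(M=2 * G), sampling="different_demes")
        ref = simulate_t2(model, 30_000, seed=8).draws
        res = stats.ks_2samp(tm, ref)
        assert res.pvalue > 0.01

    def test_same_deme_sampling_matches_t2_chain(self):
        G = 0.25
        tm = simulate_pairwise_tmrca(island_scenario(5, G), (2,), 30_000, seed=9) / N
        model = IslandModel(5, EpochSchedule.constant(M=2 * G))
        ref = simulate_t2(model, 30_000, seed=10).draws
        assert stats.ks_2samp(tm, ref).pvalue > 0.01


class TestMsprimeOracle:
    def test_island_tmrca_distribution(self):
        msprime = pytest.importorskip("msprime")
        G, D = 1.5, 3
        demography = msprime.Demography()
        for d in range(D):
            # with ploidy=1 msprime coalesces a pair at rate 1/initial_size,
            # so initial_size is the haploid deme size
            demography.add_population(initial_size=N)
        # per-lineage backward rate out of a deme is G/N, uniform over others
        for i in range(D):
            for j in range(D):
                if i != j:
                    demography.set_migration_rate(f"pop_{i}", f"pop_{j}", G / (N * (D - 1)))
        reps = msprime.sim_ancestry(
            samples={"pop_0": 2},
            ploidy=1,
            demography=demography,
            num_replicates=20_000,
            random_seed=17,
        )
        ref = np.fromiter((ts.first().time(ts.first().root) for ts in reps), dtype=float)
        tm = simulate_pairwise_tmrca(island_scenario(D, G), (2,), 20_000, seed=18)
        assert stats.ks_2samp(tm, ref).pvalue > 0.01


class TestExpectedSFS:
    def test_constant_size_folded_law(self):
        # unfolded xi_i proportional to 1/i; folded cell i gets 1/i + 1/(n-i)
        # (no doubling at i = n/2)
        sfs = expected_sfs(Scenario((N,)), (6,), R=40_000, seed=19)
        w = np.array([1.0 + 1 / 5, 0.5 + 0.25, 1 / 3])
        assert np.allclose(sfs.flat(), w / w.sum(), atol=0.01)
        assert sfs.flat().sum() == pytest.approx(1.0)

    def test_ghost_deme_marginalization(self):
        # an unsampled deme is declared via samples but receives nsam = 0;
        # the observed spectrum collapses to the 1d law of the sampled deme
        G = 2.0
        sc2 = Scenario((N, N), migration=G, samples=(0, 1))
        sc1 = Scenario((N, N), migration=G, samples=(0,))
        a = expected_sfs(sc2, (6, 0), R=5_000, seed=20)
        b = expected_sfs(sc1, (6,), R=5_000, seed=20)
        assert a.sample_sizes == (6,)
        assert np.array_equal(a.data, b.data)

    def test_joint_spectrum_shape_and_symmetry(self):
        sc = island_scenario(2, 1.0, samples=(0, 1))
        sfs = expected_sfs(sc, (4, 4), R=3_000, seed=21)
        assert sfs.sample_sizes == (4, 4)
        assert sfs.data.shape == (5, 5)
        assert sfs.flat().sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        sc = island_scenario(2, 1.0, samples=(0, 1))
        a = expected_sfs(sc, (3, 3), R=500, seed=5)
        b = expected_sfs(sc, (3, 3), R=500, seed=5)
        c = expected_sfs(sc, (3, 3), R=500, seed=6)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_branch_lengths_positive(self):
        L = branch_length_spectrum(Scenario((N,)), (4,), 500, seed=22)
        assert L.shape == (5, 1)
        assert L[1:4].sum() > 0


class TestErrors:
    def test_sample_size_arity_mismatch(self):
        with pytest.raises(ValueError, match="sampled populations"):
            simulate_pairwise_tmrca(Scenario((N,)), (2, 2), 100, seed=0)

    def test_too_few_chromosomes(self):
        with pytest.raises(ValueError, match="at least 2"):
            simulate_pairwise_tmrca(Scenario((N,)), (1,), 100, seed=0)

    def test_non_coalescing_configuration(self):
        sc = Scenario((N, N), migration=0.0, samples=(0, 1))
        with pytest.raises(ValueError, match="non-coalescing"):
            simulate_pairwise_tmrca(sc, (1, 1), 100, seed=0)

    def test_expected_sfs_needs_replicates(self):
        with pytest.raises(ValueError, match="R"):
            expected_sfs(Scenario((N,)), (4,), R=50, seed=0)
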