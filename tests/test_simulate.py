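"""Wright-Fisher simulator and Pool-Seq noise model."""

import numpy as np
import pytest
from scipy import stats

from erselect import (
    SelectionParams,
    SimDesign,
    poolseq_sample,
    sample_poolseq,
    simulate_dataset,
    simulate_locus,
    simulate_trajectories,
    wf_generation,
)


def wf_transition_matrix(n_gametes: int) -> np.ndarray:
    """Independent oracle: exact neutral WF transition matrix over allele
    copy-number states 0..n."""
    states = np.arange(n_gametes + 1)
    return stats.binom.pmf(states[None, :], n_gametes, states[:, None] / n_gametes)


def wf_state_distribution(p0: float, n_gametes: int, t: int) -> np.ndarray:
    M = wf_transition_matrix(n_gametes)
    d = np.zeros(n_gametes + 1)
    d[int(round(p0 * n_gametes))] = 1.0
    for _ in range(t):
        d = d @ M
    return d


class TestWfGeneration:
    def test_absorbing(self, rng):
        p = SelectionParams(0.3)
        assert wf_generation(0.0, p, 300, rng) == 0.0
        assert wf_generation(1.0, p, 300, rng) == 1.0

    def test_neutral_binomial_moments(self, rng):
        draws = np.array([wf_generation(0.5, SelectionParams(0.0), 300, rng) for _ in range(10_000)])
        assert draws.mean() == pytest.approx(0.5, abs=0.002)
        assert draws.var() == pytest.approx(0.25 / 600, rel=0.1)

    def test_large_ne_converges_to_deterministic(self, rng):
        draws = [
            wf_generation(0.5, SelectionParams(0.1, ploidy="haploid"), 10_000_000, rng)
            for _ in range(20)
        ]
        assert np.mean(draws) == pytest.approx(0.55 / 1.05, abs=1e-3)


class TestSimulateLocus:
    def test_large_ne_negligible_drift(self):
        design = SimDesign(ne=10**6, replicates=3, seed=1)
        traj = simulate_locus(0.4, SelectionParams(0.0), design)
        assert np.allclose(traj.freqs, 0.4, atol=0.01)

    def test_loss_fraction_matches_transition_matrix_oracle(self, rng):
        """Neutral loss probability at small Ne against exact matrix power."""
        n = 50  # haploid gamete pool
        t = 60
        p0 = 0.05 + 1e-9  # round(0.05*50) -> state 2.5 ambiguity avoided; use 3/50
        p0 = 3 / 50
        d = wf_state_distribution(p0, n, t)
        freqs = simulate_trajectories(
            np.full(4000, p0), 0.0, 0.5, ne=n, ploidy="haploid",
            sampling_times=[0, t], replicates=1, rng=rng,
        )[:, 0, 1]
        assert np.mean(freqs == 0.0) == pytest.approx(d[0], abs=0.03)

    def test_neutral_drift_variance_matches_oracle(self, rng):
        """Var(p_t) = p0(1-p0)(1-(1-1/n)^t), cross-checked three ways."""
        n, t, p0 = 50, 20, 0.3
        d = wf_state_distribution(p0, n, t)
        states = np.arange(n + 1) / n
        var_oracle = float(d @ states**2 - (d @ states) ** 2)
        var_formula = p0 * (1 - p0) * (1 - (1 - 1 / n) ** t)
        assert var_oracle == pytest.approx(var_formula, rel=1e-9)
        freqs = simulate_trajectories(
            np.full(6000, p0), 0.0, 0.5, ne=n, ploidy="haploid",
            sampling_times=[0, t], replicates=1, rng=rng,
        )[:, 0, 1]
        assert freqs.var() == pytest.approx(var_oracle, rel=0.08)

    def test_strong_selection_sweeps(self, rng):
        freqs = simulate_trajectories(
            np.full(500, 0.5), 0.3, 0.5, ne=300, ploidy="diploid",
            sampling_times=[0, 60], replicates=1, rng=rng,
        )[:, 0, 1]
        # deterministic trajectory reaches 0.9994 by t=60; drift keeps a
        # small minor-allele tail (~2% of chains sit just below 0.99)
        assert np.mean(freqs > 0.99) >= 0.95
        assert np.mean(freqs > 0.97) >= 0.99


class TestPoolseqSample:
    def test_monomorphic_trivial(self, rng):
        assert poolseq_sample(0.0, 80, rng).alt_count == 0
        s = poolseq_sample(1.0, 20, rng)
        if not s.missing:
            assert s.freq_hat == 1.0

    def test_unbiased_and_variance(self, rng):
        alt, cov = sample_poolseq(np.full(100_000, 0.5), 80.0, rng)
        ok = cov > 0
        fh = alt[ok] / cov[ok]
        assert fh.mean() == pytest.approx(0.5, abs=0.002)
        expected_var = np.mean(1 / cov[ok]) * 0.25
        assert fh.var() == pytest.approx(expected_var, rel=0.05)

    def test_pool_size_stage_adds_variance(self, rng):
        alt1, cov1 = sample_poolseq(np.full(50_000, 0.5), 80.0, rng)
        alt2, cov2 = sample_poolseq(np.full(50_000, 0.5), 80.0, rng, pool_size=100)
        v1 = np.var(alt1[cov1 > 0] / cov1[cov1 > 0])
        v2 = np.var(alt2[cov2 > 0] / cov2[cov2 > 0])
        assert v2 > v1

    def test_zero_coverage_is_missing(self, rng):
        alt, cov = sample_poolseq(np.full(2000, 0.5), 0.5, rng)
        assert np.all(alt[cov == 0] == 0)
        assert (cov == 0).any()  # Poisson(0.5) hits zero


class TestSimulateDataset:
    def test_empty(self, small_design):
        ds = simulate_dataset(0, 0.5, 0.1, 0.5, small_design, seed=0)
        assert ds.n_loci == 0

    def test_neutral_mean_final_frequency(self, standard_design):
        ds = simulate_dataset(4000, 0.25, 0.0, 0.5, standard_design, seed=7)
        assert ds.freqs[:, :, -1].mean() == pytest.approx(0.25, abs=0.01)

    def test_uniform_s_mean(self, standard_design):
        ds = simulate_dataset(4000, 0.5, (0.0, 0.3), 0.5, standard_design, seed=8)
        assert ds.truth["s"].mean() == pytest.approx(0.15, abs=0.01)

    def test_seed_determinism(self, small_design):
        a = simulate_dataset(100, (0, 1), (0, 0.3), 0.5, small_design, seed=3)
        b = simulate_dataset(100, (0, 1), (0, 0.3), 0.5, small_design, seed=3)
        assert np.array_equal(a.alt, b.alt) and np.array_equal(a.cov, b.cov)
        assert a.truth.equals(b.truth)

    def test_locus_prefix_stable_in_n_loci(self, small_design):
        """Growing the dataset never reshuffles earlier loci."""
        a = simulate_dataset(50, (0, 1), (0, 0.3), 0.5, small_design, seed=3)
        b = simulate_dataset(80, (0, 1), (0, 0.3), 0.5, small_design, seed=3)
        assert np.array_equal(a.alt, b.alt[:50])
        assert np.allclose(a.truth["p0"], b.truth["p0"][:50])

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimDesign(ne=0)
        with pytest.raises(ValueError):
            SimDesign(sampling_times=(10, 20))  # must include generation 0
        with pytest.raises(ValueError):
            SimDesign(mean_coverage=0.0)
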