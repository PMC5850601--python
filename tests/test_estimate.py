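"""LLS/NLS estimators, bias corrections, and the switching pipeline."""

import numpy as np
import pytest

from erselect import (
    EstimationError,
    SelectionParams,
    SimDesign,
    Trajectory,
    simulate_dataset,
    trajectory_continuous,
    trajectory_discrete,
)
from erselect.estimate import (
    bias_correct,
    combine_replicates,
    condition_on_survival_correct,
    estimate_auto,
    lls_estimate,
    neutral_loss_probability,
    nls_estimate,
    quadratic_term_test,
)
from erselect.model import FreqSeries, inv_logit

TIMES = np.arange(0, 61, 10)


def _traj(freq_rows, times=None):
    return Trajectory(times=TIMES if times is None else times, freqs=np.asarray(freq_rows, float))


class TestCombineReplicates:
    def test_identical_replicates(self):
        t = _traj([[0.1, 0.2, 0.4]] * 3, times=[0, 10, 20])
        fs = combine_replicates(t)
        assert np.allclose(fs.freqs, [0.1, 0.2, 0.4])

    def test_arithmetic_mean(self):
        t = _traj([[0.2, 0.4], [0.4, 0.6]], times=[0, 10])
        assert np.allclose(combine_replicates(t).freqs, [0.3, 0.5])

    def test_loss_masking_from_first_zero(self):
        """A replicate stops contributing from the time its allele reads 0."""
        t = _traj([[0.1, 0.0, 0.0], [0.1, 0.2, 0.3]], times=[0, 10, 20])
        fs = combine_replicates(t)
        assert np.allclose(fs.freqs, [0.1, 0.2, 0.3])

    def test_missing_points_skipped_without_masking(self):
        t = _traj([[0.1, np.nan, 0.3], [0.1, 0.2, np.nan]], times=[0, 10, 20])
        fs = combine_replicates(t)
        assert np.allclose(fs.freqs, [0.1, 0.2, 0.3])

    def test_too_few_points_raises(self):
        t = _traj([[0.0, 0.0, 0.0]], times=[0, 10, 20])
        with pytest.raises(EstimationError):
            combine_replicates(t)


class TestLLS:
    def test_exact_on_continuous_model(self):
        """Noise-free diploid codominant data: s and p0 recovered exactly."""
        p = trajectory_continuous(0.1, 0.1, TIMES, "diploid")
        est = lls_estimate(FreqSeries(TIMES, p), "diploid")
        assert est.s_hat == pytest.approx(0.1, abs=1e-12)
        assert est.p0_hat == pytest.approx(0.1, abs=1e-12)
        assert est.method == "LLS" and est.h_hat == 0.5

    def test_constant_series_zero_slope(self):
        est = lls_estimate(FreqSeries(TIMES, np.full(7, 0.3)), "diploid")
        assert est.s_hat == pytest.approx(0.0, abs=1e-12)

    def test_hand_ols_on_collinear_logits(self):
        freqs = inv_logit(np.array([-2.0, -1.0, 0.0]))
        est = lls_estimate(FreqSeries([0, 10, 20], freqs), "haploid")
        assert est.s_hat == pytest.approx(0.1, abs=1e-10)
        assert est.p0_hat == pytest.approx(inv_logit(-2.0), abs=1e-9)

    def test_two_points_exact_line(self):
        est = lls_estimate(FreqSeries([0, 10], [0.2, 0.4]), "haploid")
        assert est.n_points_used == 2
        assert np.isfinite(est.s_hat)

    def test_boundary_points_dropped(self):
        # the fixed point carries no logit information; fit uses the rest
        p = trajectory_continuous(0.1, 0.1, TIMES[:-1], "diploid")
        est = lls_estimate(FreqSeries(TIMES, np.append(p, 1.0)), "diploid")
        assert est.n_points_used == 6
        assert est.s_hat == pytest.approx(0.1, abs=1e-10)

    def test_monomorphic_raises(self):
        with pytest.raises(EstimationError):
            lls_estimate(FreqSeries(TIMES, np.zeros(7)), "diploid")


class TestBiasCorrect:
    def test_zero_stays_zero(self):
        est = lls_estimate(FreqSeries(TIMES, np.full(7, 0.3)), "diploid")
        corrected = bias_correct(est, TIMES, "diploid")
        assert corrected.s_hat == pytest.approx(0.0, abs=1e-9)

    def test_weak_selection_tiny_correction(self):
        p = trajectory_discrete(0.3, SelectionParams(0.001, 0.5), TIMES)
        est = lls_estimate(p, "diploid")
        corrected = bias_correct(est, TIMES, "diploid")
        assert abs(corrected.s_hat - est.s_hat) < 1e-4

    @pytest.mark.parametrize("s_true", [0.1, 0.2, 0.3])
    def test_self_consistency_on_discrete_truth(self, s_true):
        """Estimating from the exact discrete trajectory and correcting
        recovers the generating s to 1e-3."""
        p = trajectory_discrete(0.1, SelectionParams(s_true, 0.5), TIMES)
        est = lls_estimate(p, "diploid")
        assert est.s_hat < s_true  # continuous-model fit underestimates
        corrected = bias_correct(est, TIMES, "diploid")
        assert corrected.s_hat == pytest.approx(s_true, abs=1e-3)

    def test_haploid_self_consistency(self):
        p = trajectory_discrete(0.2, SelectionParams(0.25, ploidy="haploid"), TIMES)
        est = lls_estimate(p, "haploid")
        corrected = bias_correct(est, TIMES, "haploid")
        assert corrected.s_hat == pytest.approx(0.25, abs=1e-3)


class TestSurvivalConditioning:
    def test_drift_free_input_unchanged(self, rng, standard_design):
        t = _traj([trajectory_continuous(0.3, 0.05, TIMES, "diploid")])
        fs = condition_on_survival_correct(t, None, standard_design, rng)
        assert np.allclose(fs.freqs, t.freqs[0])

    def test_high_p0_negligible_correction(self, rng, standard_design):
        t = _traj([trajectory_continuous(0.5, 0.05, TIMES, "diploid")] * 6)
        fs = condition_on_survival_correct(t, 300, standard_design, rng, n_sims=400)
        assert np.allclose(fs.freqs, t.freqs[0], atol=0.02)

    def test_removes_conditioning_bias_at_low_p0(self, standard_design):
        """Neutral loci at p0=0.02: the loss-masked consensus drifts up;
        the correction removes most of that rise."""
        ds = simulate_dataset(150, 0.02, 0.0, 0.5, standard_design, seed=51)
        rng = np.random.default_rng(52)
        T = ds.times.size
        unc = np.full((ds.n_loci, T), np.nan)
        cor = np.full((ds.n_loci, T), np.nan)
        for i in range(ds.n_loci):
            traj = ds.trajectory(i)
            try:
                fs = combine_replicates(traj)
                unc[i, np.searchsorted(ds.times, fs.generations)] = fs.freqs
                fs2 = condition_on_survival_correct(traj, 300, standard_design, rng, n_sims=200)
                cor[i, np.searchsorted(ds.times, fs2.generations)] = fs2.freqs
            except EstimationError:
                pass
        t = ds.times.astype(float)
        slope_unc = np.polyfit(t, np.nanmean(unc, axis=0), 1)[0]
        slope_cor = np.polyfit(t, np.nanmean(cor, axis=0), 1)[0]
        assert slope_unc > 0
        assert abs(slope_cor) < 0.4 * slope_unc

    def test_fully_lost_replicate_masked_out(self, rng, standard_design):
        t = _traj([[0.0, 0.1, 0.2, 0.1, 0.1, 0.05, 0.0], [0.1, 0.1, 0.2, 0.1, 0.1, 0.05, 0.02]])
        # first replicate reads 0 at t=0 and is masked entirely
        fs = condition_on_survival_correct(t, 300, standard_design, rng, n_sims=100)
        assert fs.freqs[0] <= 0.1

    def test_loss_probability_trigger_helper(self):
        assert neutral_loss_probability(0.0, 600, 60) == 1.0
        assert neutral_loss_probability(0.5, 600, 60) < 1e-4
        lo = neutral_loss_probability(0.02, 600, 60)
        assert 0.01 < lo < 1.0


class TestNLS:
    @pytest.mark.parametrize("h_true", [0.0, 0.5, 1.0])
    def test_recovers_s_and_h_from_noise_free_data(self, h_true):
        p = trajectory_discrete(0.1, SelectionParams(0.1, h_true), TIMES)
        est = nls_estimate(p, "diploid")
        assert est.converged
        assert est.s_hat == pytest.approx(0.1, abs=1e-6)
        assert est.h_hat == pytest.approx(h_true, abs=1e-4)

    def test_agrees_with_corrected_lls_under_codominance(self):
        p = trajectory_discrete(0.1, SelectionParams(0.12, 0.5), TIMES)
        nls = nls_estimate(p, "diploid")
        lls = bias_correct(lls_estimate(p, "diploid"), TIMES, "diploid")
        assert nls.s_hat == pytest.approx(lls.s_hat, abs=1e-3)

    def test_constant_trajectory_s_zero_h_unidentifiable(self):
        est = nls_estimate(FreqSeries(TIMES, np.full(7, 0.3)), "diploid")
        assert est.s_hat == pytest.approx(0.0, abs=1e-6)
        assert np.isnan(est.h_hat)
        assert "h_unidentifiable" in est.notes

    def test_haploid_has_no_dominance(self):
        p = trajectory_discrete(0.2, SelectionParams(0.15, ploidy="haploid"), TIMES)
        est = nls_estimate(p, "haploid")
        assert est.s_hat == pytest.approx(0.15, abs=1e-6)
        assert np.isnan(est.h_hat)

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            nls_estimate(FreqSeries([0, 10], [0.1, 0.2]), "diploid")


class TestQuadraticTermTest:
    def test_exactly_linear_logits_pvalue_one(self):
        p = trajectory_continuous(0.2, 0.1, np.arange(0, 41, 10), "diploid")
        assert quadratic_term_test(FreqSeries(np.arange(0, 41, 10), p)) == 1.0

    def test_recessive_curvature_detected(self):
        p = trajectory_discrete(0.25, SelectionParams(0.2, 0.0), TIMES)
        assert quadratic_term_test(p) < 0.1

    def test_four_points_single_residual_df(self):
        rng = np.random.default_rng(0)
        y = 0.2 + 0.1 * rng.random(4)
        pv = quadratic_term_test(FreqSeries([0, 10, 20, 30], y))
        assert pv is not None and 0.0 < pv <= 1.0

    def test_three_points_undefined(self):
        assert quadratic_term_test(FreqSeries([0, 10, 20], [0.2, 0.3, 0.4])) is None


class TestEstimateAuto:
    def test_zero_threshold_always_lls(self, standard_design):
        ds = simulate_dataset(20, 0.25, 0.2, 0.0, standard_design, seed=9)
        for i in range(ds.n_loci):
            try:
                est = estimate_auto(ds.trajectory(i), "diploid", p_threshold=0.0, survival_correction="off")
            except EstimationError:
                continue
            assert est.method == "LLS"

    def test_switching_sensitivity_for_recessive(self, standard_design):
        """Recessive truth: most loci routed to NLS."""
        ds = simulate_dataset(60, 0.25, 0.2, 0.0, standard_design, seed=10)
        rng = np.random.default_rng(1)
        methods = []
        for i in range(ds.n_loci):
            try:
                methods.append(estimate_auto(ds.trajectory(i), "diploid", rng=rng, survival_correction="off").method)
            except EstimationError:
                pass
        assert np.mean([m == "NLS" for m in methods]) > 0.5

    def test_switching_specificity_under_codominance(self, standard_design):
        """Codominant truth at moderate p0: majority stays with LLS."""
        ds = simulate_dataset(60, 0.25, 0.15, 0.5, standard_design, seed=11)
        rng = np.random.default_rng(1)
        methods = []
        for i in range(ds.n_loci):
            try:
                methods.append(estimate_auto(ds.trajectory(i), "diploid", rng=rng, survival_correction="off").method)
            except EstimationError:
                pass
        assert np.mean([m == "LLS" for m in methods]) > 0.5
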