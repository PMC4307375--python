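import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biobridge import (
    MetricReport,
    ScenarioConfig,
    avg_ci_width,
    expand_grid,
    modified_bias,
    modified_rmse,
    run_scenario,
    true_clinical_rates,
)
from biobridge.simulation import (
    generate_historical_trials,
    generate_new_trial,
    generate_trial,
    implied_treatment_rate,
)


class TestGenerator:
    def test_perfect_concordance_copies_biomarker(self, rng):
        # PPV = NPV = 1 makes the clinical response identical to the
        # biomarker response for every patient
        for _ in range(5):
            t = generate_trial("t", 1.0, 1.0, 0.2, 0.3, 400, rng)
            assert t.x_t == t.b_t
            assert t.x_c == t.b_c

    def test_perfect_concordance_rr_equality(self, rng):
        t = generate_trial("t", 1.0, 1.0, 0.25, 0.3, 2000, rng)
        assert t.x_t / t.x_c == pytest.approx(t.b_t / t.b_c)

    def test_historical_batch_shape(self, rng):
        cfg = ScenarioConfig(ppv=0.8, npv=0.8, n_trials=7, k_reps=1, seed=0)
        trials = generate_historical_trials(cfg, rng)
        assert len(trials) == 7
        assert all(t.n_t == t.n_c == 400 for t in trials)
        assert all(t.has_endpoint for t in trials)

    def test_new_trial_has_no_endpoint(self, rng):
        cfg = ScenarioConfig(ppv=0.8, npv=0.8, n_trials=5, k_reps=1, seed=0)
        new = generate_new_trial(cfg, rng)
        assert new.x_t is None

    def test_total_probability_oracle(self, rng):
        # empirical clinical rate at n=1e5 matches the analytic law of
        # total probability within 3 MC standard errors
        n = 100_000
        ppv, npv, pi_b = 0.15, 0.9999, 0.37
        t = generate_trial("t", ppv, npv, pi_b, 0.3, n, rng)
        want = ppv * pi_b + (1 - npv) * (1 - pi_b)
        se = math.sqrt(want * (1 - want) / n)
        assert abs(t.x_t / n - want) < 3 * se

    def test_implied_rate(self):
        assert implied_treatment_rate(0.5, 0.3) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            implied_treatment_rate(0.8, 0.5)


class TestTrueRates:
    def test_derived_example(self):
        pi_xt, pi_xc, rr = true_clinical_rates(0.15, 0.9999, 0.2, 0.3)
        assert pi_xt == pytest.approx(0.03008)
        assert pi_xc == pytest.approx(0.04507)
        assert rr == pytest.approx(0.6674, abs=1e-4)

    def test_null_when_rates_equal(self):
        assert true_clinical_rates(0.9, 0.9, 0.3, 0.3)[2] == pytest.approx(1.0)

    def test_uninformative_biomarker_gives_half(self):
        for pi_bt in (0.1, 0.5, 0.9):
            pi_xt, _, rr = true_clinical_rates(0.5, 0.5, pi_bt, 0.3)
            assert pi_xt == pytest.approx(0.5)
            assert rr == pytest.approx(1.0)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            true_clinical_rates(0.0, 0.9, 0.2, 0.3)


class TestMetrics:
    def test_bias_zero_when_exact(self):
        assert modified_bias([2.0, 2.0, 2.0], 2.0) == pytest.approx(0.0)

    def test_bias_log_symmetry(self):
        assert modified_bias([4.0, 1.0], 2.0) == pytest.approx(0.0)
        assert modified_bias([2 * 3.0, 3.0 / 2], 3.0) == pytest.approx(0.0)

    def test_rmse_hand_value_natural_log(self):
        # (1, 4) about 2: residuals -ln2, +ln2 -> rmse = ln 2
        got = modified_rmse([1.0, 4.0], 2.0, base=math.e)
        assert got == pytest.approx(math.log(2), rel=1e-12)

    def test_rmse_hand_value_default_base10(self):
        got = modified_rmse([1.0, 4.0], 2.0)
        assert got == pytest.approx(math.log10(2), rel=1e-12)

    def test_rmse_single_estimate(self):
        got = modified_rmse([3.0], 2.0, base=math.e)
        assert got == pytest.approx(abs(math.log(1.5)), rel=1e-12)

    def test_rmse_zero_when_exact(self):
        assert modified_rmse([2.0, 2.0], 2.0) == 0.0

    def test_nonpositive_predictions_excluded_with_warning(self):
        with pytest.warns(RuntimeWarning, match="excluded"):
            got = modified_bias([2.0, 0.0, -1.0], 2.0)
        assert got == pytest.approx(0.0)

    @given(
        rr_hats=st.lists(
            st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=30
        ),
        rr_true=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_rmse_dominates_abs_bias(self, rr_hats, rr_true):
        b = modified_bias(rr_hats, rr_true)
        r = modified_rmse(rr_hats, rr_true)
        assert r >= abs(b) - 1e-12

    def test_width_degenerate_intervals(self):
        assert avg_ci_width([(0.5, 0.5), (2.0, 2.0)]) == pytest.approx(1.0)

    def test_width_hand_values(self):
        assert avg_ci_width([(0.5, 1.0)]) == pytest.approx(0.5)
        assert avg_ci_width([(0.2, 0.8), (0.5, 1.0)]) == pytest.approx(0.375)

    def test_width_input_errors(self):
        with pytest.raises(ValueError):
            avg_ci_width([(1.0, 0.5)])
        with pytest.raises(ValueError):
            avg_ci_width([(0.0, 0.5)])
        with pytest.raises(ValueError):
            avg_ci_width([])

    @given(
        lows=st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=20),
        scale=st.floats(min_value=1.0, max_value=10.0),
    )
    def test_width_antitone_in_interval_growth(self, lows, scale):
        pairs = [(lo, lo * 2.0) for lo in lows]
        wider = [(lo, lo * 2.0 * scale) for lo in lows]
        assert avg_ci_width(wider) <= avg_ci_width(pairs)


class TestScenarioConfig:
    def test_phi_bj_bound(self):
        with pytest.raises(ValueError, match="phi_bj_new"):
            ScenarioConfig(ppv=0.9, npv=0.9, n_trials=5, phi_bj_new=0.8)

    def test_probability_domains(self):
        with pytest.raises(ValueError):
            ScenarioConfig(ppv=1.0, npv=0.9, n_trials=5)

    def test_phi_b_range_checked(self):
        with pytest.raises(ValueError, match="phi_b_range"):
            ScenarioConfig(ppv=0.9, npv=0.9, n_trials=5, phi_b_range=(0.0, 0.9))

    def test_expand_grid(self):
        base = ScenarioConfig(ppv=0.9, npv=0.9, n_trials=5, seed=100)
        grid = expand_grid(base, ppv=[0.5, 0.9], phi_bj_new=[0.1, 0.3])
        assert len(grid) == 4
        assert sorted({c.ppv for c in grid}) == [0.5, 0.9]
        assert len({c.seed for c in grid}) == 4  # distinct cell seeds


class TestRunScenario:
    def test_deterministic(self):
        cfg = ScenarioConfig(ppv=0.9, npv=0.9, n_trials=5, k_reps=8, seed=42)
        assert run_scenario(cfg) == run_scenario(cfg)

    def test_report_fields(self):
        cfg = ScenarioConfig(ppv=0.9, npv=0.9, n_trials=5, k_reps=8, seed=42)
        rep = run_scenario(cfg)
        assert isinstance(rep, MetricReport)
        assert rep.k_effective <= rep.k_requested == 8
        assert rep.modified_rmse >= abs(rep.modified_bias)
        assert 0 < rep.avg_ci_width <= 1

    def test_strong_concordance_small_errors(self):
        # near-perfect concordance: predictions track truth closely
        cfg = ScenarioConfig(
            ppv=0.99, npv=0.99, n_trials=10, phi_bj_new=0.5, k_reps=40, seed=7
        )
        rep = run_scenario(cfg)
        assert abs(rep.modified_bias) < 0.05
        assert rep.modified_rmse < 0.15

    def test_logit_not_worse_than_cloglog(self):
        # reproducible part of the reported link ranking
        kw = dict(ppv=0.8, npv=0.8, n_trials=10, phi_bj_new=0.3, k_reps=80)
        r_logit = run_scenario(ScenarioConfig(link="logit", seed=3, **kw))
        r_clog = run_scenario(ScenarioConfig(link="cloglog", seed=3, **kw))
        assert r_logit.modified_rmse <= r_clog.modified_rmse + 0.01

    def test_predictive_interval_coverage(self):
        # synthetic trials with strong concordance: 95% credible intervals
        # cover the analytic truth at (at least) roughly nominal rate over
        # 120 replicates; intervals are mildly conservative at this cell,
        # so only the lower side is bounded
        from biobridge.model import fit
        from biobridge.prediction import predict

        cfg = ScenarioConfig(
            ppv=0.99, npv=0.99, n_trials=10, phi_bj_new=0.5, k_reps=120, seed=5
        )
        pi_btj = implied_treatment_rate(0.5, 0.3)
        rr_true = true_clinical_rates(0.99, 0.99, pi_btj, 0.3)[2]
        covered = total = 0
        for child in np.random.SeedSequence(5).spawn(cfg.k_reps):
            gen = np.random.default_rng(child)
            trials = [
                t
                for t in generate_historical_trials(cfg, gen)
                if t.b > 0 and t.x > 0
            ]
            seed = int(gen.integers(2**31 - 1))
            if len(trials) < 2:
                continue
            post = fit(trials, settings=cfg.mcmc, seed=seed, compute_diagnostics=False)
            pred = predict(post, phi_bj=0.5, seed=seed)
            total += 1
            covered += pred.rr_ci[0] <= rr_true <= pred.rr_ci[1]
        # nominal 0.95 minus 3 binomial standard errors at n=120
        assert covered / total >= 0.95 - 3 * math.sqrt(0.95 * 0.05 / 120)

    def test_propagate_mode_runs(self):
        cfg = ScenarioConfig(
            ppv=0.9, npv=0.9, n_trials=5, k_reps=5, seed=1, propagate=True
        )
        rep = run_scenario(cfg)
        assert rep.k_effective == 5
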