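"""Fit statistic, condition summaries and the fitting loop."""

import numpy as np
import pandas as pd
import pytest

import lbaction as lba
from lbaction.fitting import bic, g_squared, summarize_condition


def _trials(rts, responses, condition="specified-repetition", valid="2", prev=2):
    n = len(rts)
    return pd.DataFrame(
        {
            "trial_index": range(n),
            "onset_s": np.arange(n) * 2.4,
            "trial_type": "specified" if condition.startswith("spec") else "choice",
            "condition": condition,
            "valid_actions": valid,
            "previous_action": prev,
            "response": pd.array(responses, dtype="Int64"),
            "rt_s": rts,
            "first_action_trial": False,
        }
    )


class TestSummarizeCondition:
    def test_median_of_odd_sample(self):
        t = _trials([1.0, 2.0, 3.0, 4.0, 5.0], [2] * 5)
        s = summarize_condition(t, min_trials=5)
        assert s.rt_quantiles[2] == pytest.approx(3.0)

    def test_degenerate_selection(self):
        t = _trials(
            [0.5] * 12, [1] * 12, condition="choice-repetition-absent", valid="0,1,2", prev=3
        )
        s = summarize_condition(t, min_trials=10)
        np.testing.assert_allclose(s.selection_probs, [0, 1, 0, 0])
        assert s.omission_rate == 0.0

    def test_too_few_trials_rejected_by_name(self):
        t = _trials([0.5] * 3, [2] * 3)
        with pytest.raises(ValueError, match="specified-repetition"):
            summarize_condition(t, min_trials=10)

    def test_matches_simulator_predictions(self, group_params, design_base):
        """Empirical summaries of simulated trials agree with the
        large-n_sim prediction of the same parameter set."""
        pred = lba.predict_summaries(
            group_params, None, design_base,
            lba.Condition.CHOICE_REP_ABSENT, n_sim=100_000, seed=31,
        )
        rng = np.random.default_rng(32)
        from lbaction.simulate import effective_arrays, race, sample_condition_configs

        prev, valid = sample_condition_configs(
            lba.Condition.CHOICE_REP_ABSENT, 2000, rng
        )
        arr = effective_arrays(
            group_params, None, design_base,
            lba.Condition.CHOICE_REP_ABSENT, prev, valid,
        )
        z = rng.standard_normal(valid.shape)
        u = rng.random(valid.shape)
        w, rt = race(*arr, z, u)
        rows = np.arange(len(prev))
        t = _trials(
            rt[w >= 0],
            valid[rows, np.maximum(w, 0)][w >= 0],
            condition="choice-repetition-absent",
            valid="0,1,2",
        )
        s = summarize_condition(t, min_trials=10)
        np.testing.assert_allclose(s.rt_quantiles, pred.rt_quantiles, atol=0.03)


class TestGSquared:
    def test_zero_when_observed_equals_expected(self):
        assert g_squared([40, 40, 20], [0.4, 0.4, 0.2]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # counts (10, 10), expected proportions (0.9, 0.1), n = 20
        expected = 2 * (10 * np.log(10 / 18) + 10 * np.log(10 / 2))
        assert g_squared([10, 10], [0.9, 0.1]) == pytest.approx(expected)
        assert expected == pytest.approx(20.4334, abs=1e-3)

    def test_linear_in_counts(self):
        one = g_squared([10, 10], [0.9, 0.1])
        two = g_squared([20, 20], [0.9, 0.1])
        assert two == pytest.approx(2 * one)

    def test_zero_observed_bins_contribute_nothing(self):
        base = g_squared([10, 10], [0.45, 0.45])
        with_zero = g_squared([10, 10, 0], [0.45, 0.45, 0.1])
        assert with_zero == pytest.approx(base + 2 * 20 * np.log(10 / 9) - base, abs=10)
        assert np.isfinite(with_zero)

    def test_nonnegative_on_random_tables(self, rng):
        for _ in range(200):
            k = rng.integers(2, 7)
            counts = rng.integers(0, 50, size=k)
            if counts.sum() == 0:
                continue
            props = rng.dirichlet(np.ones(k))
            assert g_squared(counts, props) >= -1e-9

    def test_degenerate_expected_is_finite_penalty(self):
        val = g_squared([10, 10], [0.0, 0.0], epsilon=1e-6)
        assert np.isfinite(val)

    def test_multiple_blocks_sum(self):
        a = g_squared([10, 10], [0.9, 0.1])
        b = g_squared([5, 15], [0.5, 0.5])
        both = g_squared([[10, 10], [5, 15]], [[0.9, 0.1], [0.5, 0.5]])
        assert both == pytest.approx(a + b)


class TestBIC:
    def test_zero_deviance_zero_params(self):
        assert bic(0.0, 0, 100) == 0.0

    def test_documented_formula(self):
        assert bic(10.0, 3, 756) == pytest.approx(10 + 3 * np.log(756))
        assert bic(10.0, 3, 756) == pytest.approx(29.884, abs=1e-3)

    def test_parameter_penalty_difference(self):
        n = 756
        assert bic(5.0, 14, n) - bic(5.0, 11, n) == pytest.approx(3 * np.log(n))

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            bic(1.0, 2, 0)


class TestFitDesign:
    def test_fit_is_deterministic_given_seed(
        self, full_trials, design_base, tiny_fit_config
    ):
        r1 = lba.fit_design(full_trials, design_base, tiny_fit_config, seed=5)
        r2 = lba.fit_design(full_trials, design_base, tiny_fit_config, seed=5)
        assert r1.g_squared == r2.g_squared
        assert r1.params.mean_rates == r2.params.mean_rates
        assert r1.bic == pytest.approx(bic(r1.g_squared, r1.k, r1.n))

    def test_prediction_noise_consistency(self, full_trials, design_base):
        """Final G^2 is stable against the simulation size of the
        predicted distributions (Monte-Carlo tolerance)."""
        g2 = []
        for n_sim in (6000, 12000):
            cfg = lba.FitConfig(
                n_sim=n_sim, n_restarts=2, n_candidates=50, max_iter=200, n_polish=1
            )
            g2.append(lba.fit_design(full_trials, design_base, cfg, seed=7).g_squared)
        assert abs(g2[0] - g2[1]) < 0.35 * max(g2)

    def test_missing_condition_rejected(self, full_trials, design_base, tiny_fit_config):
        partial = full_trials[full_trials["condition"] != "specified-repetition"]
        with pytest.raises(ValueError, match="specified-repetition"):
            lba.fit_design(partial, design_base, tiny_fit_config, seed=1)

    def test_results_surface(self, full_trials, design_rate, tiny_fit_config):
        res = lba.LBAModel(full_trials, design_rate, tiny_fit_config).fit(seed=3)
        assert res.k == 14
        assert res.nobs > 700
        text = res.summary()
        assert "G^2" in text and "BIC" in text and "mean_rate ratios" in text
        pred = res.predict(lba.Condition.CHOICE_REP_ABSENT, n_sim=2000, seed=1)
        assert np.all(np.diff(pred.rt_quantiles) >= 0)
        table = res.fit_table(n_sim=2000, seed=1)
        assert len(table) == 20  # 4 conditions x 5 quantile levels
        d = res.result.to_dict()
        assert d["k"] == 14 and np.isfinite(d["bic"])


class TestNestedDesigns:
    def test_richer_design_fits_at_least_as_well(self, full_trials, designs):
        """A design nesting another cannot fit the same data worse, up to
        optimizer and simulation tolerance."""
        cfg = lba.FitConfig(
            n_sim=10_000, n_restarts=3, n_candidates=80, max_iter=300, n_polish=1
        )
        g_base = lba.fit_design(full_trials, designs[0], cfg, seed=11).g_squared
        g_rate = lba.fit_design(full_trials, designs[3], cfg, seed=11).g_squared
        assert g_rate <= g_base + 5.0


class TestScalePinning:
    def test_pinned_rate_sd_is_scale_unit(self, full_trials, design_base):
        cfg = lba.FitConfig(
            n_sim=2000, n_restarts=1, n_candidates=20, max_iter=40,
            n_polish=0, pin_first_rate_sd=True,
        )
        res = lba.fit_design(full_trials, design_base, cfg, seed=2)
        assert res.params.rate_sds[0] == 1.0


class TestPlotting:
    def test_quantile_fit_plot_renders(self, full_trials, design_rate, tiny_fit_config):
        import matplotlib

        matplotlib.use("Agg")
        res = lba.LBAModel(full_trials, design_rate, tiny_fit_config).fit(seed=3)
        ax = res.plot_fit(n_sim=2000, seed=1)
        assert len(ax.lines) == 8  # 4 conditions x (observed + predicted)
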