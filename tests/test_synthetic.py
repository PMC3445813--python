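"""Task-session structure and synthetic behaviour generation."""

import numpy as np
import pytest

import lbaction as lba
from lbaction.synthetic import generate_session, generate_behavior, parse_actions


def max_run_length(types):
    best = run = 1
    for a, b in zip(types, types[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class TestSession:
    def test_default_composition(self):
        s = generate_session(lba.SessionSpec(), seed=0)
        counts = s["trial_type"].value_counts()
        assert len(s) == 1008
        assert counts["choice"] == 504
        assert counts["specified"] == 252
        assert counts["null"] == 252

    def test_exact_condition_split(self):
        s = generate_session(lba.SessionSpec(), seed=3)
        cond = s["condition"].value_counts()
        assert cond["choice-repetition-available"] == 252
        assert cond["choice-repetition-absent"] == 252
        assert cond["specified-repetition"] == 126
        assert cond["specified-nonrepetition"] == 126

    def test_run_length_constraint(self):
        for seed in range(50):
            s = generate_session(lba.SessionSpec(), seed=seed)
            assert max_run_length(list(s["trial_type"])) <= 4

    def test_deterministic_given_seed(self):
        a = generate_session(lba.SessionSpec(), seed=7)
        b = generate_session(lba.SessionSpec(), seed=7)
        assert a.to_csv() == b.to_csv()

    def test_onsets_follow_trial_duration(self):
        s = generate_session(lba.SessionSpec(n_trials=40), seed=1)
        np.testing.assert_allclose(np.diff(s["onset_s"]), 2.4)

    def test_condition_consistency(self):
        s = generate_session(lba.SessionSpec(), seed=9)
        act = s[s["trial_type"] != "null"]
        for _, row in act.iterrows():
            valid = parse_actions(row["valid_actions"])
            prev = int(row["previous_action"])
            cond = row["condition"]
            if cond == "choice-repetition-available":
                assert prev in valid and len(valid) == 3
            elif cond == "choice-repetition-absent":
                assert prev not in valid and len(valid) == 3
            elif cond == "specified-repetition":
                assert valid == (prev,)
            else:
                assert len(valid) == 1 and valid[0] != prev

    def test_single_flagged_first_action_trial(self):
        s = generate_session(lba.SessionSpec(), seed=2)
        assert s["first_action_trial"].sum() == 1
        first_action = s[s["trial_type"] != "null"].index[0]
        assert bool(s.loc[first_action, "first_action_trial"])

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            lba.SessionSpec(prop_choice=0.5, prop_specified=0.4, prop_null=0.4)

    def test_infeasible_run_constraint_fails(self):
        spec = lba.SessionSpec(
            n_trials=20, prop_choice=1.0, prop_specified=0.0, prop_null=0.0,
            max_run_same_type=4,
        )
        with pytest.raises(RuntimeError):
            generate_session(spec, seed=0)


class TestBehavior:
    def test_preserves_trial_count_and_order(self, small_session, small_trials):
        assert len(small_trials) == len(small_session)
        np.testing.assert_array_equal(
            small_trials["trial_index"], small_session["trial_index"]
        )
        np.testing.assert_array_equal(
            small_trials["trial_type"], small_session["trial_type"]
        )

    def test_realized_conditions_consistent_with_responses(self, small_trials):
        act = small_trials[small_trials["trial_type"] != "null"]
        prev = None
        for _, row in act.iterrows():
            valid = parse_actions(row["valid_actions"])
            if prev is not None:
                assert int(row["previous_action"]) == prev
                rep_in_valid = prev in valid
                if row["condition"] == "choice-repetition-available":
                    assert rep_in_valid
                elif row["condition"] == "choice-repetition-absent":
                    assert not rep_in_valid
            if not (row["response"] is None) and not np.all(
                np.isnan([row["rt_s"]])
            ):
                if row["response"] is not np.nan and row["response"] == row["response"]:
                    assert int(row["response"]) in valid
                    prev = int(row["response"])

    def test_deterministic_trial_tables(
        self, small_session, group_params, rate_mods, design_rate
    ):
        a = generate_behavior(small_session, group_params, rate_mods, design_rate, seed=5)
        b = generate_behavior(small_session, group_params, rate_mods, design_rate, seed=5)
        assert a.to_csv() == b.to_csv()

    def test_unit_ratio_repetition_rate_is_chance(
        self, group_params, design_rate
    ):
        mods = [lba.default_modulations(1.0, 1.0, 1.0)]
        k = n = 0
        for seed in range(3):
            s = generate_session(lba.SessionSpec(), seed=600 + seed)
            tr = generate_behavior(s, group_params, mods, design_rate, seed=700 + seed)
            act = tr[tr["response"].notna() & ~tr["first_action_trial"]]
            ra = act[act["condition"] == "choice-repetition-available"]
            k += int((ra["response"] == ra["previous_action"]).sum())
            n += len(ra)
        p = k / n
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(p - 1 / 3) < 4 * se

    def test_suppressing_ratio_lowers_repetition_rate(
        self, group_params, design_rate
    ):
        mods = [lba.default_modulations(beta_choice=0.6)]
        s = generate_session(lba.SessionSpec(), seed=801)
        tr = generate_behavior(s, group_params, mods, design_rate, seed=802)
        act = tr[tr["response"].notna() & ~tr["first_action_trial"]]
        ra = act[act["condition"] == "choice-repetition-available"]
        p = (ra["response"] == ra["previous_action"]).mean()
        n = len(ra)
        assert p < 1 / 3 - 3 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_sigma_near_zero_collapses_rts(self, design_rate):
        params = lba.LBAParams((2.0,) * 4, (1e-9,) * 4, 1.2, 1e-12, 0.25)
        mods = [lba.default_modulations(1.0, 1.0, 1.0)]
        s = generate_session(lba.SessionSpec(n_trials=120), seed=30)
        tr = generate_behavior(s, params, mods, design_rate, seed=31)
        rts = tr.loc[tr["response"].notna(), "rt_s"]
        assert rts.std() < 1e-6

    def test_high_omission_rate_warns(self, design_rate):
        params = lba.LBAParams((0.2,) * 4, (0.3,) * 4, 2.5, 0.1, 0.3)
        mods = [lba.default_modulations(1.0, 1.0, 1.0)]
        s = generate_session(lba.SessionSpec(n_trials=120), seed=40)
        with pytest.warns(UserWarning, match="omission rate"):
            generate_behavior(s, params, mods, design_rate, seed=41)


class TestParticipantJitter:
    def test_jitter_perturbs_rates_and_t0(self, group_params, rng):
        j = lba.jitter_participant(group_params, rng)
        assert j.mean_rates != group_params.mean_rates
        assert j.threshold == group_params.threshold
        assert j.non_decision >= 0.05

    def test_default_behaviour_matches_reported_scale(
        self, group_params, design_rate
    ):
        """The generator defaults land in the reported behavioural regime:
        repetition rate near 19%, specified responses faster than choices."""
        mods = [lba.default_modulations()]
        s = generate_session(lba.SessionSpec(), seed=900)
        tr = generate_behavior(s, group_params, mods, design_rate, seed=901)
        act = tr[tr["response"].notna() & ~tr["first_action_trial"]]
        ra = act[act["condition"] == "choice-repetition-available"]
        p_rep = (ra["response"] == ra["previous_action"]).mean()
        assert 0.10 < p_rep < 0.28
        rt_choice = act.loc[act["trial_type"] == "choice", "rt_s"].mean()
        rt_spec = act.loc[act["trial_type"] == "specified", "rt_s"].mean()
        assert rt_spec < rt_choice
        assert 0.45 < rt_spec < 0.75 and 0.5 < rt_choice < 0.8
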