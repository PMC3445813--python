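"""Design-family enumeration, parameter counting and per-trial expansion."""

import itertools

import numpy as np
import pytest

import lbaction as lba
from lbaction.design_space import ModelDesign, effective_params, parameter_count


def brute_force_designs():
    """Independent oracle: all 64 flag vectors, filtered by the stated
    meaningfulness rules and deduplicated after normalisation."""
    seen = set()
    for flags in itertools.product([False, True], repeat=6):
        f1, f2, f3, f4, f5, f6 = flags
        if f6 and not (f2 or f3 or f4):
            f6 = False
        if f5 and not f3:
            f5 = False
        seen.add((f1, f2, f3, f4, f5, f6))
    return seen


class TestEnumeration:
    def test_matches_brute_force_oracle(self, designs):
        oracle = brute_force_designs()
        got = {d.flags for d in designs}
        assert got == oracle
        assert len(designs) == len(oracle) == 46

    def test_duplicate_free_and_closed(self, designs):
        assert len({d.flags for d in designs}) == len(designs)
        for d in designs:
            assert d.is_canonical()
            assert d.canonicalize() == d

    def test_first_design_is_null_model(self, designs):
        assert designs[0].flags == (False,) * 6

    def test_fourth_design_is_repetition_only_rate_modulation(self, designs):
        d = designs[3]
        assert d.f3_rate_varies_by_condition
        assert not d.f6_changes_apply_to_all
        assert sum(d.flags) == 1

    def test_ordering_is_stable(self, designs):
        assert designs == lba.enumerate_designs()


class TestParameterCount:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((0, 0, 0, 0, 0, 0), 11),  # base model
            ((0, 0, 1, 0, 0, 0), 14),  # rate modulation: +3 condition ratios
            ((1, 0, 0, 0, 0, 0), 14),  # per-accumulator start ranges
            ((0, 1, 1, 1, 0, 0), 20),  # three modulated parameters
        ],
    )
    def test_counts(self, flags, expected):
        assert parameter_count(ModelDesign.from_flags(flags)) == expected

    def test_each_modulated_parameter_adds_three(self):
        f3 = ModelDesign.from_flags((0, 0, 1, 0, 0, 0))
        f34 = ModelDesign.from_flags((0, 0, 1, 1, 0, 0))
        assert parameter_count(f34) == parameter_count(f3) + 3

    def test_monotone_in_features(self, designs):
        for d in designs:
            for i in range(6):
                flags = list(d.flags)
                if flags[i]:
                    continue
                flags[i] = True
                richer = ModelDesign.from_flags(flags)
                if richer.is_canonical():
                    assert parameter_count(richer) >= parameter_count(d)

    def test_rejects_non_meaningful_design(self):
        with pytest.raises(ValueError):
            parameter_count(ModelDesign.from_flags((0, 0, 0, 0, 0, 1)))


def _mods(beta, scope="repetition-accumulator-only"):
    return lba.ModulationSet(
        "mean_rate",
        ratio_choice_repetition_available=beta,
        ratio_specified_repetition=1.0,
        ratio_specified_nonrepetition=1.0,
        scope=scope,
    )


class TestEffectiveParams:
    def setup_method(self):
        self.design = ModelDesign.from_flags((0, 0, 1, 0, 0, 0))
        self.design_all = ModelDesign.from_flags((0, 0, 1, 0, 0, 1))

    def test_repetition_only_scales_previous_action(self):
        base = lba.LBAParams((1, 1, 1, 1), (0.5,) * 4, 1.0, 0.2, 0.1)
        eff = effective_params(
            base, _mods(0.7), self.design,
            lba.Condition.CHOICE_REP_AVAILABLE, 0, (0, 1, 2),
        )
        np.testing.assert_allclose(eff.mean_rates, [0.7, 1.0, 1.0])

    def test_all_scope_scales_every_valid_accumulator(self):
        base = lba.LBAParams((1, 2, 1, 1), (0.5,) * 4, 1.0, 0.2, 0.1)
        eff = effective_params(
            base, _mods(0.5, scope="all-accumulators"), self.design_all,
            lba.Condition.CHOICE_REP_AVAILABLE, 0, (0, 1, 3),
        )
        np.testing.assert_allclose(eff.mean_rates, [0.5, 1.0, 0.5])

    def test_baseline_condition_unchanged(self):
        base = lba.LBAParams((1.3, 0.9, 2.0, 1.1), (0.4,) * 4, 1.2, 0.3, 0.2)
        eff = effective_params(
            base, _mods(0.5), self.design,
            lba.Condition.CHOICE_REP_ABSENT, 3, (0, 1, 2),
        )
        np.testing.assert_allclose(eff.mean_rates, [1.3, 0.9, 2.0])
        np.testing.assert_allclose(eff.thresholds, 1.2)

    def test_unit_ratios_are_identity_everywhere(self, designs):
        base = lba.LBAParams((1.3, 0.9, 2.0, 1.1), (0.4, 0.5, 0.6, 0.7), 1.2, 0.3, 0.2)
        cases = [
            (lba.Condition.CHOICE_REP_AVAILABLE, 1, (0, 1, 2)),
            (lba.Condition.CHOICE_REP_ABSENT, 3, (0, 1, 2)),
            (lba.Condition.SPECIFIED_REP, 2, (2,)),
            (lba.Condition.SPECIFIED_NONREP, 2, (0,)),
        ]
        for cond, prev, valid in cases:
            eff = effective_params(base, _mods(1.0), self.design, cond, prev, valid)
            idx = np.asarray(valid)
            np.testing.assert_allclose(eff.mean_rates, np.asarray(base.mean_rates)[idx])
            np.testing.assert_allclose(eff.rate_sds, np.asarray(base.rate_sds)[idx])
            np.testing.assert_allclose(eff.thresholds, base.threshold)
            np.testing.assert_allclose(eff.non_decisions, base.non_decision)

    def test_specified_condition_modulates_single_accumulator(self):
        base = lba.LBAParams((1, 1, 1, 1), (0.5,) * 4, 1.0, 0.2, 0.1)
        mods = lba.ModulationSet("mean_rate", 1.0, 1.5, 0.8)
        eff = effective_params(
            base, mods, self.design, lba.Condition.SPECIFIED_REP, 2, (2,)
        )
        np.testing.assert_allclose(eff.mean_rates, [1.5])
        eff = effective_params(
            base, mods, self.design, lba.Condition.SPECIFIED_NONREP, 2, (0,)
        )
        np.testing.assert_allclose(eff.mean_rates, [0.8])

    def test_only_valid_actions_returned(self):
        base = lba.LBAParams((1, 1, 1, 1), (0.5,) * 4, 1.0, 0.2, 0.1)
        eff = effective_params(
            base, _mods(0.7), self.design,
            lba.Condition.CHOICE_REP_AVAILABLE, 1, (1, 2, 3),
        )
        assert set(eff.actions) == {1, 2, 3}

    @pytest.mark.parametrize(
        "cond,prev,valid",
        [
            (lba.Condition.CHOICE_REP_AVAILABLE, 3, (0, 1, 2)),  # prev not valid
            (lba.Condition.CHOICE_REP_ABSENT, 0, (0, 1, 2)),  # prev valid
            (lba.Condition.SPECIFIED_REP, 1, (2,)),  # cue != previous
            (lba.Condition.SPECIFIED_NONREP, 2, (2,)),  # cue == previous
            (lba.Condition.CHOICE_REP_ABSENT, 3, (0, 1)),  # wrong set size
        ],
    )
    def test_inconsistent_context_rejected(self, cond, prev, valid):
        base = lba.LBAParams((1, 1, 1, 1), (0.5,) * 4, 1.0, 0.2, 0.1)
        with pytest.raises(ValueError):
            effective_params(base, _mods(0.7), self.design, cond, prev, valid)


class TestParamInvariants:
    def test_start_range_must_stay_below_threshold(self):
        with pytest.raises(ValueError):
            lba.LBAParams((1, 1, 1, 1), (0.5,) * 4, 1.0, 1.0, 0.1)

    def test_rate_sds_positive(self):
        with pytest.raises(ValueError):
            lba.LBAParams((1, 1, 1, 1), (0.5, 0.5, 0.0, 0.5), 1.0, 0.2, 0.1)

    def test_json_round_trip(self, design_rate):
        d = lba.ModelDesign.from_dict(design_rate.to_dict())
        assert d == design_rate
        m = lba.default_modulations()
        assert lba.ModulationSet.from_dict(m.to_dict()) == m
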