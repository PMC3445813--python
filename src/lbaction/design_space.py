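"""The constrained family of accumulator-model designs.

A model design is a combination of six binary structural features laid on
top of the 11-parameter base model (four mean rates, four rate SDs,
threshold, start-point range, non-decision time):

1. ``start_varies_by_accumulator`` — the start-point range ``c0`` differs
   across accumulators (prior response bias).
2. ``threshold_varies_by_condition`` — ``b`` is modulated by condition.
3. ``rate_varies_by_condition`` — the mean rates are modulated by condition.
4. ``nondecision_varies_by_condition`` — ``t0`` is modulated by condition.
5. ``rates_equal_in_specified`` — a single shared mean rate replaces the
   per-accumulator means in specified-trial conditions.
6. ``changes_apply_to_all`` — condition modulations multiply every active
   accumulator rather than only the previous action's accumulator.

Condition modulation is multiplicative: one ratio per non-baseline
condition per modulated parameter, with choice / repetition-absent as the
baseline (implicit ratio 1).

Not every flag vector is a distinct model.  Two normalisation rules apply:

* feature 6 is interpretable only when at least one of features 2/3/4 is
  on (there must be a modulation for its scope to apply to);
* feature 5 is interpretable only when feature 3 is on — equalising rates
  solely in specified trials already makes the rates differ between
  specified and choice conditions, which is exactly feature 3.

Uninterpretable flags are normalised off and duplicates removed; 46
distinct designs remain of the 64 raw combinations.  Designs are ordered by
number of active features, then lexicographically by feature index, so
design 1 is the unconstrained-feature-free base model and design 4 is the
rate-modulation / repetition-accumulator-only design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    N_ACTIONS,
    Condition,
    LBAParams,
    ModulatedParameter,
    ModulationScope,
    ModulationSet,
)

__all__ = [
    "ModelDesign",
    "enumerate_designs",
    "parameter_count",
    "design_table",
    "EffectiveParams",
    "effective_params",
    "validate_trial_context",
]

#: Number of free parameters in the base model: mu1..4, sigma1..4, b, c0, t0.
BASE_PARAMETER_COUNT = 11
#: Non-baseline conditions each contribute one ratio per modulated parameter.
N_MODULATED_CONDITIONS = 3


@dataclass(frozen=True)
class ModelDesign:
    """One member of the six-feature design family."""

    f1_start_varies_by_accumulator: bool = False
    f2_threshold_varies_by_condition: bool = False
    f3_rate_varies_by_condition: bool = False
    f4_nondecision_varies_by_condition: bool = False
    f5_rates_equal_in_specified: bool = False
    f6_changes_apply_to_all: bool = False

    @property
    def flags(self) -> tuple[bool, ...]:
        return (
            self.f1_start_varies_by_accumulator,
            self.f2_threshold_varies_by_condition,
            self.f3_rate_varies_by_condition,
            self.f4_nondecision_varies_by_condition,
            self.f5_rates_equal_in_specified,
            self.f6_changes_apply_to_all,
        )

    @property
    def has_modulation(self) -> bool:
        return (
            self.f2_threshold_varies_by_condition
            or self.f3_rate_varies_by_condition
            or self.f4_nondecision_varies_by_condition
        )

    @property
    def modulated_parameters(self) -> tuple[ModulatedParameter, ...]:
        out = []
        if self.f2_threshold_varies_by_condition:
            out.append(ModulatedParameter.THRESHOLD)
        if self.f3_rate_varies_by_condition:
            out.append(ModulatedParameter.MEAN_RATE)
        if self.f4_nondecision_varies_by_condition:
            out.append(ModulatedParameter.NON_DECISION)
        return tuple(out)

    @property
    def scope(self) -> ModulationScope:
        return (
            ModulationScope.ALL
            if self.f6_changes_apply_to_all
            else ModulationScope.REPETITION_ONLY
        )

    def is_canonical(self) -> bool:
        """True when no flag is uninterpretable under the normalisation
        rules (f6 requires f2|f3|f4; f5 requires f3)."""
        if self.f6_changes_apply_to_all and not self.has_modulation:
            return False
        if self.f5_rates_equal_in_specified and not self.f3_rate_varies_by_condition:
            return False
        return True

    def canonicalize(self) -> "ModelDesign":
        """Normalise uninterpretable flags off."""
        f5 = self.f5_rates_equal_in_specified and self.f3_rate_varies_by_condition
        f6 = self.f6_changes_apply_to_all and self.has_modulation
        return ModelDesign(
            self.f1_start_varies_by_accumulator,
            self.f2_threshold_varies_by_condition,
            self.f3_rate_varies_by_condition,
            self.f4_nondecision_varies_by_condition,
            f5,
            f6,
        )

    @classmethod
    def from_flags(cls, flags: Sequence[bool | int]) -> "ModelDesign":
        if len(flags) != 6:
            raise ValueError("expected six feature flags")
        return cls(*(bool(f) for f in flags))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelDesign":
        return cls(**dict(d))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    def label(self) -> str:
        on = [f"f{i + 1}" for i, f in enumerate(self.flags) if f]
        return "+".join(on) if on else "base"


def enumerate_designs() -> list[ModelDesign]:
    """All distinct, meaningful designs in a stable documented order.

    Every one of the 2^6 raw flag vectors is generated, normalised and
    deduplicated; the survivors are sorted by (number of active features,
    lexicographic feature indices).  Re-applying the filter to the output
    is a no-op.
    """
    seen: set[tuple[bool, ...]] = set()
    designs: list[ModelDesign] = []
    for code in range(64):
        raw = ModelDesign.from_flags([(code >> i) & 1 for i in range(6)])
        canon = raw.canonicalize()
        if canon.flags not in seen:
            seen.add(canon.flags)
            designs.append(canon)
    designs.sort(key=lambda d: (sum(d.flags), tuple(i for i, f in enumerate(d.flags) if f)))
    return designs


def parameter_count(design: ModelDesign) -> int:
    """Number of free scalar parameters of a design.

    Base 11, plus 3 extra start ranges (feature 1), plus one ratio per
    non-baseline condition per modulated parameter (features 2/3/4), plus
    the shared specified-trial mean rate (feature 5).  Counts are nominal:
    the race model's scale invariance (a joint rescaling of rates,
    threshold and start range leaves predictions unchanged) is not
    subtracted.
    """
    if not isinstance(design, ModelDesign):
        raise TypeError("design must be a ModelDesign")
    if not design.is_canonical():
        raise ValueError(f"design {design.flags} is not meaningful (normalise first)")
    k = BASE_PARAMETER_COUNT
    if design.f1_start_varies_by_accumulator:
        k += N_ACTIONS - 1
    k += N_MODULATED_CONDITIONS * len(design.modulated_parameters)
    if design.f5_rates_equal_in_specified:
        k += 1
    return k


def design_table() -> pd.DataFrame:
    """The full design list as a table: index (1-based), the six flags and
    the nominal parameter count."""
    rows = []
    for i, d in enumerate(enumerate_designs(), start=1):
        row = {"design": i}
        row.update({f"f{j + 1}": int(f) for j, f in enumerate(d.flags)})
        row["n_params"] = parameter_count(d)
        row["label"] = d.label()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-trial effective parameters


def validate_trial_context(
    condition: Condition,
    previous_action: int | None,
    valid_actions: Sequence[int],
) -> tuple[Condition, np.ndarray]:
    """Check the consistency of a trial's condition, previous action and
    valid-action set; return the condition and the sorted valid actions."""
    condition = Condition(condition)
    valid = np.unique(np.asarray(list(valid_actions), dtype=int))
    if np.any(valid < 0) or np.any(valid >= N_ACTIONS):
        raise ValueError(f"action ids must be in [0, {N_ACTIONS - 1}]: {valid}")
    n_expected = 3 if condition.trial_type.value == "choice" else 1
    if valid.size != n_expected:
        raise ValueError(
            f"{condition.value} trials need {n_expected} valid actions, got {valid.size}"
        )
    if previous_action is None:
        raise ValueError(f"{condition.value} requires a previous action")
    previous_action = int(previous_action)
    in_valid = previous_action in valid
    if condition is Condition.CHOICE_REP_AVAILABLE and not in_valid:
        raise ValueError("repetition-available trial excludes the previous action")
    if condition is Condition.CHOICE_REP_ABSENT and in_valid:
        raise ValueError("repetition-absent trial includes the previous action")
    if condition is Condition.SPECIFIED_REP and valid[0] != previous_action:
        raise ValueError("specified-repetition trial must cue the previous action")
    if condition is Condition.SPECIFIED_NONREP and valid[0] == previous_action:
        raise ValueError("specified-nonrepetition trial cues the previous action")
    return condition, valid


@dataclass(frozen=True)
class EffectiveParams:
    """Per-trial parameters of the active accumulators only (sorted by
    action id).  All fields are aligned length-k arrays, k = 3 (choice)
    or 1 (specified)."""

    actions: np.ndarray
    mean_rates: np.ndarray
    rate_sds: np.ndarray
    thresholds: np.ndarray
    start_ranges: np.ndarray
    non_decisions: np.ndarray

    def __len__(self) -> int:
        return len(self.actions)


def _as_modulation_map(
    mods: ModulationSet | Iterable[ModulationSet] | Mapping[ModulatedParameter, ModulationSet] | None,
) -> dict[ModulatedParameter, ModulationSet]:
    if mods is None:
        return {}
    if isinstance(mods, ModulationSet):
        mods = [mods]
    if isinstance(mods, Mapping):
        mods = list(mods.values())
    out: dict[ModulatedParameter, ModulationSet] = {}
    for m in mods:
        if m.modulated_parameter in out:
            raise ValueError(f"duplicate modulation set for {m.modulated_parameter}")
        out[m.modulated_parameter] = m
    return out


def effective_params(
    base: LBAParams,
    mods: ModulationSet | Iterable[ModulationSet] | Mapping[ModulatedParameter, ModulationSet] | None,
    design: ModelDesign,
    condition: Condition,
    previous_action: int | None,
    valid_actions: Sequence[int],
) -> EffectiveParams:
    """Expand base parameters into one trial's effective per-accumulator
    parameters under a design, condition and previous action.

    Ratios multiply the modulated parameter of either the previous action's
    accumulator only (repetition-only scope; in specified conditions, the
    single active accumulator) or of all active accumulators.  The baseline
    condition returns base values unchanged.
    """
    condition, valid = validate_trial_context(condition, previous_action, valid_actions)
    if not design.is_canonical():
        raise ValueError("design is not in canonical form")
    mod_map = _as_modulation_map(mods)
    allowed = set(design.modulated_parameters)
    extra = set(mod_map) - allowed
    if extra:
        raise ValueError(f"design does not modulate {sorted(p.value for p in extra)}")

    mu = np.asarray(base.mean_rates, dtype=float)[valid].copy()
    if (
        design.f5_rates_equal_in_specified
        and condition.trial_type.value == "specified"
    ):
        if base.specified_mean is None:
            raise ValueError("design equalises specified rates but specified_mean is unset")
        mu[:] = base.specified_mean
    sd = np.asarray(base.rate_sds, dtype=float)[valid].copy()
    if design.f1_start_varies_by_accumulator:
        c0 = base.start_ranges[valid].copy()
    else:
        c0 = np.full(valid.size, float(np.asarray(base.start_range).reshape(-1)[0]))
    b = np.full(valid.size, base.threshold)
    t0 = np.full(valid.size, base.non_decision)

    if not condition.is_baseline:
        # which active accumulators the ratio multiplies
        if condition.trial_type.value == "specified":
            target = np.ones(valid.size, dtype=bool)
        else:  # choice repetition-available
            target_all = np.ones(valid.size, dtype=bool)
            target_rep = valid == int(previous_action)
            target = None  # chosen per-set below
        arrays = {
            ModulatedParameter.MEAN_RATE: mu,
            ModulatedParameter.THRESHOLD: b,
            ModulatedParameter.NON_DECISION: t0,
        }
        for pname in design.modulated_parameters:
            mset = mod_map.get(pname)
            if mset is None:
                continue
            ratio = mset.ratio_for(condition)
            if condition.trial_type.value == "specified":
                mask = target
            else:
                mask = target_all if mset.scope is ModulationScope.ALL else target_rep
            arrays[pname][mask] *= ratio

    return EffectiveParams(
        actions=valid,
        mean_rates=mu,
        rate_sds=sd,
        thresholds=b,
        start_ranges=c0,
        non_decisions=t0,
    )
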