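"""Core parameter containers for the four-accumulator race model.

The task has four response alternatives (four fingers). Each alternative is
represented by a linear ballistic accumulator: evidence starts at a value
drawn uniformly from ``[0, c0]``, grows linearly at a rate drawn once per
trial from ``Normal(mu_i, sigma_i)``, and the first accumulator to reach the
threshold ``b`` triggers its response.  Observed response time is the winning
accumulator's finishing time plus a constant non-decision latency ``t0``.

Trials fall into four conditions defined by trial type (free choice among
three alternatives vs. a single cued alternative) crossed with the relation
to the previous response (the previous action is among the valid options, or
not).  The choice / repetition-absent condition is the baseline; parameter
changes in the other three conditions are expressed as multiplicative
ratios relative to it.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

N_ACTIONS = 4

__all__ = [
    "N_ACTIONS",
    "Condition",
    "TrialType",
    "ModulatedParameter",
    "ModulationScope",
    "LBAParams",
    "ModulationSet",
]


class TrialType(str, enum.Enum):
    """Trial type: free selection among three alternatives, a single cued
    alternative, or a null event (no response required)."""

    CHOICE = "choice"
    SPECIFIED = "specified"
    NULL = "null"


class Condition(str, enum.Enum):
    """The four experimental conditions.

    ``CHOICE_REP_ABSENT`` is the baseline condition: all modulation ratios
    equal 1 there by construction.
    """

    CHOICE_REP_AVAILABLE = "choice-repetition-available"
    CHOICE_REP_ABSENT = "choice-repetition-absent"
    SPECIFIED_REP = "specified-repetition"
    SPECIFIED_NONREP = "specified-nonrepetition"

    @property
    def trial_type(self) -> TrialType:
        if self in (Condition.CHOICE_REP_AVAILABLE, Condition.CHOICE_REP_ABSENT):
            return TrialType.CHOICE
        return TrialType.SPECIFIED

    @property
    def is_baseline(self) -> bool:
        return self is Condition.CHOICE_REP_ABSENT


#: Non-baseline conditions, in the order modulation ratios are stored.
MODULATED_CONDITIONS = (
    Condition.CHOICE_REP_AVAILABLE,
    Condition.SPECIFIED_REP,
    Condition.SPECIFIED_NONREP,
)


class ModulatedParameter(str, enum.Enum):
    MEAN_RATE = "mean_rate"
    THRESHOLD = "threshold"
    NON_DECISION = "non_decision"


class ModulationScope(str, enum.Enum):
    """Whether a condition's ratio multiplies only the accumulator of the
    previously executed action, or every active accumulator.

    With repetition-only scope the distinction matters only in the
    choice / repetition-available condition: in specified conditions a single
    accumulator is active and the ratio applies to it either way, and the
    baseline condition is never modulated.
    """

    REPETITION_ONLY = "repetition-accumulator-only"
    ALL = "all-accumulators"


@dataclass(frozen=True)
class LBAParams:
    """Base (baseline-condition) parameters of one participant's model.

    Parameters
    ----------
    mean_rates : 4-vector of mean accumulation rates (evidence units / s).
    rate_sds : 4-vector of rate standard deviations (evidence units / s).
    threshold : response threshold ``b`` (evidence units), > 0.
    start_range : upper bound ``c0`` of the uniform start-point
        distribution; a scalar, or a 4-vector when start points differ by
        accumulator.  Must satisfy ``0 <= c0 < b``.
    non_decision : non-decision time ``t0`` in seconds, >= 0.
    specified_mean : optional single mean rate used for every accumulator in
        specified-trial conditions (the "equal specified rates" constraint);
        ``None`` when the constraint is off.
    """

    mean_rates: tuple[float, float, float, float]
    rate_sds: tuple[float, float, float, float]
    threshold: float
    start_range: float | tuple[float, float, float, float]
    non_decision: float
    specified_mean: float | None = None

    def __post_init__(self):
        mr = np.asarray(self.mean_rates, dtype=float)
        sd = np.asarray(self.rate_sds, dtype=float)
        if mr.shape != (N_ACTIONS,) or sd.shape != (N_ACTIONS,):
            raise ValueError("mean_rates and rate_sds must have length 4")
        if not np.all(sd > 0):
            raise ValueError("rate_sds must be strictly positive")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        c0 = np.asarray(self.start_range, dtype=float)
        if np.any(c0 < 0):
            raise ValueError("start_range must be >= 0")
        if np.any(c0 >= self.threshold):
            raise ValueError("start_range must be < threshold")
        if self.non_decision < 0:
            raise ValueError("non_decision must be >= 0")
        object.__setattr__(self, "mean_rates", tuple(float(x) for x in mr))
        object.__setattr__(self, "rate_sds", tuple(float(x) for x in sd))
        if c0.ndim == 0:
            object.__setattr__(self, "start_range", float(c0))
        else:
            if c0.shape != (N_ACTIONS,):
                raise ValueError("per-accumulator start_range must have length 4")
            object.__setattr__(self, "start_range", tuple(float(x) for x in c0))

    @property
    def start_ranges(self) -> np.ndarray:
        """Start-point range per accumulator as a length-4 array."""
        c0 = np.asarray(self.start_range, dtype=float)
        if c0.ndim == 0:
            return np.full(N_ACTIONS, float(c0))
        return c0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LBAParams":
        d = dict(d)
        sr = d["start_range"]
        if isinstance(sr, (list, tuple)):
            d["start_range"] = tuple(sr)
        d["mean_rates"] = tuple(d["mean_rates"])
        d["rate_sds"] = tuple(d["rate_sds"])
        return cls(**d)


@dataclass(frozen=True)
class ModulationSet:
    """Multiplicative condition ratios for one modulated parameter.

    One ratio per non-baseline condition, shared across accumulator
    identities; the baseline (choice / repetition-absent) condition has an
    implicit ratio of 1.
    """

    modulated_parameter: ModulatedParameter
    ratio_choice_repetition_available: float = 1.0
    ratio_specified_repetition: float = 1.0
    ratio_specified_nonrepetition: float = 1.0
    scope: ModulationScope = ModulationScope.REPETITION_ONLY

    def __post_init__(self):
        for r in (
            self.ratio_choice_repetition_available,
            self.ratio_specified_repetition,
            self.ratio_specified_nonrepetition,
        ):
            if not r > 0:
                raise ValueError("modulation ratios must be > 0")
        object.__setattr__(
            self, "modulated_parameter", ModulatedParameter(self.modulated_parameter)
        )
        object.__setattr__(self, "scope", ModulationScope(self.scope))

    def ratio_for(self, condition: Condition) -> float:
        if condition is Condition.CHOICE_REP_ABSENT:
            return 1.0
        if condition is Condition.CHOICE_REP_AVAILABLE:
            return self.ratio_choice_repetition_available
        if condition is Condition.SPECIFIED_REP:
            return self.ratio_specified_repetition
        return self.ratio_specified_nonrepetition

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modulated_parameter"] = self.modulated_parameter.value
        d["scope"] = self.scope.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModulationSet":
        return cls(**dict(d))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())
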