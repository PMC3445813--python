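"""Stochastic forward simulation of the accumulator race.

Each trial draws an independent start point ``U[0, c0_i]`` and rate
``N(mu_i, sigma_i)`` for every active accumulator; accumulator ``i``'s
finishing time is ``(b_i - start_i) / rate_i`` when the rate is positive,
and infinite otherwise (a negative-rate accumulator never reaches
threshold).  The response is the earliest finisher plus its non-decision
time.  Trials on which no accumulator finishes before the deadline are
omissions, mirroring the behavioural exclusion of non-responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .design_space import (
    EffectiveParams,
    ModelDesign,
    _as_modulation_map,
    effective_params,
)
from .parameters import (
    N_ACTIONS,
    Condition,
    LBAParams,
    ModulatedParameter,
    ModulationScope,
    ModulationSet,
)

__all__ = [
    "QUANTILE_LEVELS",
    "DEFAULT_DEADLINE",
    "TrialOutcome",
    "ConditionSummary",
    "simulate_trial",
    "predict_summaries",
]

#: RT quantile levels used throughout summarisation and fitting.
QUANTILE_LEVELS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])

#: Trial duration in seconds; responses after this are omissions.
DEFAULT_DEADLINE = 2.4


@dataclass(frozen=True)
class TrialOutcome:
    """Outcome of one simulated trial: the selected action id and the
    response time in seconds, or ``None``/``nan`` for an omission."""

    selected_action: int | None
    rt: float | None

    @property
    def is_omission(self) -> bool:
        return self.selected_action is None


@dataclass(frozen=True)
class ConditionSummary:
    """Behavioural summary of one condition (observed or model-predicted).

    ``rt_quantiles`` are taken over responded trials only; RT quantiles use
    linear interpolation of the empirical CDF.  ``selection_probs`` are
    defective per-action probabilities (response counts over *all* trials),
    so ``selection_probs.sum() + omission_rate == 1``.
    """

    rt_quantiles: np.ndarray
    selection_probs: np.ndarray
    n_trials: int
    omission_rate: float
    levels: np.ndarray = field(default_factory=lambda: QUANTILE_LEVELS.copy())

    def __post_init__(self):
        q = np.asarray(self.rt_quantiles, dtype=float)
        if np.any(np.diff(q) < 0):
            raise ValueError("RT quantiles must be non-decreasing")
        p = np.asarray(self.selection_probs, dtype=float)
        if np.any(p < -1e-12):
            raise ValueError("selection probabilities must be nonnegative")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        object.__setattr__(self, "rt_quantiles", q)
        object.__setattr__(self, "selection_probs", p)

    def to_dict(self) -> dict:
        return {
            "levels": list(map(float, self.levels)),
            "rt_quantiles": list(map(float, self.rt_quantiles)),
            "selection_probs": list(map(float, self.selection_probs)),
            "n_trials": int(self.n_trials),
            "omission_rate": float(self.omission_rate),
        }


# ---------------------------------------------------------------------------
# vectorised race core


def race(mu, sigma, b, c0, t0, z, u, deadline=DEFAULT_DEADLINE):
    """Run ``n`` races of ``k`` accumulators from pre-drawn noise.

    Parameters are arrays broadcastable to the (n, k) shape of the standard
    normal draws ``z`` and uniform draws ``u``.  Returns ``(winner_col,
    rt)`` where ``winner_col`` is the column index of the winning
    accumulator (-1 for omissions) and ``rt`` is the response time in
    seconds (nan for omissions).

    A start point at or above threshold finishes immediately (time 0); a
    non-positive rate never finishes.
    """
    z = np.atleast_2d(z)
    u = np.atleast_2d(u)
    rates = mu + sigma * z
    gap = b - u * c0
    with np.errstate(divide="ignore", invalid="ignore"):
        ft = np.where(gap <= 0, 0.0, np.where(rates > 0, gap / rates, np.inf))
    winner = np.argmin(ft, axis=1)
    rows = np.arange(ft.shape[0])
    decision = ft[rows, winner]
    t0_arr = np.broadcast_to(np.asarray(t0, dtype=float), ft.shape)
    rt = decision + t0_arr[rows, winner]
    responded = np.isfinite(rt) & (rt <= deadline)
    rt = np.where(responded, rt, np.nan)
    winner = np.where(responded, winner, -1)
    return winner, rt


def simulate_trial(
    params: EffectiveParams,
    rng: np.random.Generator,
    deadline: float = DEFAULT_DEADLINE,
) -> TrialOutcome:
    """Simulate a single trial from its effective per-accumulator
    parameters; reproducible given the generator state."""
    k = len(params)
    z = rng.standard_normal((1, k))
    u = rng.random((1, k))
    winner, rt = race(
        params.mean_rates,
        params.rate_sds,
        params.thresholds,
        params.start_ranges,
        params.non_decisions,
        z,
        u,
        deadline=deadline,
    )
    if winner[0] < 0:
        return TrialOutcome(None, None)
    return TrialOutcome(int(params.actions[winner[0]]), float(rt[0]))


# ---------------------------------------------------------------------------
# condition-level prediction


def sample_condition_configs(
    condition: Condition,
    n: int,
    rng: np.random.Generator,
    previous_action_mix: Mapping[int, float] | Sequence[float] | None = None,
):
    """Draw ``n`` (previous action, valid-action set) configurations for a
    condition.

    Previous actions are drawn from ``previous_action_mix`` (default
    uniform over the four actions).  Valid sets follow the task rules:
    repetition-available excludes one of the three non-previous fingers at
    random; repetition-absent excludes the previous finger; specified
    repetition cues the previous finger; specified non-repetition cues a
    uniform non-previous finger.

    Returns ``(prev, valid)`` with ``valid`` a sorted (n, k) action-id
    array, k = 3 or 1.
    """
    condition = Condition(condition)
    if previous_action_mix is None:
        probs = np.full(N_ACTIONS, 1.0 / N_ACTIONS)
    elif isinstance(previous_action_mix, Mapping):
        probs = np.zeros(N_ACTIONS)
        for a, p in previous_action_mix.items():
            probs[int(a)] = p
        probs = probs / probs.sum()
    else:
        probs = np.asarray(previous_action_mix, dtype=float)
        probs = probs / probs.sum()
    prev = rng.choice(N_ACTIONS, size=n, p=probs)

    # the three non-previous actions of each trial, as an (n, 3) array
    others = np.argsort(np.equal.outer(prev, np.arange(N_ACTIONS)), axis=1, kind="stable")[:, :3]
    others = np.sort(others, axis=1)

    if condition is Condition.CHOICE_REP_ABSENT:
        valid = others
    elif condition is Condition.CHOICE_REP_AVAILABLE:
        drop = rng.integers(0, 3, size=n)
        keep = np.ones((n, 3), dtype=bool)
        keep[np.arange(n), drop] = False
        valid = np.sort(
            np.column_stack([prev, others[keep].reshape(n, 2)]), axis=1
        )
    elif condition is Condition.SPECIFIED_REP:
        valid = prev[:, None].copy()
    else:  # specified non-repetition
        pick = rng.integers(0, 3, size=n)
        valid = others[np.arange(n), pick][:, None]
    return prev, valid


def effective_arrays(
    base: LBAParams,
    mods,
    design: ModelDesign,
    condition: Condition,
    prev: np.ndarray,
    valid: np.ndarray,
):
    """Vectorised analogue of :func:`lbaction.design_space.effective_params`
    for ``n`` trials of one condition: returns (mu, sigma, b, c0, t0)
    arrays of shape (n, k)."""
    condition = Condition(condition)
    mod_map = _as_modulation_map(mods)
    n, k = valid.shape
    mu = np.asarray(base.mean_rates, dtype=float)[valid]
    if design.f5_rates_equal_in_specified and condition.trial_type.value == "specified":
        if base.specified_mean is None:
            raise ValueError("design equalises specified rates but specified_mean is unset")
        mu = np.full((n, k), float(base.specified_mean))
    sd = np.asarray(base.rate_sds, dtype=float)[valid]
    if design.f1_start_varies_by_accumulator:
        c0 = base.start_ranges[valid]
    else:
        c0 = np.full((n, k), float(np.asarray(base.start_range).reshape(-1)[0]))
    b = np.full((n, k), base.threshold)
    t0 = np.full((n, k), base.non_decision)

    if not condition.is_baseline:
        arrays = {
            ModulatedParameter.MEAN_RATE: mu,
            ModulatedParameter.THRESHOLD: b,
            ModulatedParameter.NON_DECISION: t0,
        }
        rep_mask = valid == prev[:, None]
        for pname in design.modulated_parameters:
            mset = mod_map.get(pname)
            if mset is None:
                continue
            ratio = mset.ratio_for(condition)
            if (
                condition.trial_type.value == "specified"
                or mset.scope is ModulationScope.ALL
            ):
                arrays[pname] *= ratio
            else:
                arrays[pname][rep_mask] *= ratio
    return mu, sd, b, c0, t0


def summarize_simulation(winner_action, rt, n_total=None) -> ConditionSummary:
    """Build a :class:`ConditionSummary` from per-trial winning actions
    (-1 = omission) and RTs."""
    winner_action = np.asarray(winner_action)
    rt = np.asarray(rt, dtype=float)
    if n_total is None:
        n_total = winner_action.size
    responded = winner_action >= 0
    n_resp = int(responded.sum())
    if n_resp == 0:
        raise RuntimeError("all simulated trials were omissions")
    q = np.quantile(rt[responded], QUANTILE_LEVELS)
    counts = np.bincount(winner_action[responded], minlength=N_ACTIONS)
    return ConditionSummary(
        rt_quantiles=q,
        selection_probs=counts / n_total,
        n_trials=int(n_total),
        omission_rate=1.0 - n_resp / n_total,
    )


def repetition_probability(
    base: LBAParams,
    mods,
    design: ModelDesign,
    n_sim: int = 100_000,
    seed: int | np.random.Generator = 0,
    previous_action_mix=None,
    deadline: float = DEFAULT_DEADLINE,
) -> float:
    """Probability of selecting the previous action in repetition-available
    choice trials, conditional on responding, from ``n_sim`` simulations.

    With three identical accumulators and a unit modulation ratio this is
    the 1/3 chance level; a repetition-suppressing ratio (< 1) pulls it
    below.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cond = Condition.CHOICE_REP_AVAILABLE
    prev, valid = sample_condition_configs(cond, n_sim, rng, previous_action_mix)
    mu, sd, b, c0, t0 = effective_arrays(base, mods, design, cond, prev, valid)
    z = rng.standard_normal(valid.shape)
    u = rng.random(valid.shape)
    winner_col, _ = race(mu, sd, b, c0, t0, z, u, deadline=deadline)
    responded = winner_col >= 0
    if not responded.any():
        raise RuntimeError("all simulated trials were omissions")
    rows = np.flatnonzero(responded)
    winner_action = valid[rows, winner_col[responded]]
    return float(np.mean(winner_action == prev[rows]))


def predict_summaries(
    base: LBAParams,
    mods,
    design: ModelDesign,
    condition: Condition,
    previous_action_mix=None,
    n_sim: int = 100_000,
    seed: int | np.random.Generator = 0,
    deadline: float = DEFAULT_DEADLINE,
) -> ConditionSummary:
    """Model-predicted RT quantiles and selection probabilities for one
    condition from ``n_sim`` numerical simulations.

    Previous actions are drawn from ``previous_action_mix`` and valid-action
    sets constructed per the task rules; reproducible given the seed.
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    condition = Condition(condition)
    prev, valid = sample_condition_configs(condition, n_sim, rng, previous_action_mix)
    mu, sd, b, c0, t0 = effective_arrays(base, mods, design, condition, prev, valid)
    k = valid.shape[1]
    z = rng.standard_normal((n_sim, k))
    u = rng.random((n_sim, k))
    winner_col, rt = race(mu, sd, b, c0, t0, z, u, deadline=deadline)
    rows = np.arange(n_sim)
    winner_action = np.where(winner_col >= 0, valid[rows, np.maximum(winner_col, 0)], -1)
    return summarize_simulation(winner_action, rt)
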