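"""Closed-form expected accumulated activity (EAA) per trial.

Given a trial's RT ``t`` and the fitted parameters, the winning
accumulator must have travelled from its expected start ``c0/2`` to the
threshold ``b`` in ``T = t - t0`` seconds, so its expected realised rate
is

    E[mu_W] = (b - c0/2) / (t - t0).

The losing accumulators have not reached threshold by then, so their
realised rates follow normal distributions upper-truncated at ``E[mu_W]``;
the truncated mean is ``mu_L - sigma_L * phi(z) / Phi(z)`` with
``z = (E[mu_W] - mu_L) / sigma_L``.

Each accumulator's EAA is the (signed) area under its expected linear
trajectory over ``[0, T]``: a trapezoid from ``c0/2`` to ``b`` for the
winner, ``(1/2)(b + c0/2) T``, and ``(c0/2) T + (1/2) E[mu_L] T^2`` for
each loser.  The trial's EAA is the sum over valid accumulators; in
specified trials only one accumulator is active so the total equals the
winner area.  Negative expected loser rates are retained (activity is not
floored at zero) and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .design_space import ModelDesign, effective_params
from .parameters import Condition, LBAParams
from .synthetic import parse_actions

__all__ = [
    "expected_winner_rate",
    "truncated_loser_rate",
    "EAARecord",
    "trial_eaa",
    "compute_eaa_table",
    "residualize_eaa",
    "write_events_tsv",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def expected_winner_rate(threshold, start_range, rt, non_decision):
    """Expected realised rate of the winning accumulator,
    ``(b - c0/2) / (t - t0)``.  Requires ``t > t0`` and ``b > c0/2``."""
    T = rt - non_decision
    if np.any(np.asarray(T) <= 0):
        raise ValueError("rt must exceed the non-decision time")
    num = threshold - start_range / 2.0
    if np.any(np.asarray(num) <= 0):
        raise ValueError("threshold must exceed half the start range")
    return num / T


def truncated_loser_rate(mean, sd, upper_bound):
    """Mean of a normal distribution upper-truncated at ``upper_bound``:
    ``mu - sd * phi(z)/Phi(z)`` with ``z = (upper_bound - mean)/sd``.

    Evaluated in the log domain (``exp(log phi - log Phi)``) so the
    inverse Mills ratio stays finite for bounds far below the mean.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    z = (np.asarray(upper_bound, dtype=float) - mean) / sd
    log_phi = -0.5 * z * z - _LOG_SQRT_2PI
    mills = np.exp(log_phi - log_ndtr(z))
    out = mean - sd * mills
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EAARecord:
    """Per-trial EAA decomposition.  Areas are in evidence x seconds;
    rates in evidence units / s.  ``loser_rates`` is empty for specified
    trials, where the total equals the winner area."""

    trial_index: int
    condition: str
    duration: float  # t - t0
    winner_action: int
    winner_rate: float
    loser_rates: tuple[float, ...]
    eaa_winner: float
    eaa_losers: tuple[float, ...]
    eaa_total: float
    negative_loser_rate: bool

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        total = self.eaa_winner + sum(self.eaa_losers)
        if abs(total - self.eaa_total) > 1e-9 * max(1.0, abs(total)):
            raise ValueError("eaa_total must equal winner + loser areas")


def trial_eaa(
    eff,
    winner_action: int,
    rt: float,
    condition: Condition,
    trial_index: int = -1,
) -> EAARecord:
    """EAA record for one trial from its effective per-accumulator
    parameters (:class:`~lbaction.design_space.EffectiveParams`), the
    selected action and the RT.  Raises for ``rt <= t0``; callers exclude
    and log such trials rather than zeroing them."""
    condition = Condition(condition)
    actions = np.asarray(eff.actions)
    w = np.flatnonzero(actions == int(winner_action))
    if w.size != 1:
        raise ValueError(f"winner {winner_action} not among valid actions {actions}")
    w = int(w[0])
    t0 = float(eff.non_decisions[w])
    T = rt - t0
    if T <= 0:
        raise ValueError(f"rt {rt:.4f} s does not exceed non-decision time {t0:.4f} s")
    b = float(eff.thresholds[w])
    c0_w = float(eff.start_ranges[w])
    mu_w = expected_winner_rate(b, c0_w, rt, t0)
    eaa_w = 0.5 * (b + c0_w / 2.0) * T

    loser_rates: list[float] = []
    eaa_losers: list[float] = []
    for j in range(len(actions)):
        if j == w:
            continue
        mu_l = truncated_loser_rate(eff.mean_rates[j], eff.rate_sds[j], mu_w)
        c0_l = float(eff.start_ranges[j])
        loser_rates.append(float(mu_l))
        eaa_losers.append((c0_l / 2.0) * T + 0.5 * float(mu_l) * T * T)
    return EAARecord(
        trial_index=int(trial_index),
        condition=condition.value,
        duration=float(T),
        winner_action=int(winner_action),
        winner_rate=float(mu_w),
        loser_rates=tuple(loser_rates),
        eaa_winner=float(eaa_w),
        eaa_losers=tuple(eaa_losers),
        eaa_total=float(eaa_w + sum(eaa_losers)),
        negative_loser_rate=bool(any(r < 0 for r in loser_rates)),
    )


def compute_eaa_table(
    trials: pd.DataFrame,
    params: LBAParams,
    mods,
    design: ModelDesign,
    include_first: bool = False,
) -> pd.DataFrame:
    """Per-trial EAA table over a trial table's responded action trials.

    Each trial uses its own condition-specific effective parameters
    (including any modulation of the repetition accumulator).  Trials with
    ``rt <= t0`` are excluded; their count is recorded in
    ``DataFrame.attrs['n_excluded_fast']``.
    """
    rows = []
    n_fast = 0
    for _, tr in trials.iterrows():
        if tr["trial_type"] not in ("choice", "specified") or pd.isna(tr["response"]):
            continue
        if not include_first and bool(tr.get("first_action_trial", False)):
            continue
        cond = Condition(tr["condition"])
        valid = parse_actions(tr["valid_actions"])
        eff = effective_params(
            params, mods, design, cond, int(tr["previous_action"]), valid
        )
        try:
            rec = trial_eaa(
                eff, int(tr["response"]), float(tr["rt_s"]), cond, int(tr["trial_index"])
            )
        except ValueError:
            n_fast += 1
            continue
        rows.append(
            {
                "trial_index": rec.trial_index,
                "onset_s": float(tr["onset_s"]),
                "condition": rec.condition,
                "rt_s": float(tr["rt_s"]),
                "duration": rec.duration,
                "winner_action": rec.winner_action,
                "winner_rate": rec.winner_rate,
                "eaa_winner": rec.eaa_winner,
                "eaa_losers": float(sum(rec.eaa_losers)),
                "eaa_total": rec.eaa_total,
                "negative_loser_rate": rec.negative_loser_rate,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_excluded_fast"] = n_fast
    return df


def residualize_eaa(eaa_vector, rt_vector) -> np.ndarray:
    """Residuals of a least-squares projection of EAA on [intercept, RT].

    Removes the component of the EAA collinear with single-trial RT; the
    residuals are mean-zero and orthogonal to RT.
    """
    e = np.asarray(eaa_vector, dtype=float)
    r = np.asarray(rt_vector, dtype=float)
    if e.shape != r.shape or e.ndim != 1 or e.size < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(r) == 0:
        raise ValueError("constant RT vector: projection undefined beyond intercept")
    X = np.column_stack([np.ones_like(r), r])
    coef, *_ = np.linalg.lstsq(X, e, rcond=None)
    return e - X @ coef


def write_events_tsv(
    eaa_table: pd.DataFrame,
    path,
    cue_duration: float = 1.0,
    mean_center: bool = False,
) -> pd.DataFrame:
    """Write a BIDS-style events table (onset, duration, trial_type, then
    parametric modulators ``eaa`` and ``eaa_residual``) for first-level
    GLM software.  Modulators are optionally mean-centred."""
    ev = pd.DataFrame(
        {
            "onset": eaa_table["onset_s"],
            "duration": cue_duration,
            "trial_type": eaa_table["condition"],
            "response_time": eaa_table["rt_s"],
            "eaa": eaa_table["eaa_total"],
            "eaa_residual": residualize_eaa(
                eaa_table["eaa_total"].to_numpy(), eaa_table["rt_s"].to_numpy()
            ),
        }
    )
    if mean_center:
        ev["eaa"] = ev["eaa"] - ev["eaa"].mean()
        # residuals are mean-zero already
    ev.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return ev
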