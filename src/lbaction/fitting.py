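"""Quantile-based chi-square fitting of accumulator designs.

The observed behaviour of each condition is reduced to RT quantiles at
levels 0.1/0.3/0.5/0.7/0.9 plus, for choice conditions, per-action
selection counts.  A candidate parameter set is scored by the
likelihood-ratio chi-square

    G^2 = 2 * sum_i O_i * ln(O_i / E_i),

summed over the six RT bins delimited by the observed quantiles (expected
proportions read off the model's simulated RT distribution) and over the
selection categories.  Selection counts are per finger; in the
repetition-available condition responses are categorised as repetition
vs. non-repetition-by-finger, so the statistic retains the
repetition-suppression signal that the plain finger marginal averages
out.  G^2 is minimised by multi-restart Nelder-Mead
simplex: each restart draws random candidate parameter sets from
documented ranges, starts the simplex from the best candidate, and the
best restart wins.  Within a restart the same simulation noise is reused
for every objective evaluation (common random numbers), so the stochastic
objective is a fixed deterministic surface for the simplex.

The public surface follows the Model/Results convention: build an
:class:`LBAModel` from a trial table, call :meth:`~LBAModel.fit`, and read
estimates, fit statistics and diagnostics off the returned
:class:`LBAResults`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .design_space import ModelDesign, parameter_count, _as_modulation_map


def _as_mod_list(mods):
    return list(_as_modulation_map(mods).values())
from .parameters import (
    Condition,
    LBAParams,
    ModulatedParameter,
    ModulationSet,
    N_ACTIONS,
)
from .simulate import (
    DEFAULT_DEADLINE,
    QUANTILE_LEVELS,
    ConditionSummary,
    predict_summaries,
)
from .synthetic import parse_actions

ALL_CONDITIONS = (
    Condition.CHOICE_REP_AVAILABLE,
    Condition.CHOICE_REP_ABSENT,
    Condition.SPECIFIED_REP,
    Condition.SPECIFIED_NONREP,
)

__all__ = [
    "FitConfig",
    "summarize_condition",
    "g_squared",
    "bic",
    "FitResult",
    "fit_design",
    "LBAModel",
    "LBAResults",
]


@dataclass(frozen=True)
class FitConfig:
    """Tunable fitting configuration.

    Defaults follow the estimation procedure: 100,000-simulation
    predictions, 20 restarts each started from the best of 100 random
    candidate parameter sets, and a 10,000-iteration simplex cap.  The
    random-start ranges are package choices (none are stated for the
    original procedure).
    """

    n_sim: int = 100_000
    n_restarts: int = 20
    n_candidates: int = 100
    max_iter: int = 10_000
    n_polish: int = 1
    ftol: float = 1e-4
    xtol: float = 1e-4
    deadline: float = DEFAULT_DEADLINE
    min_trials_per_condition: int = 10
    mu_range: tuple[float, float] = (0.5, 5.0)
    sigma_range: tuple[float, float] = (0.2, 2.0)
    b_range: tuple[float, float] = (0.5, 3.0)
    c0_frac_range: tuple[float, float] = (0.05, 0.95)
    t0_min: float = 0.05
    ratio_range: tuple[float, float] = (0.3, 3.0)
    penalty: float = 1e10
    #: optional identifiability aid: fix sigma_1 = 1 as the scale unit
    #: (the race model is invariant to a joint rescaling of mu, sigma, b,
    #: c0, so one SD can serve as the unit without loss of fit)
    pin_first_rate_sd: bool = False

    @property
    def epsilon(self) -> float:
        """Floor for simulated expected proportions (half a simulated
        trial's worth of mass)."""
        return 1.0 / (2.0 * self.n_sim)


# ---------------------------------------------------------------------------
# observed-data summaries


def summarize_condition(
    trials: pd.DataFrame, min_trials: int = 10, condition: str | None = None
) -> ConditionSummary:
    """Empirical :class:`ConditionSummary` for one condition's trials.

    Quantiles use linear interpolation of the empirical CDF; selection
    probabilities are response counts over all of the condition's trials
    (defective, so they sum with the omission rate to 1).
    """
    name = condition or (
        str(trials["condition"].iloc[0]) if len(trials) else "<empty>"
    )
    responded = trials[trials["response"].notna()]
    if len(responded) < min_trials:
        raise ValueError(
            f"condition {name!r} has {len(responded)} responded trials "
            f"(minimum {min_trials})"
        )
    q = np.quantile(responded["rt_s"].to_numpy(dtype=float), QUANTILE_LEVELS)
    counts = np.bincount(responded["response"].to_numpy(dtype=int), minlength=N_ACTIONS)
    n_total = len(trials)
    return ConditionSummary(
        rt_quantiles=q,
        selection_probs=counts / n_total,
        n_trials=n_total,
        omission_rate=1.0 - len(responded) / n_total,
    )


def g_squared(observed_counts, expected_props, epsilon: float = 1e-6) -> float:
    """Likelihood-ratio chi-square over one or more multinomial blocks.

    ``observed_counts`` and ``expected_props`` are matching arrays, or
    matching lists of arrays (one per block).  Within each block the
    expected proportions are floored at ``epsilon`` and renormalised;
    expected counts are ``n_block * p``.  Zero-observed cells contribute
    zero.  Degenerate expected distributions yield a large but finite
    value so an optimiser can traverse them.
    """
    if isinstance(observed_counts, np.ndarray) or not isinstance(
        observed_counts[0], (list, tuple, np.ndarray)
    ):
        observed_counts = [observed_counts]
        expected_props = [expected_props]
    total = 0.0
    for obs, props in zip(observed_counts, expected_props, strict=True):
        obs = np.asarray(obs, dtype=float)
        props = np.asarray(props, dtype=float)
        if obs.shape != props.shape:
            raise ValueError("observed and expected blocks must align")
        n = obs.sum()
        if n == 0:
            continue
        props = np.maximum(props, epsilon)
        props = props / props.sum()
        expected = n * props
        mask = obs > 0
        total += 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))
    return total


def bic(g2: float, k: int, n: int) -> float:
    """Bayesian Information Criterion in the multinomial-deviance form:
    ``BIC = G^2 + k * ln(n)`` with ``n`` the participant's fitted trial
    count."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(g2) + k * float(np.log(n))


# ---------------------------------------------------------------------------
# observed-data structures used by the objective


@dataclass
class _ObservedCondition:
    condition: Condition
    n_resp: int
    edges: np.ndarray  # the five observed RT quantiles
    bin_counts: np.ndarray  # six RT-bin counts
    sel_counts: np.ndarray | None  # per-action counts (choice only)
    prev: np.ndarray  # previous action per responded trial
    valid: np.ndarray  # (n_resp, k) valid-action sets


def _action_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for fitting: action trials that are not the flagged
    first action trial and not commission errors."""
    t = trials[trials["trial_type"].isin(["choice", "specified"])].copy()
    if "first_action_trial" in t.columns:
        t = t[~t["first_action_trial"].astype(bool)]
    # commission errors: response outside the valid set
    def _valid_response(row):
        if pd.isna(row["response"]):
            return True
        return int(row["response"]) in parse_actions(row["valid_actions"])

    ok = t.apply(_valid_response, axis=1)
    n_commission = int((~ok).sum())
    if n_commission:
        warnings.warn(f"excluding {n_commission} commission-error trials", stacklevel=2)
    return t[ok]


def _prepare_observed(trials: pd.DataFrame, config: FitConfig):
    t = _action_trials(trials)
    observed: dict[Condition, _ObservedCondition] = {}
    n_total = 0
    for cond in ALL_CONDITIONS:
        sub = t[t["condition"] == cond.value]
        if len(sub) == 0:
            raise ValueError(f"condition {cond.value!r} absent from the trial table")
        responded = sub[sub["response"].notna()]
        if len(responded) < config.min_trials_per_condition:
            raise ValueError(
                f"condition {cond.value!r} has only {len(responded)} responded trials"
            )
        rts = responded["rt_s"].to_numpy(dtype=float)
        edges = np.quantile(rts, QUANTILE_LEVELS)
        idx = np.searchsorted(edges, rts, side="left")
        bin_counts = np.bincount(idx, minlength=6).astype(float)
        if cond.trial_type.value == "choice":
            resp_arr = responded["response"].to_numpy(dtype=int)
            finger = np.bincount(resp_arr, minlength=N_ACTIONS).astype(float)
            if cond is Condition.CHOICE_REP_AVAILABLE:
                # repetition-relative categories: repeats in category 0,
                # non-repeat responses by finger — this carries the
                # repetition-suppression signal the finger marginal hides
                prev_arr = responded["previous_action"].to_numpy(dtype=int)
                is_rep = resp_arr == prev_arr
                nonrep = np.bincount(resp_arr[~is_rep], minlength=N_ACTIONS)
                sel = np.concatenate([[is_rep.sum()], nonrep]).astype(float)
            else:
                sel = finger
        else:
            sel = None
        valid = np.array(
            [parse_actions(v) for v in responded["valid_actions"]], dtype=int
        )
        observed[cond] = _ObservedCondition(
            condition=cond,
            n_resp=len(responded),
            edges=edges,
            bin_counts=bin_counts,
            sel_counts=sel,
            prev=responded["previous_action"].to_numpy(dtype=int),
            valid=valid,
        )
        n_total += len(responded)
    return observed, n_total


# ---------------------------------------------------------------------------
# parameter vector packing and transforms


class _ParameterVector:
    """Maps between a design's free parameters, an unconstrained search
    vector, and (LBAParams, modulation sets).

    Transforms: log for rates, SDs, threshold and ratios; logit of the
    fraction ``c0 / b`` (keeping the start range strictly below
    threshold); scaled logit for ``t0`` on ``(0, t0_max)`` with ``t0_max``
    just below the fastest observed RT.
    """

    def __init__(self, design: ModelDesign, config: FitConfig, t0_max: float):
        self.design = design
        self.config = config
        self.t0_max = t0_max
        names = [f"mu{i + 1}" for i in range(N_ACTIONS)]
        sd_start = 2 if config.pin_first_rate_sd else 1
        names += [f"sigma{i}" for i in range(sd_start, N_ACTIONS + 1)]
        names += ["b"]
        if design.f1_start_varies_by_accumulator:
            names += [f"c0_frac{i + 1}" for i in range(N_ACTIONS)]
        else:
            names += ["c0_frac"]
        names += ["t0"]
        if design.f5_rates_equal_in_specified:
            names += ["mu_spec"]
        tags = {
            ModulatedParameter.THRESHOLD: "b",
            ModulatedParameter.MEAN_RATE: "rate",
            ModulatedParameter.NON_DECISION: "t0",
        }
        for p in design.modulated_parameters:
            tag = tags[p]
            names += [
                f"{tag}_ratio_choice_rep",
                f"{tag}_ratio_spec_rep",
                f"{tag}_ratio_spec_nonrep",
            ]
        self.names = names

    def __len__(self):
        return len(self.names)

    def sample_natural(self, rng: np.random.Generator) -> dict[str, float]:
        c = self.config
        out = {}
        for name in self.names:
            if name.startswith("mu"):
                out[name] = rng.uniform(*c.mu_range)
            elif name.startswith("sigma"):
                out[name] = rng.uniform(*c.sigma_range)
            elif name == "b":
                out[name] = rng.uniform(*c.b_range)
            elif name.startswith("c0_frac"):
                out[name] = rng.uniform(*c.c0_frac_range)
            elif name == "t0":
                out[name] = rng.uniform(
                    min(c.t0_min, 0.5 * self.t0_max), 0.98 * self.t0_max
                )
            else:  # ratios
                out[name] = rng.uniform(*c.ratio_range)
        return out

    def to_vector(self, natural: Mapping[str, float]) -> np.ndarray:
        x = np.empty(len(self.names))
        for i, name in enumerate(self.names):
            v = natural[name]
            if name.startswith("c0_frac"):
                x[i] = logit(np.clip(v, 1e-6, 1 - 1e-6))
            elif name == "t0":
                x[i] = logit(np.clip(v / self.t0_max, 1e-6, 1 - 1e-6))
            else:
                x[i] = np.log(v)
        return x

    def to_natural(self, x: np.ndarray) -> dict[str, float]:
        out = {}
        for i, name in enumerate(self.names):
            if name.startswith("c0_frac"):
                out[name] = float(expit(x[i]))
            elif name == "t0":
                out[name] = float(self.t0_max * expit(x[i]))
            else:
                out[name] = float(np.exp(x[i]))
        return out

    def to_params(self, natural: Mapping[str, float]):
        d = natural
        b = d["b"]
        if self.design.f1_start_varies_by_accumulator:
            c0 = tuple(b * d[f"c0_frac{i + 1}"] for i in range(N_ACTIONS))
        else:
            c0 = b * d["c0_frac"]
        base = LBAParams(
            mean_rates=tuple(d[f"mu{i + 1}"] for i in range(N_ACTIONS)),
            rate_sds=tuple(d.get(f"sigma{i + 1}", 1.0) for i in range(N_ACTIONS)),
            threshold=b,
            start_range=c0,
            non_decision=d["t0"],
            specified_mean=d.get("mu_spec"),
        )
        mods = []
        tags = {
            "b": ModulatedParameter.THRESHOLD,
            "rate": ModulatedParameter.MEAN_RATE,
            "t0": ModulatedParameter.NON_DECISION,
        }
        for tag, p in tags.items():
            key = f"{tag}_ratio_choice_rep"
            if key in d:
                mods.append(
                    ModulationSet(
                        modulated_parameter=p,
                        ratio_choice_repetition_available=d[key],
                        ratio_specified_repetition=d[f"{tag}_ratio_spec_rep"],
                        ratio_specified_nonrepetition=d[f"{tag}_ratio_spec_nonrep"],
                        scope=self.design.scope,
                    )
                )
        return base, mods


# ---------------------------------------------------------------------------
# the simulation-based objective


class _Objective:
    """G^2 objective over a fixed set of pre-drawn simulation noise.

    For each condition the simulated trial configurations are resampled
    (with replacement) from the observed responded trials, so predictions
    marginalise over previous actions and valid sets exactly as the data
    do.  Races and histograms run in a fused numba kernel; valid-action
    columns are permuted so the modulated (previous-action) accumulator is
    always column 0.
    """

    def __init__(self, observed, design, config: FitConfig, pvec, rng):
        from ._kernels import condition_counts

        self._kernel = condition_counts
        self.observed = observed
        self.design = design
        self.config = config
        self.pvec = pvec
        n = config.n_sim
        self.draws = {}
        for cond, oc in observed.items():
            k = oc.valid.shape[1]
            pick = rng.integers(0, oc.n_resp, size=n)
            valid = oc.valid[pick]
            prev = oc.prev[pick]
            # stable-sort columns so the previous-action accumulator leads
            order = np.argsort(valid != prev[:, None], axis=1, kind="stable")
            if cond is Condition.CHOICE_REP_AVAILABLE:
                valid = np.take_along_axis(valid, order, axis=1)
            self.draws[cond] = {
                "valid": np.ascontiguousarray(valid, dtype=np.int64),
                "z": rng.standard_normal((n, k)),
                "u": rng.random((n, k)),
                "bins": np.zeros(6),
                "sel": np.zeros(N_ACTIONS + 1),
            }
        self.n_eval = 0

    def g2_for(self, base: LBAParams, mods) -> float:
        cfg = self.config
        design = self.design
        mod_by_param = {m.modulated_parameter: m for m in _as_mod_list(mods)}
        mu4 = np.asarray(base.mean_rates, dtype=float)
        sd4 = np.asarray(base.rate_sds, dtype=float)
        c04 = np.ascontiguousarray(base.start_ranges, dtype=float)
        scope_all = design.f6_changes_apply_to_all
        obs_blocks, exp_blocks = [], []
        for cond, oc in self.observed.items():
            d = self.draws[cond]
            is_spec = cond.trial_type.value == "specified"
            if design.f5_rates_equal_in_specified and is_spec:
                mu_c = np.full(N_ACTIONS, float(base.specified_mean))
            else:
                mu_c = mu4
            ratios = {}
            for p, tag in (
                (ModulatedParameter.MEAN_RATE, "rate"),
                (ModulatedParameter.THRESHOLD, "b"),
                (ModulatedParameter.NON_DECISION, "t0"),
            ):
                m = mod_by_param.get(p)
                ratios[tag] = m.ratio_for(cond) if m is not None else 1.0
            bins, sel = d["bins"], d["sel"]
            bins[:] = 0.0
            sel[:] = 0.0
            rep_cat = cond is Condition.CHOICE_REP_AVAILABLE
            n_resp = self._kernel(
                d["valid"],
                d["z"],
                d["u"],
                mu_c,
                sd4,
                c04,
                float(base.threshold),
                float(base.non_decision),
                ratios["rate"],
                ratios["b"],
                ratios["t0"],
                scope_all or is_spec,
                rep_cat,
                cfg.deadline,
                oc.edges,
                bins,
                sel,
            )
            if n_resp == 0:
                return cfg.penalty
            obs_blocks.append(oc.bin_counts)
            exp_blocks.append(bins / n_resp)
            if oc.sel_counts is not None:
                pred_sel = sel if rep_cat else sel[1:]
                obs_blocks.append(oc.sel_counts)
                exp_blocks.append(pred_sel / n_resp)
        return g_squared(obs_blocks, exp_blocks, epsilon=cfg.epsilon)

    def __call__(self, x: np.ndarray) -> float:
        self.n_eval += 1
        natural = self.pvec.to_natural(x)
        try:
            base, mods = self.pvec.to_params(natural)
        except ValueError:
            return self.config.penalty
        val = self.g2_for(base, mods)
        if not np.isfinite(val):
            return self.config.penalty
        return val


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Outcome of fitting one design to one participant's trials."""

    design: ModelDesign
    design_index: int | None
    params: LBAParams
    modulations: list[ModulationSet]
    g_squared: float
    k: int
    n: int
    bic: float
    restarts: int
    converged: bool
    seed: int
    restart_g2: list[float] = field(default_factory=list)
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "design_index": self.design_index,
            "params": self.params.to_dict(),
            "modulations": [m.to_dict() for m in self.modulations],
            "g_squared": self.g_squared,
            "k": self.k,
            "n": self.n,
            "bic": self.bic,
            "restarts": self.restarts,
            "converged": self.converged,
            "seed": self.seed,
            "restart_g2": self.restart_g2,
            "n_evaluations": self.n_evaluations,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def fit_design(
    trials: pd.DataFrame,
    design: ModelDesign,
    config: FitConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one design to one participant's trial table.

    Each restart draws ``n_candidates`` random parameter sets, evaluates
    G^2 on all of them, runs Nelder-Mead from the best, and the restart
    with the lowest final G^2 wins.  Fully reproducible from ``seed``.
    """
    config = config or FitConfig()
    observed, n_total = _prepare_observed(trials, config)
    # t0 must sit below the fastest observed RT for the model to produce it
    t = _action_trials(trials)
    t0_max = float(t["rt_s"].min()) * 0.999
    pvec = _ParameterVector(design, config, t0_max)

    ss = np.random.SeedSequence(seed)
    restart_seeds = ss.spawn(config.n_restarts)
    best = None
    best_x = None
    restart_g2 = []
    n_eval = 0
    converged = False
    for rs in restart_seeds:
        rng = np.random.default_rng(rs)
        obj = _Objective(observed, design, config, pvec, rng)
        cand = [pvec.sample_natural(rng) for _ in range(config.n_candidates)]
        cand_vals = [obj(pvec.to_vector(c)) for c in cand]
        x0 = pvec.to_vector(cand[int(np.argmin(cand_vals))])
        options = {
            "maxiter": config.max_iter,
            "xatol": config.xtol,
            "fatol": config.ftol,
            "disp": False,
        }
        res = optimize.minimize(obj, x0, method="Nelder-Mead", options=options)
        # fresh-simplex reruns from the endpoint: Nelder-Mead's simplex
        # collapses along ridges; re-expanding it recovers progress cheaply
        for _ in range(config.n_polish):
            res = optimize.minimize(obj, res.x, method="Nelder-Mead", options=options)
        restart_g2.append(float(res.fun))
        n_eval += obj.n_eval
        if best is None or res.fun < best:
            best = float(res.fun)
            best_x = res.x.copy()
            converged = bool(res.success)
    if best is None or not np.isfinite(best) or best >= config.penalty:
        raise RuntimeError("no restart produced a finite G^2")
    base, mods = pvec.to_params(pvec.to_natural(best_x))
    k = parameter_count(design)
    from .design_space import enumerate_designs

    designs = enumerate_designs()
    design_index = designs.index(design) + 1 if design in designs else None
    return FitResult(
        design=design,
        design_index=design_index,
        params=base,
        modulations=mods,
        g_squared=best,
        k=k,
        n=n_total,
        bic=bic(best, k, n_total),
        restarts=config.n_restarts,
        converged=converged,
        seed=seed,
        restart_g2=restart_g2,
        n_evaluations=n_eval,
    )


# ---------------------------------------------------------------------------
# Model / Results surface


class LBAModel:
    """Accumulator model of one participant's action decisions.

    Parameters
    ----------
    trials : trial table with columns ``trial_index, onset_s, trial_type,
        condition, valid_actions, previous_action, response, rt_s`` (and
        optionally ``first_action_trial``); omissions carry a missing
        response/RT, null events a missing condition.
    design : the structural design to fit.
    config : fitting configuration; defaults to :class:`FitConfig`.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        design: ModelDesign,
        config: FitConfig | None = None,
    ):
        required = {
            "trial_type",
            "condition",
            "valid_actions",
            "previous_action",
            "response",
            "rt_s",
        }
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table is missing columns: {sorted(missing)}")
        if not design.is_canonical():
            raise ValueError("design is not in canonical form")
        self.trials = trials
        self.design = design
        self.config = config or FitConfig()

    @classmethod
    def from_tsv(cls, path, design: ModelDesign, config: FitConfig | None = None):
        from .io import read_trial_table

        return cls(read_trial_table(path), design, config)

    def observed_summaries(self) -> dict[Condition, ConditionSummary]:
        t = _action_trials(self.trials)
        return {
            cond: summarize_condition(
                t[t["condition"] == cond.value],
                min_trials=self.config.min_trials_per_condition,
                condition=cond.value,
            )
            for cond in ALL_CONDITIONS
        }

    def fit(self, seed: int = 0) -> "LBAResults":
        result = fit_design(self.trials, self.design, self.config, seed=seed)
        return LBAResults(self, result)


class LBAResults:
    """Fitted-model results: parameter estimates, fit statistics,
    predictions, summaries and derived per-trial activity."""

    def __init__(self, model: LBAModel, result: FitResult):
        self.model = model
        self.result = result

    # -- pass-through estimates and statistics
    @property
    def params(self) -> LBAParams:
        return self.result.params

    @property
    def modulations(self) -> list[ModulationSet]:
        return self.result.modulations

    @property
    def g_squared(self) -> float:
        return self.result.g_squared

    @property
    def bic(self) -> float:
        return self.result.bic

    @property
    def k(self) -> int:
        return self.result.k

    @property
    def nobs(self) -> int:
        return self.result.n

    def predict(
        self,
        condition: Condition | None = None,
        n_sim: int | None = None,
        seed: int = 0,
    ):
        """Model-predicted condition summaries at the fitted parameters,
        marginalising previous actions over their empirical frequencies."""
        conds = ALL_CONDITIONS if condition is None else (Condition(condition),)
        t = _action_trials(self.model.trials)
        out = {}
        for c in conds:
            sub = t[(t["condition"] == c.value) & t["response"].notna()]
            mix = np.bincount(
                sub["previous_action"].to_numpy(dtype=int), minlength=N_ACTIONS
            ).astype(float)
            out[c] = predict_summaries(
                self.params,
                self.modulations,
                self.model.design,
                c,
                previous_action_mix=mix,
                n_sim=n_sim or self.model.config.n_sim,
                seed=seed,
                deadline=self.model.config.deadline,
            )
        return out[conds[0]] if condition is not None else out

    def fit_table(self, n_sim: int | None = None, seed: int = 0) -> pd.DataFrame:
        """Observed vs. predicted quantiles and selection probabilities,
        one row per condition x quantile level."""
        obs = self.model.observed_summaries()
        pred = self.predict(n_sim=n_sim, seed=seed)
        rows = []
        for cond in ALL_CONDITIONS:
            o, p = obs[cond], pred[cond]
            for lvl, oq, pq in zip(QUANTILE_LEVELS, o.rt_quantiles, p.rt_quantiles):
                rows.append(
                    {
                        "condition": cond.value,
                        "quantile": lvl,
                        "observed_rt_s": oq,
                        "predicted_rt_s": pq,
                        "observed_omission_rate": o.omission_rate,
                        "predicted_omission_rate": p.omission_rate,
                    }
                )
        return pd.DataFrame(rows)

    def eaa_table(self, **kwargs) -> pd.DataFrame:
        """Per-trial expected accumulated activity at the fitted
        parameters; see :func:`lbaction.eaa.compute_eaa_table`."""
        from .eaa import compute_eaa_table

        return compute_eaa_table(
            self.model.trials,
            self.params,
            self.modulations,
            self.model.design,
            **kwargs,
        )

    def summary(self) -> str:
        r = self.result
        lines = [
            "Accumulator model fit (quantile chi-square)",
            "=" * 47,
            f"Design:        {r.design.label()} (index {r.design_index})",
            f"Free params:   {r.k}   Trials fitted: {r.n}",
            f"G^2:           {r.g_squared:.4f}",
            f"BIC:           {r.bic:.4f}",
            f"Restarts:      {r.restarts} (converged: {r.converged}, seed {r.seed})",
            "-" * 47,
            "Parameter estimates",
        ]
        p = r.params
        for i in range(N_ACTIONS):
            lines.append(
                f"  mu{i + 1} = {p.mean_rates[i]:.4f}   sigma{i + 1} = {p.rate_sds[i]:.4f}"
            )
        c0 = p.start_range
        c0s = (
            f"{c0:.4f}" if np.isscalar(c0) else "[" + ", ".join(f"{v:.4f}" for v in c0) + "]"
        )
        lines.append(f"  b = {p.threshold:.4f}   c0 = {c0s}   t0 = {p.non_decision:.4f}")
        if p.specified_mean is not None:
            lines.append(f"  mu_specified = {p.specified_mean:.4f}")
        for m in r.modulations:
            lines.append(
                f"  {m.modulated_parameter.value} ratios "
                f"[choice-rep {m.ratio_choice_repetition_available:.4f}, "
                f"spec-rep {m.ratio_specified_repetition:.4f}, "
                f"spec-nonrep {m.ratio_specified_nonrepetition:.4f}] "
                f"({m.scope.value})"
            )
        return "\n".join(lines)

    def plot_fit(self, ax=None, n_sim: int | None = None, seed: int = 0):
        """Observed vs. predicted RT quantiles per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        table = self.fit_table(n_sim=n_sim, seed=seed)
        for cond, grp in table.groupby("condition"):
            (line,) = ax.plot(
                grp["quantile"], grp["observed_rt_s"], "o-", label=f"{cond} (obs)"
            )
            ax.plot(
                grp["quantile"],
                grp["predicted_rt_s"],
                "s--",
                color=line.get_color(),
                alpha=0.6,
            )
        ax.set_xlabel("quantile level")
        ax.set_ylabel("RT (s)")
        ax.legend(fontsize=7)
        return ax
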