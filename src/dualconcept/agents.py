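"""Generative model of synthetic participants.

No mechanistic agent is implied by the experimental framework itself;
this module operationalizes the reported behavioral biases as an
explicit decision hierarchy so every analysis can be exercised
end-to-end with known ground truth:

1. *stickiness* — with probability ``p_stick``, if the previously
   attended feature set hosts a consistent candidate rule, adopt it
   (and learn faster by the multiplicative factor ``stick_speed``);
2. otherwise sample among the trial's candidate rules with softmax
   weights exp(−``lambda_mdl`` · MDL), the simplicity bias;
3. when exactly two candidates tie in MDL and oppose a conjunction to
   a disjunction, resolve toward the conjunction with probability
   ``p_conj``.

The selection at generalization is the chosen rule's predicted
selection, except that with probability ``p_lapse`` the agent picks a
uniformly random subset.  Learning times are log-normal.  Defaults
reproduce the study's headline conditions (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import analyze, default_candidates, predicted_selection
from .logic import And, Or, formula_vars
from .mdl import mdl_of
from .stimuli import ParticipantRecord, TrialResponse
from .trials import ExperimentPlan, TrialSpec, standard_experiment


@dataclass(frozen=True)
class AgentParams:
    """Tunable behavioral parameters of a simulated participant."""

    p_conj: float = 0.875  # conjunction tie-break probability
    lambda_mdl: float = 1.0  # softmax inverse temperature on rule MDL
    p_stick: float = 0.36  # probability of reusing the previous features
    p_lapse: float = 0.12  # probability of a random generalization subset
    time_mu: float = 4.0  # log-seconds, learning-time location
    time_sigma: float = 0.5  # log-seconds, learning-time scale
    stick_speed: float = 0.8  # multiplicative time factor when sticking
    seed: int = 0

    def __post_init__(self):
        for name in ("p_conj", "p_stick", "p_lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.lambda_mdl < 0 or self.time_sigma < 0:
            raise ValueError("lambda_mdl and time_sigma must be nonnegative")
        if not 0.0 < self.stick_speed <= 1.0:
            raise ValueError("stick_speed must lie in (0, 1]")


@dataclass(frozen=True)
class SimulatedCohort:
    records: tuple
    params: AgentParams
    plan: ExperimentPlan


def _trial_candidates(t: TrialSpec):
    """Candidate rules with cached MDLs and predicted selections."""
    out = []
    for sub, rule in default_candidates(t):
        out.append(
            (frozenset(sub), rule, mdl_of(rule).length, predicted_selection(rule, t))
        )
    return out


def _choose_rule(candidates, prev_attended, params: AgentParams, rng):
    """The documented decision hierarchy; returns (entry, stuck)."""
    if prev_attended is not None and rng.random() < params.p_stick:
        hosted = [c for c in candidates if formula_vars(c[1]) <= prev_attended]
        if hosted:
            return min(hosted, key=lambda c: c[2]), True
    mdls = np.array([c[2] for c in candidates], dtype=float)
    if len(candidates) == 2 and mdls[0] == mdls[1]:
        ops = {type(candidates[0][1]), type(candidates[1][1])}
        if ops == {And, Or}:
            conj = next(c for c in candidates if isinstance(c[1], And))
            disj = next(c for c in candidates if isinstance(c[1], Or))
            return (conj if rng.random() < params.p_conj else disj), False
    weights = np.exp(-params.lambda_mdl * (mdls - mdls.min()))
    weights /= weights.sum()
    return candidates[rng.choice(len(candidates), p=weights)], False


def simulate_participant(
    plan: ExperimentPlan,
    params: AgentParams,
    seed,
    participant_id: str = "sim",
    _candidate_cache: dict = None,
) -> ParticipantRecord:
    """One synthetic participant playing all six trials of a plan."""
    rng = np.random.default_rng(seed)
    cache = _candidate_cache if _candidate_cache is not None else {}
    responses = {}
    prev_attended = None
    for t in plan.trials:
        key = (plan.group, t.index)
        if key not in cache:
            cache[key] = _trial_candidates(t)
        (attended, rule, _, predicted), stuck = _choose_rule(
            cache[key], prev_attended, params, rng
        )
        lapsed = rng.random() < params.p_lapse
        if lapsed:
            shown = sorted(t.gen_shown_ids)
            selection = frozenset(e for e in shown if rng.random() < 0.5)
            explanation = "no consistent rule"
        else:
            selection = predicted
            from .logic import format_formula

            explanation = f"rule: {format_formula(rule)}"
        time_s = float(rng.lognormal(params.time_mu, params.time_sigma))
        if stuck:
            time_s *= params.stick_speed
        if params.p_lapse == 0:
            attempts = 1
        else:
            # geometric number of training rounds; capped for degenerate p_lapse=1
            attempts = int(min(rng.geometric(max(1 - params.p_lapse, 1e-6)), 99))
        responses[t.index] = TrialResponse(
            selection=selection,
            learning_time_s=time_s,
            training_attempts=attempts,
            explanation_text=explanation,
            negative_flag=False,
        )
        prev_attended = frozenset(attended)
    return ParticipantRecord(id=participant_id, group=plan.group, responses=responses)


def simulate_cohort(
    n: int, plan: ExperimentPlan, params: AgentParams, seed
) -> SimulatedCohort:
    """``n`` independent participants with per-participant derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    cache: dict = {}
    records = tuple(
        simulate_participant(
            plan,
            params,
            child,
            participant_id=f"{plan.group}{i + 1:04d}",
            _candidate_cache=cache,
        )
        for i, child in enumerate(children)
    )
    return SimulatedCohort(records=records, params=params, plan=plan)


def simulate_study(
    n_per_group: int, params: AgentParams, seed
) -> tuple:
    """Both groups of the standard experiment; returns (records, plans)."""
    plans = {g: standard_experiment(g, seed=0) for g in ("X", "Y")}
    root = np.random.SeedSequence(seed).spawn(2)
    records = []
    for child, g in zip(root, ("X", "Y")):
        records.extend(simulate_cohort(n_per_group, plans[g], params, child).records)
    return records, plans


def recover_params(cohort: SimulatedCohort, n_sims: int = 10_000, seed=0) -> dict:
    """Run the full analysis suite on a simulated cohort.

    Returns analysis-based estimates next to the generating parameters,
    for parameter-recovery checks.  The time-ratio test needs both
    groups, so it is reported only when the cohort contains them.
    """
    report = analyze(cohort.plan, list(cohort.records), n_sims=n_sims, seed=seed)
    h1 = report["h1"]["counts"]
    n = sum(h1.values())
    bias = report["mdl_bias"]["counts"]
    n_bias = sum(bias.values())
    return {
        "generating": cohort.params,
        "conjunction_fraction": h1["conjunction"] / n,
        "neither_fraction": h1["neither"] / n,
        "mean_stickiness": report["h2"]["mean"],
        "stickiness_p": report["h2"]["p"],
        "mdl_short_fraction": bias["short_rule_consistent"] / n_bias,
        "report": report,
    }
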