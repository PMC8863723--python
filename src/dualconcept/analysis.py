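"""Inference of attended features from generalization selections, and the
statistical analyses of the standard experiment.

The key move: a learner who internalized rule r should select exactly
the shown generalization elements satisfying r.  Matching an observed
selection against the predicted selections of a candidate family
therefore recovers the rule — and hence the attended feature set —
without any attention-tracking apparatus.  Trial 6 carries seven
designed elements whose candidate family spans the seven feature
subsets between {p3,p4} and {p7,p8}; the *stickiness score* of an
attended set A is |A ∩ previous| / |A|, the fraction of currently used
features carried over from the previous trial.

Statistical machinery: exact binomial and Monte-Carlo nulls for the
conjunction-bias count, a simulated random-attention null for the mean
stickiness score, a two-sample t-test with Cohen's d (pooled SD) for
the learning-time ratio between groups, operator/feature transition
classification, and the short-vs-long rule consistency tally.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .logic import And, Formula, Or, eval_formula, formula_vars, parse_formula
from .trials import ExperimentPlan, TrialSpec

#: stickiness scores of the seven trial-6 attended sets, previous = {p7,p8}
TRIAL6_PREVIOUS = frozenset({7, 8})


@dataclass(frozen=True)
class AttendedInference:
    verdict: str  # "matched" | "one_away" | "no_rationale"
    attended: frozenset = None
    rule: Formula = None


@dataclass(frozen=True)
class StickinessResult:
    scores: dict  # participant id -> float
    n_valid: int
    mean: float
    p_value: float
    group_means: dict
    group_t: float
    group_d: float
    excluded: tuple


@dataclass(frozen=True)
class StickinessNull:
    means: np.ndarray
    p_value: float
    observed_mean: float


@dataclass(frozen=True)
class TimeRatioResult:
    ratios: dict  # participant id -> t4/t5
    excluded: tuple
    t: float
    df: int
    p_value: float
    d: float
    group_means: dict


def predicted_selection(rule: Formula, t: TrialSpec) -> frozenset:
    """Ids of the shown generalization elements satisfying ``rule``."""
    if not formula_vars(rule) <= frozenset(t.ctx):
        missing = sorted(formula_vars(rule) - frozenset(t.ctx))
        raise ValueError(f"rule mentions features outside the context: {missing}")
    return frozenset(
        t.element_id(v) for v in t.gen_shown if eval_formula(rule, v, t.ctx)
    )


def trial6_candidates():
    """The seven (attended subset, minimal rule) candidates of trial 6.

    Each subset spanning {p3,p4} to {p3,p4,p7,p8} pairs with the minimal
    rule over exactly those features that is consistent with the trial-6
    examples; their predicted selections over the seven designed
    elements are pairwise distinct.
    """
    table = (
        ({3, 4}, "p3 & p4"),
        ({3, 4, 7}, "p3 & p4 & ~p7"),
        ({3, 4, 8}, "p3 & p4 & ~p8"),
        ({3, 4, 7, 8}, "p3 & p4 & ~p7 & ~p8"),
        ({3, 7, 8}, "p3 & ~p7 & ~p8"),
        ({4, 7, 8}, "p4 & ~p7 & ~p8"),
        ({7, 8}, "~p7 & ~p8"),
    )
    return tuple((frozenset(sub), parse_formula(text)) for sub, text in table)


def default_candidates(t: TrialSpec):
    """Candidate family for a trial: the designed seven for trial 6,
    otherwise the trial's two competing rules."""
    if t.index == 6:
        return trial6_candidates()
    return (
        (formula_vars(t.phi1), t.phi1),
        (formula_vars(t.phi2), t.phi2),
    )


def infer_attended(
    selection,
    t: TrialSpec,
    candidates=None,
    tolerance: str = "exact",
) -> AttendedInference:
    """Recover the attended feature set behind a generalization selection.

    ``matched``: the selection equals exactly one candidate's predicted
    selection.  ``one_away`` (only with ``tolerance="one_away"``): it is
    at symmetric distance 1 from a unique nearest candidate.  Anything
    else — including ties — is ``no_rationale``.
    """
    if tolerance not in ("exact", "one_away"):
        raise ValueError(f"unknown tolerance {tolerance!r}")
    selection = frozenset(selection)
    if not selection <= t.gen_shown_ids:
        raise ValueError("selection contains ids outside the trial's shown elements")
    if candidates is None:
        candidates = default_candidates(t)
    exact = [
        (sub, rule)
        for sub, rule in candidates
        if predicted_selection(rule, t) == selection
    ]
    if len(exact) == 1:
        sub, rule = exact[0]
        return AttendedInference("matched", frozenset(sub), rule)
    if len(exact) > 1 or tolerance == "exact":
        return AttendedInference("no_rationale")
    near = [
        (sub, rule)
        for sub, rule in candidates
        if len(predicted_selection(rule, t) ^ selection) == 1
    ]
    if len(near) == 1:
        sub, rule = near[0]
        return AttendedInference("one_away", frozenset(sub), rule)
    return AttendedInference("no_rationale")


def stickiness_score(attended, previous) -> Fraction:
    """Fraction of the attended features reused from the previous trial."""
    attended = frozenset(attended)
    if not attended:
        raise ValueError("empty attended set")
    return Fraction(len(attended & frozenset(previous)), len(attended))


def stickiness_null(
    n_participants: int,
    n_sims: int,
    seed,
    observed_mean: float = None,
) -> StickinessNull:
    """Random-attention null for the cohort mean stickiness score.

    Each simulated agent attends uniformly to one of the seven trial-6
    subsets; the per-simulation mean score is recorded.  The p-value is
    the add-one Monte-Carlo estimate of P(null mean >= observed), never
    smaller than 1/(n_sims+1).  The analytic null mean is 1/2.
    """
    if n_participants < 1 or n_sims < 1:
        raise ValueError("n_participants and n_sims must be >= 1")
    scores = np.array(
        [float(stickiness_score(sub, TRIAL6_PREVIOUS)) for sub, _ in trial6_candidates()]
    )
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(scores), size=(n_sims, n_participants))
    means = scores[draws].mean(axis=1)
    if observed_mean is None:
        p = float("nan")
    else:
        p = (np.count_nonzero(means >= observed_mean) + 1) / (n_sims + 1)
    return StickinessNull(means=means, p_value=p, observed_mean=observed_mean)


# ---------------------------------------------------------------------------
# Hypothesis I: conjunction vs disjunction

def _conj_disj_sides(t: TrialSpec):
    """Map the trial's two generalization sides to operator labels."""
    labels = {}
    for phi, side in ((t.phi1, t.gen_side1), (t.phi2, t.gen_side2)):
        if isinstance(phi, And):
            labels["conjunction"] = t.ids_of(side)
        elif isinstance(phi, Or):
            labels["disjunction"] = t.ids_of(side)
    if set(labels) != {"conjunction", "disjunction"}:
        raise ValueError("trial does not oppose a conjunction to a disjunction")
    return labels


def classify_h1(selection, t: TrialSpec, negative_flag: bool = False) -> str:
    """Classify a trial-1 selection as conjunction, disjunction or neither.

    Selecting exactly the elements satisfied only by the conjunctive rule
    reveals a conjunctive explanation, and symmetrically.  A participant
    who verbally explained the *negative* examples has, by De Morgan,
    internalized the dual operator, so the flag swaps the two labels.
    """
    labels = _conj_disj_sides(t)
    selection = frozenset(selection)
    if selection == labels["conjunction"]:
        verdict = "conjunction"
    elif selection == labels["disjunction"]:
        verdict = "disjunction"
    else:
        return "neither"
    if negative_flag:
        verdict = "disjunction" if verdict == "conjunction" else "conjunction"
    return verdict


def h1_test(
    n_conj: int,
    n_disj: int,
    n_neither: int,
    null: str = "binomial_half",
    seed=None,
    trial: TrialSpec = None,
    n_sims: int = 100_000,
) -> float:
    """Tail probability of the observed conjunction count under a null.

    ``binomial_half``: exact upper tail of Binomial(n_conj+n_disj, 1/2)
    at n_conj.  ``random_subset_sim``: Monte-Carlo null in which every
    participant picks a uniformly random subset of the shown elements
    and is classified; p is the add-one fraction of simulations with at
    least the observed conjunction count (requires ``trial``).
    """
    if min(n_conj, n_disj, n_neither) < 0:
        raise ValueError("counts must be nonnegative")
    if null == "binomial_half":
        n = n_conj + n_disj
        if n == 0:
            return 1.0
        return float(stats.binom.sf(n_conj - 1, n, 0.5))
    if null == "random_subset_sim":
        if trial is None:
            raise ValueError("random_subset_sim requires the trial")
        labels = _conj_disj_sides(trial)
        shown = sorted(trial.gen_shown_ids)
        index = {eid: i for i, eid in enumerate(shown)}
        mask_conj = sum(1 << index[e] for e in labels["conjunction"])
        n_total = n_conj + n_disj + n_neither
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 1 << len(shown), size=(n_sims, n_total), dtype=np.uint64)
        conj_counts = (draws == np.uint64(mask_conj)).sum(axis=1)
        return float((np.count_nonzero(conj_counts >= n_conj) + 1) / (n_sims + 1))
    raise ValueError(f"unknown null {null!r}")


# ---------------------------------------------------------------------------
# Hypothesis IV: operator vs feature transitions

def _top_operator(f: Formula) -> str:
    if isinstance(f, And):
        return "and"
    if isinstance(f, Or):
        return "or"
    return "literal"


def classify_transition(rule_t1: Formula, rule_t2: Formula) -> str:
    """Four-way classification of a consecutive-trial rule transition."""
    if rule_t1 is None or rule_t2 is None:
        return "unclassifiable"
    same_op = _top_operator(rule_t1) == _top_operator(rule_t2) != "literal"
    same_features = formula_vars(rule_t1) == formula_vars(rule_t2)
    if same_op and same_features:
        return "kept_both"
    if same_op:
        return "kept_operator"
    if same_features:
        return "kept_features"
    return "kept_neither"


# ---------------------------------------------------------------------------
# Hypothesis III: learning-time ratios

def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / pooled)


def time_ratio_test(records, outlier_factor: float = 5.0) -> TimeRatioResult:
    """Group X vs Y comparison of the trial-4 / trial-5 learning-time ratio.

    Participants whose ratio exceeds ``outlier_factor`` in either
    direction are excluded; the surviving ratios are compared with a
    pooled two-sample t-test and Cohen's d (pooled SD).
    """
    ratios, excluded, by_group = {}, [], {"X": [], "Y": []}
    for rec in records:
        t4 = rec.response(4).learning_time_s
        t5 = rec.response(5).learning_time_s
        r = t4 / t5
        ratios[rec.id] = r
        if r > outlier_factor or r < 1.0 / outlier_factor:
            excluded.append(rec.id)
            continue
        if rec.group not in by_group:
            raise ValueError(f"unknown group {rec.group!r} for participant {rec.id}")
        by_group[rec.group].append(r)
    x = np.asarray(by_group["X"], dtype=float)
    y = np.asarray(by_group["Y"], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least two unexcluded participants per group")
    t_stat, p = stats.ttest_ind(x, y, equal_var=True)
    return TimeRatioResult(
        ratios=ratios,
        excluded=tuple(excluded),
        t=float(t_stat),
        df=len(x) + len(y) - 2,
        p_value=float(p),
        d=_cohens_d(x, y),
        group_means={"X": float(x.mean()), "Y": float(y.mean())},
    )


# ---------------------------------------------------------------------------
# stickiness analysis over a cohort

def stickiness_analysis(
    records,
    plans,
    n_sims: int = 100_000,
    seed=None,
    tolerance: str = "exact",
) -> StickinessResult:
    """Per-participant stickiness scores at trial 6 plus the null test.

    A participant is valid when the trial-6 selection exactly matches one
    candidate (one-away selections are excluded, as are participants with
    no clear rationale at trial 5, whose attended features are unknown).
    ``previous`` is each participant's inferred trial-5 attended set.
    """
    scores, excluded = {}, []
    for rec in records:
        plan = _plan_for(plans, rec.group)
        t5 = plan.trial(5)
        t6 = plan.trial(6)
        inf5 = infer_attended(rec.response(5).selection, t5, tolerance=tolerance)
        inf6 = infer_attended(rec.response(6).selection, t6, tolerance="exact")
        if inf5.verdict == "no_rationale" or inf6.verdict != "matched":
            excluded.append(rec.id)
            continue
        scores[rec.id] = float(stickiness_score(inf6.attended, inf5.attended))
    if not scores:
        raise ValueError("no valid participants for the stickiness analysis")
    values = np.array(list(scores.values()))
    mean = float(values.mean())
    null = stickiness_null(len(values), n_sims, seed, observed_mean=mean)
    group_vals = {
        g: np.array([s for pid, s in scores.items() if _group_of(records, pid) == g])
        for g in ("X", "Y")
    }
    if all(len(v) >= 2 for v in group_vals.values()):
        t_stat, _ = stats.ttest_ind(group_vals["X"], group_vals["Y"], equal_var=True)
        d = _cohens_d(group_vals["X"], group_vals["Y"])
        group_means = {g: float(v.mean()) for g, v in group_vals.items()}
    else:
        t_stat, d = float("nan"), float("nan")
        group_means = {g: float(v.mean()) if len(v) else float("nan")
                       for g, v in group_vals.items()}
    return StickinessResult(
        scores=scores,
        n_valid=len(scores),
        mean=mean,
        p_value=null.p_value,
        group_means=group_means,
        group_t=float(t_stat),
        group_d=d,
        excluded=tuple(excluded),
    )


def _group_of(records, pid: str) -> str:
    for rec in records:
        if rec.id == pid:
            return rec.group
    raise KeyError(pid)


def _plan_for(plans, group: str) -> ExperimentPlan:
    if isinstance(plans, ExperimentPlan):
        return plans
    return plans[group]


# ---------------------------------------------------------------------------
# MDL bias

def mdl_bias_tally(records, plans, trials=(3, 4, 5)) -> dict:
    """Count generalization responses consistent with the short rule, the
    long rule, or neither, over the MDL-contrast trials."""
    counts = {"short_rule_consistent": 0, "long_rule_consistent": 0, "neither": 0}
    from .logic import formula_length

    for rec in records:
        plan = _plan_for(plans, rec.group)
        for idx in trials:
            t = plan.trial(idx)
            short, long_ = (
                (t.phi1, t.phi2)
                if formula_length(t.phi1) <= formula_length(t.phi2)
                else (t.phi2, t.phi1)
            )
            sel = rec.response(idx).selection
            if sel == predicted_selection(short, t):
                counts["short_rule_consistent"] += 1
            elif sel == predicted_selection(long_, t):
                counts["long_rule_consistent"] += 1
            else:
                counts["neither"] += 1
    return counts


# ---------------------------------------------------------------------------
# full report

def analyze(
    plans,
    records,
    tolerance: str = "exact",
    outlier_factor: float = 5.0,
    n_sims: int = 100_000,
    seed=0,
) -> dict:
    """Run all analyses over a cohort and return the JSON-ready report."""
    rng = np.random.default_rng(seed)

    h1_counts = {"conjunction": 0, "disjunction": 0, "neither": 0}
    some_plan = _plan_for(plans, records[0].group)
    for rec in records:
        t1 = _plan_for(plans, rec.group).trial(1)
        resp = rec.response(1)
        h1_counts[classify_h1(resp.selection, t1, resp.negative_flag)] += 1
    p_binom = h1_test(
        h1_counts["conjunction"], h1_counts["disjunction"], h1_counts["neither"]
    )
    p_sim = h1_test(
        h1_counts["conjunction"],
        h1_counts["disjunction"],
        h1_counts["neither"],
        null="random_subset_sim",
        seed=int(rng.integers(2**31)),
        trial=some_plan.trial(1),
        n_sims=n_sims,
    )

    h2 = stickiness_analysis(
        records, plans, n_sims=n_sims, seed=int(rng.integers(2**31)), tolerance=tolerance
    )

    groups = {rec.group for rec in records}
    h3 = None
    if groups >= {"X", "Y"}:
        h3 = time_ratio_test(records, outlier_factor=outlier_factor)

    h4_counts: dict = {}
    for rec in records:
        plan = _plan_for(plans, rec.group)
        inf1 = infer_attended(rec.response(1).selection, plan.trial(1), tolerance=tolerance)
        inf2 = infer_attended(rec.response(2).selection, plan.trial(2), tolerance=tolerance)
        cls = classify_transition(inf1.rule, inf2.rule)
        h4_counts[cls] = h4_counts.get(cls, 0) + 1

    bias = mdl_bias_tally(records, plans)

    report = {
        "h1": {"counts": h1_counts, "p_binomial": p_binom, "p_sim": p_sim},
        "h2": {
            "scores": h2.scores,
            "n_valid": h2.n_valid,
            "mean": h2.mean,
            "p": h2.p_value,
            "group_means": h2.group_means,
            "t": h2.group_t,
            "d": h2.group_d,
            "excluded": list(h2.excluded),
        },
        "h3": None
        if h3 is None
        else {
            "ratios": h3.ratios,
            "excluded": list(h3.excluded),
            "t": h3.t,
            "df": h3.df,
            "p": h3.p_value,
            "d": h3.d,
            "group_means": h3.group_means,
        },
        "h4": {"transition_counts": h4_counts},
        "mdl_bias": {"counts": bias},
    }
    return report
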