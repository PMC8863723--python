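"""Construction and validation of dual-explanation concept-learning trials.

A trial presents an underdetermined concept: positives are the
intersection of two experimenter-chosen concepts C1, C2 (models of
minimal rules φ1, φ2 on disjoint feature sets) and negatives are the
complement of their union.  Both rules then classify every shown example
correctly, and — the soundness guarantee — any other consistent rule
must mention a superset of one rule's features.  The generalization
stage shows elements from the symmetric difference C1∖C2 / C2∖C1, which
the two rules classify oppositely, revealing which rule (hence which
features) a learner internalized.

:func:`validate_trial` checks the guarantee constructively: for every
feature subset S containing neither rule's full variable set, some
positive and negative example coincide on S, so no rule over S alone can
separate the data; and :func:`flip_certificate` exhibits, for each pair
(p, q) of variables from the two rules, a positive example turned
negative by flipping exactly p and q — the constructive core of the
soundness proof.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .logic import (
    And,
    Formula,
    Lit,
    Or,
    Valuation,
    eval_formula,
    flip,
    formula_vars,
    iter_valuations,
    parse_formula,
    project,
    validate_context,
)
from .mdl import is_minimal

#: positive/negative example counts required of the six standard trials
TABLE_COUNTS = {1: (12, 12), 2: (12, 12), 3: (10, 18), 4: (10, 18), 5: (10, 18), 6: (4, 36)}

#: (p3,p4,p7,p8) values of the seven designed trial-6 generalization elements
TRIAL6_ELEMENTS = (
    (1, 1, 1, 1),
    (1, 1, 0, 1),
    (1, 1, 1, 0),
    (1, 1, 0, 0),
    (1, 0, 0, 0),
    (0, 1, 0, 0),
    (0, 0, 0, 0),
)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: the two competing rules and all derived example sets.

    Example sequences are stored in coordinate-lexicographic order of the
    context.  ``gen_shown`` is the subset of the universe actually shown
    at generalization; for trials 1–5 it defaults to the full symmetric
    difference, while trial 6 uses seven designed elements (one of which
    satisfies both rules, so it is not restricted to the differences).
    """

    index: int
    group: str  # "X", "Y" or "both"
    phi1: Formula
    phi2: Formula
    ctx: tuple
    positives: tuple
    negatives: tuple
    gen_side1: tuple  # C1 \ C2
    gen_side2: tuple  # C2 \ C1
    gen_shown: tuple

    # -- element identifiers: "t<trial>_e<rank>" with rank the valuation's
    #    coordinate-lexicographic position in the 2^k universe.
    def rank(self, v: Valuation) -> int:
        r = 0
        for bit in v:
            r = (r << 1) | bit
        return r

    def element_id(self, v: Valuation) -> str:
        return f"t{self.index}_e{self.rank(v)}"

    def ids_of(self, valuations) -> frozenset:
        return frozenset(self.element_id(v) for v in valuations)

    @property
    def gen_shown_ids(self) -> frozenset:
        return self.ids_of(self.gen_shown)

    def valuation_of(self, element_id: str) -> Valuation:
        prefix = f"t{self.index}_e"
        if not element_id.startswith(prefix):
            raise KeyError(element_id)
        r = int(element_id[len(prefix):])
        k = len(self.ctx)
        if not (0 <= r < 1 << k):
            raise KeyError(element_id)
        return tuple((r >> (k - 1 - i)) & 1 for i in range(k))


@dataclass(frozen=True)
class ValidationReport:
    """Per-check outcome of the trial soundness validator."""

    disjoint_vars: bool
    minimality_phi1: bool
    minimality_phi2: bool
    distinct_concepts: bool
    projection_coverage: bool
    #: subsets S (sorted tuples) with no positive/negative projection collision
    uncovered_subsets: tuple = ()
    #: S -> one colliding (positive, negative) pair, for every tested S that passed
    collision_witnesses: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.disjoint_vars
            and self.minimality_phi1
            and self.minimality_phi2
            and self.distinct_concepts
            and self.projection_coverage
        )


@dataclass(frozen=True)
class ExperimentPlan:
    """Six ordered trials for one group of the standard experiment."""

    group: str
    trials: tuple
    seed: int

    def trial(self, index: int) -> TrialSpec:
        for t in self.trials:
            if t.index == index:
                return t
        raise KeyError(f"no trial {index} in plan")


def build_trial(
    phi1: Formula,
    phi2: Formula,
    ctx,
    index: int = 0,
    group: str = "both",
    gen_shown=None,
) -> TrialSpec:
    """Derive all example sets of a dual-explanation trial.

    Positives are models of φ1∧φ2, negatives of ¬(φ1∨φ2); the two
    generalization sides are the set differences.  The rules must use
    disjoint, nonempty variable sets inside ``ctx`` and neither derived
    learning set may be empty (degenerate rules).
    """
    ctx = tuple(ctx)
    validate_context(ctx)
    v1, v2 = formula_vars(phi1), formula_vars(phi2)
    if v1 & v2:
        raise ValueError(f"rules share variables {sorted(v1 & v2)}")
    if not (v1 | v2) <= frozenset(ctx):
        raise ValueError("rule variables outside the shown context")

    positives, negatives, side1, side2 = [], [], [], []
    for v in iter_valuations(ctx):
        s1 = eval_formula(phi1, v, ctx)
        s2 = eval_formula(phi2, v, ctx)
        if s1 and s2:
            positives.append(v)
        elif not s1 and not s2:
            negatives.append(v)
        elif s1:
            side1.append(v)
        else:
            side2.append(v)
    if not positives or not negatives:
        raise ValueError("degenerate rule pair: empty positive or negative set")

    if gen_shown is None:
        shown = tuple(sorted(side1 + side2))
    else:
        shown = tuple(gen_shown)
        universe = set(iter_valuations(ctx))
        if not set(shown) <= universe:
            raise ValueError("gen_shown contains valuations outside the universe")
    return TrialSpec(
        index=index,
        group=group,
        phi1=phi1,
        phi2=phi2,
        ctx=ctx,
        positives=tuple(positives),
        negatives=tuple(negatives),
        gen_side1=tuple(side1),
        gen_side2=tuple(side2),
        gen_shown=shown,
    )


def separating_rule_exists(t: TrialSpec, subset) -> bool:
    """Whether some Boolean function of the ``subset`` coordinates alone
    classifies all positives true and all negatives false.

    Decided by the projection-collision test: such a function exists iff
    no positive and negative example share the same projection onto the
    subset (the indicator of projected positives then separates).
    """
    subset = frozenset(subset)
    pos_proj = {project(v, t.ctx, subset) for v in t.positives}
    neg_proj = {project(v, t.ctx, subset) for v in t.negatives}
    return not (pos_proj & neg_proj)


def validate_trial(t: TrialSpec) -> ValidationReport:
    """Check the dual-explanation soundness conditions on a trial.

    (a) the rules use disjoint variables; (b) each rule is minimal for
    its own concept; (c) the two concepts differ over the context;
    (d) projection coverage: every subset S that contains neither rule's
    variable set admits a positive/negative collision, so no rule over S
    separates the examples.  Failures are reported, never raised.
    """
    v1, v2 = formula_vars(t.phi1), formula_vars(t.phi2)
    disjoint = not (v1 & v2)
    min1 = is_minimal(t.phi1)
    min2 = is_minimal(t.phi2)
    m1 = {v for v in iter_valuations(t.ctx) if eval_formula(t.phi1, v, t.ctx)}
    m2 = {v for v in iter_valuations(t.ctx) if eval_formula(t.phi2, v, t.ctx)}
    distinct = m1 != m2

    uncovered, witnesses = [], {}
    features = tuple(t.ctx)
    for r in range(len(features) + 1):
        for combo in combinations(features, r):
            s = frozenset(combo)
            if v1 <= s or v2 <= s:
                continue  # a separating rule legitimately exists here
            pos_proj = {}
            for v in t.positives:
                pos_proj.setdefault(project(v, t.ctx, s), v)
            witness = None
            for v in t.negatives:
                p = project(v, t.ctx, s)
                if p in pos_proj:
                    witness = (pos_proj[p], v)
                    break
            if witness is None:
                uncovered.append(tuple(sorted(s)))
            else:
                witnesses[tuple(sorted(s))] = witness
    return ValidationReport(
        disjoint_vars=disjoint,
        minimality_phi1=min1,
        minimality_phi2=min2,
        distinct_concepts=distinct,
        projection_coverage=not uncovered,
        uncovered_subsets=tuple(uncovered),
        collision_witnesses=witnesses,
    )


def flip_certificate(t: TrialSpec, p: int, q: int):
    """A positive example that flipping exactly {p, q} turns negative.

    ``p`` must occur in φ1 and ``q`` in φ2.  Returns the (positive,
    negative) pair — the first in canonical order — or ``None`` if no
    positive example admits the flip (never the case for sound trials).
    """
    if p not in formula_vars(t.phi1):
        raise ValueError(f"p{p} does not occur in phi1")
    if q not in formula_vars(t.phi2):
        raise ValueError(f"p{q} does not occur in phi2")
    negatives = set(t.negatives)
    for v in t.positives:
        flipped = flip(v, t.ctx, {p, q})
        if flipped in negatives:
            return v, flipped
    return None


# ---------------------------------------------------------------------------
# the standard six-trial experiment

def long_rule(a: int, b: int, c: int) -> Formula:
    """The length-15 rule template ((a∨(b∨c))∧(¬a∨((b∨¬c)∧(c∨¬b)))).

    Its concept has MDL 15 over {a, b, c}; substituting variables keeps
    the competing rules' feature sets disjoint trial by trial.
    """
    return And(
        Or(Lit(a), Or(Lit(b), Lit(c))),
        Or(
            Lit(a, False),
            And(Or(Lit(b), Lit(c, False)), Or(Lit(c), Lit(b, False))),
        ),
    )


def standard_experiment(group: str, seed: int = 0) -> ExperimentPlan:
    """The six standard trials for group X or Y.

    Trials 1–4 span features p1..p6, trials 5–6 span p3..p8; the groups
    differ only in trial 3 (X learns the short rule on {p1,p2}, Y on
    {p5,p6}).  The length-15 alternative uses {p3,p4,p5} in trial 3(X),
    {p1,p2,p3} in trials 3(Y) and 4, and {p4,p5,p6} in trial 5.  Example
    counts are asserted against the design table at build time.
    """
    if group not in ("X", "Y"):
        raise ValueError(f"group must be 'X' or 'Y', got {group!r}")
    ctx_a = (1, 2, 3, 4, 5, 6)
    ctx_b = (3, 4, 5, 6, 7, 8)
    if group == "X":
        trial3 = build_trial(parse_formula("p1 & p2"), long_rule(3, 4, 5), ctx_a, 3, group)
    else:
        trial3 = build_trial(parse_formula("p5 & p6"), long_rule(1, 2, 3), ctx_a, 3, group)

    # Seven designed trial-6 elements: (p3,p4,p7,p8) per the design table,
    # the free features p5,p6 fixed to 0.  Context order is p3..p8.
    t6_shown = tuple((a, b, 0, 0, c, d) for a, b, c, d in TRIAL6_ELEMENTS)

    trials = (
        build_trial(parse_formula("p1 | p2"), parse_formula("p3 & p4"), ctx_a, 1, group),
        build_trial(parse_formula("~p1 & p2"), parse_formula("p3 | ~p4"), ctx_a, 2, group),
        trial3,
        build_trial(parse_formula("~p5 & p6"), long_rule(1, 2, 3), ctx_a, 4, group),
        build_trial(parse_formula("p7 & p8"), long_rule(4, 5, 6), ctx_b, 5, group),
        build_trial(
            parse_formula("~p7 & ~p8"), parse_formula("p3 & p4"), ctx_b, 6, group,
            gen_shown=t6_shown,
        ),
    )
    for t in trials:
        want = TABLE_COUNTS[t.index]
        got = (len(t.positives), len(t.negatives))
        if got != want:
            raise AssertionError(
                f"trial {t.index} ({group}): example counts {got} != designed {want}"
            )
    return ExperimentPlan(group=group, trials=trials, seed=seed)
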