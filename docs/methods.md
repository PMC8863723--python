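# Methods

## The dual-explanation construction

A trial is specified by two NNF rules φ1, φ2 over disjoint feature sets
inside a shown context of 6 features (a 64-element universe). The derived
example sets are

- positives  = models(φ1 ∧ φ2),
- negatives  = models(¬(φ1 ∨ φ2)),
- generalization sides = models(φ1 ∧ ¬φ2) and models(φ2 ∧ ¬φ1),

a partition of the universe. Both rules classify every shown example
correctly, and the soundness property states that any rule consistent with
the shown examples must use a superset of vars(φ1) or of vars(φ2).

`validate_trial` checks this constructively rather than symbolically. For a
feature subset S, a rule over S alone separating positives from negatives
exists iff no positive and negative example coincide on their S-projection
(if projections are disjoint, the indicator of projected positives is such a
rule). The validator therefore enumerates all 2^6 subsets S with
vars(φ1) ⊄ S and vars(φ2) ⊄ S and records one colliding (positive, negative)
pair per subset; any uncovered subset is a construction failure. It also
checks variable disjointness, minimality of each rule for its own concept
(via the MDL engine), and that the two concepts differ over the context.

`flip_certificate(t, p, q)` realizes the proof idea behind the collision
property: it finds a positive example that becomes a negative example when
exactly one variable of each rule (p ∈ vars(φ1), q ∈ vars(φ2)) is flipped.
Such a pair collides on every S avoiding p and q. When several certificates
exist the first in coordinate-lexicographic order of the positives is
returned; the choice is arbitrary and documented, not semantic.

## The length metric and the MDL engine

len(φ) counts literal occurrences plus ∧/∨ occurrences; negation is free.
Consequences used throughout: a binary tree with n leaves has length 2n−1
(all lengths are odd, and the metric is invariant to re-association of
printed n-ary chains), and De Morgan rewriting is length-preserving, so
storing formulas in NNF loses no generality.

MDL is computed exactly by a bottom-up dynamic program over truth tables
(2^k-bit masks, bit i = value at the i-th valuation in coordinate-
lexicographic order). Literals seed their masks at length 1; for increasing
odd L = a + b + 1, every pair of already-assigned (hence minimal) functions
of lengths a, b is combined under AND (mask intersection) and OR (mask
union); an unassigned mask first produced at L has MDL exactly L, because
any length-L formula splits into two shorter subformulas whose masks were
assigned at no more than their own lengths. Witness tie-breaking is
lexicographic on the formatted formula string, making the table
deterministic.

Numerical/scale choices: exact mode is limited to k ≤ 4 support variables
(65 536 functions; every rule in the standard experiment has ≤ 3, every
trial-6 candidate ≤ 4). The default cap is 19 because the hardest
3-variable function needs length 19; the k ≤ 3 tables are therefore
complete. MDL is computed over a formula's own support: we assume a
shortest rule never profits from mentioning variables outside the concept's
support, which holds for every concept checked here but is not proved in
general.

## The standard experiment

Trials 1–4 span p1..p6, trials 5–6 span p3..p8; groups X and Y differ only
in trial 3. The length-15 alternative in trials 3–5 is the template
((a ∨ (b ∨ c)) ∧ (¬a ∨ ((b ∨ ¬c) ∧ (c ∨ ¬b)))) with per-trial variable
substitutions keeping the two rules' features disjoint: {p3,p4,p5} in
3(X), {p1,p2,p3} in 3(Y) and 4, {p4,p5,p6} in 5. The design fixes only the
substitutions' disjointness; the {p1,p2,p3} choice for 3(Y)/4 is ours and
the example counts are invariant to it. Expected counts
(12/12, 12/12, 10/18, 10/18, 10/18, 4/36) are asserted at build time.

Trials 1–5 show the full symmetric difference at generalization (maximal
discriminability; overridable per trial). Trial 6 shows seven designed
elements with (p3,p4,p7,p8) ∈ {(1,1,1,1), (1,1,0,1), (1,1,1,0), (1,1,0,0),
(1,0,0,0), (0,1,0,0), (0,0,0,0)}; the free features p5, p6 are fixed to 0
(inference depends only on the four named coordinates). Note the element
(1,1,0,0) satisfies both rules — it belongs to every candidate's predicted
selection and is the one generalization element not drawn from the set
differences; trial 6 is deliberately exceptional in this respect.

## Inference and scores

A learner holding rule r should select exactly the shown generalization
elements satisfying r. `infer_attended` matches an observed selection
against a candidate family (trials 1–5: the two designed rules; trial 6:
the seven minimal rules over the subsets spanning {p3,p4} and {p7,p8});
the predicted selections are pairwise distinct, so an exact match is
unique. A selection at symmetric distance 1 from a unique candidate can
optionally be labelled `one_away`; everything else has no rationale.

The stickiness score of an attended set A given the previous trial's set P
is |A ∩ P| / |A| — the simplest ratio reproducing the seven designed
trial-6 values (1, 2/3, 2/3, 1/2, 1/3, 1/3, 0 with P = {p7,p8}). Cohort
analysis keeps participants whose trial-6 selection matches a candidate
exactly and whose trial-5 selection has a clear rationale (their inferred
trial-5 attended set supplies P); the random-attention null draws each
agent's subset uniformly among the seven candidates (analytic null mean
1/2) and the p-value is the add-one Monte-Carlo estimate
(count + 1)/(n_sims + 1), so a zero count reports an upper bound rather
than 0.

The conjunction-bias count is tested against two nulls, reported side by
side because the choice is genuinely open: an exact binomial(n, 1/2) upper
tail over the classified participants, and a Monte-Carlo null in which
every participant selects a uniformly random subset of the shown elements.
Participants flagged as having explained the *negative* examples have, by
De Morgan, internalized the dual operator, so the flag swaps the
conjunction/disjunction labels. The time-transfer analysis uses the
trial-4/trial-5 learning-time ratio, excludes participants beyond a 5×
ratio in either direction, and compares groups with a pooled two-sample
t-test and Cohen's d (pooled SD; the variant is a convention choice).

## The agent simulator

The framework implies no mechanistic agent; the simulator operationalizes
the studied biases as an explicit decision hierarchy so analyses can be
validated end-to-end (parameter recovery), and its structure is an explicit
modeling assumption:

1. with probability `p_stick`, if the previously attended feature set hosts
   a consistent candidate rule, adopt it and multiply learning time by
   `stick_speed`;
2. otherwise sample candidates with softmax weights exp(−`lambda_mdl`·MDL);
3. a two-candidate MDL tie opposing a conjunction to a disjunction resolves
   toward the conjunction with probability `p_conj`.

Selections are the chosen rule's predicted selection, except a `p_lapse`
chance of a uniformly random subset. Learning times are log-normal
(`time_mu`, `time_sigma` in log-seconds). Defaults encode the study's
headline conditions: p_conj = 0.875 (77 conjunctive vs 11 disjunctive
classified responses), p_lapse = 0.12 (12/100 without rationale),
p_stick = 0.36 (solving p + 0.5(1−p) = 0.68, the observed mean stickiness),
lambda_mdl = 1 (the 280-vs-2 short/long split is saturated for any λ ≳ 1),
time_mu = 4.0 ≈ log(55 s), time_sigma = 0.5, stick_speed = 0.8. Training
attempts are geometric in p_lapse, for schema completeness only.

What the simulator does *not* emulate: within-trial learning dynamics,
verbal explanation content, memory or fatigue across trials, individual
parameter heterogeneity, and selections that are near-misses of a rule
(lapses are fully random). Passing recovery tests therefore show that the
analysis pipeline is consistent and well-calibrated under the generative
assumptions, not that human data satisfy them.

## Problem sizes and determinism

All randomness flows through numpy Generators seeded explicitly;
per-participant seeds derive from a SeedSequence, so cohorts are
reproducible bit-for-bit. Test-suite simulations use cohorts of 10–300
agents and Monte-Carlo nulls of 500–10 000 draws; the stochastic
recovery checks (e.g. 20 replicate 50-per-group studies for the
stick-speed effect) were sized to keep the whole suite in a few seconds
while leaving the checked effects many standard errors wide.

## Known limitations

- Exact MDL stops at 4 support variables; no heuristic fallback.
- Only two competing rules per trial (the construction generalizes, the
  implementation does not).
- `one_away` inference can be ambiguous (several candidates at distance 1);
  ambiguity is conservatively reported as no rationale.
- The trial-6 candidate family is specific to the standard design; custom
  trials with different generalization sets need their own families.
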