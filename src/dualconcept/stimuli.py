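"""Icon randomization, presentation ordering, and plan/response files.

Each of the eight features is rendered by a fixed pair of glyphs — one
for the positive value, one for the negative.  The pairing of glyph
pairs to features is randomized once per participant, but polarity
within a pair is never swapped (the positive glyph always means 1).
Glyphs here are abstract symbol identifiers; rendering is a presentation
concern the framework's logic never depends on, and symbol positions
inside a box are not modeled (they carry no information).

Learning-stage ordering follows the protocol: positives are shuffled
among themselves, negatives among themselves, and all positives precede
all negatives; the training stage reshuffles the same elements untagged.

File formats: an experiment plan is a versioned JSON document and
participant responses are a flat CSV, one row per participant × trial,
with selections as ``;``-separated element ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .logic import format_formula, parse_formula
from .trials import ExperimentPlan, TrialSpec, build_trial

SCHEMA_VERSION = 1

#: the eight fixed glyph pairs (positive id, negative id)
ICON_PAIRS = tuple((f"pair{i}_pos", f"pair{i}_neg") for i in range(1, 9))

RESPONSE_COLUMNS = [
    "participant_id",
    "group",
    "trial",
    "learning_time_s",
    "training_attempts",
    "selection",
    "explanation_text",
    "negative_interpretation_flag",
]


@dataclass(frozen=True)
class IconAssignment:
    """Seeded bijection between features p1..p8 and the glyph pairs."""

    mapping: dict  # feature -> (positive_glyph, negative_glyph)
    seed: int

    def glyphs_for(self, valuation, ctx) -> frozenset:
        return frozenset(
            self.mapping[feat][0 if bit else 1] for bit, feat in zip(valuation, ctx)
        )


@dataclass(frozen=True)
class StimulusElement:
    element_id: str
    valuation: tuple
    glyphs: frozenset
    border: str  # "positive" | "negative" | "untagged"


@dataclass(frozen=True)
class TrialPresentation:
    learning_order: tuple
    training_order: tuple
    seed: int


@dataclass(frozen=True)
class TrialResponse:
    selection: frozenset  # element ids chosen at generalization
    learning_time_s: float
    training_attempts: int
    explanation_text: str = ""
    negative_flag: bool = False


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: group label plus the six per-trial responses."""

    id: str
    group: str
    responses: dict = field(default_factory=dict)  # trial index -> TrialResponse

    def response(self, trial: int) -> TrialResponse:
        return self.responses[trial]


def assign_icons(seed: int) -> IconAssignment:
    """Uniformly random feature→glyph-pair bijection, deterministic in seed."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ICON_PAIRS))
    mapping = {feat: ICON_PAIRS[order[feat - 1]] for feat in range(1, 9)}
    return IconAssignment(mapping=mapping, seed=seed)


def present_learning(t: TrialSpec, icons: IconAssignment, seed: int) -> TrialPresentation:
    """Seeded learning and training orderings of a trial's examples."""
    rng = np.random.default_rng(seed)

    def element(v, border):
        return StimulusElement(
            element_id=t.element_id(v),
            valuation=v,
            glyphs=icons.glyphs_for(v, t.ctx),
            border=border,
        )

    pos = [element(v, "positive") for v in t.positives]
    neg = [element(v, "negative") for v in t.negatives]
    learning = [pos[i] for i in rng.permutation(len(pos))]
    learning += [neg[i] for i in rng.permutation(len(neg))]
    untagged = [
        StimulusElement(e.element_id, e.valuation, e.glyphs, "untagged")
        for e in pos + neg
    ]
    training = [untagged[i] for i in rng.permutation(len(untagged))]
    return TrialPresentation(tuple(learning), tuple(training), seed)


# ---------------------------------------------------------------------------
# plan JSON

def _trial_record(t: TrialSpec) -> dict:
    return {
        "index": t.index,
        "group": t.group,
        "phi1": format_formula(t.phi1),
        "phi2": format_formula(t.phi2),
        "context": [f"p{i}" for i in t.ctx],
        "positives": [list(v) for v in t.positives],
        "negatives": [list(v) for v in t.negatives],
        "gen_shown": [list(v) for v in t.gen_shown],
        "element_ids": {t.element_id(v): list(v) for v in t.gen_shown},
    }


def export_experiment(plan: ExperimentPlan, icons: IconAssignment, path) -> dict:
    """Write the plan (and icon assignment) as a versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "group": plan.group,
        "seed": plan.seed,
        "icon_assignment": {
            "seed": icons.seed,
            "mapping": {f"p{feat}": list(pair) for feat, pair in icons.mapping.items()},
        },
        "trials": [_trial_record(t) for t in plan.trials],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return doc


class SchemaError(ValueError):
    """The plan document violates the expected schema."""


def load_experiment(path):
    """Read a plan JSON back into (ExperimentPlan, IconAssignment).

    Trials are rebuilt from their formula strings and the derived example
    sets are checked against the stored ones, so a hand-edited document
    that breaks the dual-rule construction is rejected.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {doc.get('schema_version')!r}")
    trials = []
    for rec in doc["trials"]:
        ctx = tuple(int(name[1:]) for name in rec["context"])
        gen_shown = tuple(tuple(v) for v in rec["gen_shown"])
        t = build_trial(
            parse_formula(rec["phi1"]),
            parse_formula(rec["phi2"]),
            ctx,
            index=rec["index"],
            group=rec.get("group", doc["group"]),
            gen_shown=gen_shown,
        )
        if [list(v) for v in t.positives] != rec["positives"]:
            raise SchemaError(f"trial {t.index}: stored positives disagree with rules")
        if [list(v) for v in t.negatives] != rec["negatives"]:
            raise SchemaError(f"trial {t.index}: stored negatives disagree with rules")
        trials.append(t)
    icons_doc = doc["icon_assignment"]
    icons = IconAssignment(
        mapping={int(name[1:]): tuple(pair) for name, pair in icons_doc["mapping"].items()},
        seed=icons_doc["seed"],
    )
    plan = ExperimentPlan(group=doc["group"], trials=tuple(trials), seed=doc["seed"])
    return plan, icons


# ---------------------------------------------------------------------------
# responses CSV

def _parse_flag(value) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise ValueError(f"invalid boolean flag {value!r}")


def read_responses(path, plan: ExperimentPlan):
    """Load participant records from a responses CSV, validated against a plan.

    Selections must reference generalization element ids of their trial;
    every participant must cover all six trials.  Malformed rows are
    reported with their (1-based, header-inclusive) row number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"responses CSV missing columns: {missing}")
    known = {t.index: t.gen_shown_ids for t in plan.trials}
    partial: dict = {}
    groups: dict = {}
    for row_idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            trial = int(row.trial)
            if trial not in known:
                raise ValueError(f"unknown trial {trial}")
            sel = frozenset(s for s in str(row.selection).split(";") if s)
            unknown = sel - known[trial]
            if unknown:
                raise ValueError(f"unknown element id(s) {sorted(unknown)}")
            resp = TrialResponse(
                selection=sel,
                learning_time_s=float(row.learning_time_s),
                training_attempts=int(row.training_attempts),
                explanation_text=str(row.explanation_text),
                negative_flag=_parse_flag(row.negative_interpretation_flag),
            )
        except ValueError as exc:
            raise ValueError(f"row {row_idx}: {exc}") from exc
        pid = str(row.participant_id)
        groups.setdefault(pid, str(row.group))
        partial.setdefault(pid, {})[trial] = resp
    records = []
    for pid, responses in partial.items():
        absent = sorted(set(known) - set(responses))
        if absent:
            raise ValueError(f"participant {pid}: missing trial(s) {absent}")
        records.append(ParticipantRecord(id=pid, group=groups[pid], responses=responses))
    return records


def write_responses(records, path) -> None:
    """Write participant records in the standard responses CSV format."""
    rows = []
    for rec in records:
        for trial in sorted(rec.responses):
            resp = rec.responses[trial]
            rows.append(
                {
                    "participant_id": rec.id,
                    "group": rec.group,
                    "trial": trial,
                    "learning_time_s": f"{resp.learning_time_s:.3f}",
                    "training_attempts": resp.training_attempts,
                    "selection": ";".join(sorted(resp.selection)),
                    "explanation_text": resp.explanation_text,
                    "negative_interpretation_flag": resp.negative_flag,
                }
            )
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS).to_csv(path, index=False)
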