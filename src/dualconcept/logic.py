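"""Propositional formulas in negation normal form over binary features.

Concepts are subsets of the valuation space {0,1}^k spanned by an ordered
feature context (p1..p8).  Rules are formulas built from literals with the
binary connectives AND/OR; negation appears only on literals (negation
normal form).  The description-length metric counts literal occurrences
plus AND/OR occurrences — negation is free — so De Morgan rewriting into
NNF never changes a formula's length and NNF is without loss of generality.

Canonical text syntax: atoms ``p1``..``p8``, prefix ``~`` (any
subexpression), infix ``&`` and ``|``, parentheses; precedence
``~ > & > |`` with left association.  The Unicode connectives ``∧ ∨ ¬``
are accepted as input aliases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Iterator, Union

MAX_FEATURES = 8
#: enumeration bound for :func:`models`
MAX_CONTEXT = 16

FeatureId = int
Valuation = tuple  # tuple of 0/1 aligned with a FeatureContext
FeatureContext = tuple  # ordered tuple of FeatureId


@dataclass(frozen=True)
class Lit:
    """A positive or negative occurrence of a feature."""

    feature: FeatureId
    positive: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.feature <= MAX_FEATURES):
            raise ValueError(
                f"feature index {self.feature} outside the alphabet p1..p{MAX_FEATURES}"
            )


@dataclass(frozen=True)
class And:
    left: "Formula"
    right: "Formula"


@dataclass(frozen=True)
class Or:
    left: "Formula"
    right: "Formula"


Formula = Union[Lit, And, Or]


class FormulaSyntaxError(ValueError):
    """Raised on malformed formula text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# parsing / formatting

_TOKEN = re.compile(r"\s*(p\d+|[~&|()])")
_ALIASES = {"∧": "&", "∨": "|", "¬": "~", "&&": "&", "||": "|"}


def _tokenize(text: str) -> list:
    for uni, ascii_ in _ALIASES.items():
        text = text.replace(uni, ascii_)
    tokens, pos = [], 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaSyntaxError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(1), pos))
        pos = m.end()
    tokens.append((None, len(text)))  # sentinel
    return tokens


def parse_formula(text: str) -> Formula:
    """Parse canonical rule text into an NNF :data:`Formula`.

    Negations on non-atomic subexpressions are pushed inward by De Morgan,
    which preserves the length metric.
    """
    tokens = _tokenize(text)
    idx = 0

    def peek():
        return tokens[idx][0]

    def advance():
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or(neg: bool) -> Formula:
        # Under an odd number of enclosing negations the connectives dualize.
        node = parse_and(neg)
        while peek() == "|":
            advance()
            rhs = parse_and(neg)
            node = And(node, rhs) if neg else Or(node, rhs)
        return node

    def parse_and(neg: bool) -> Formula:
        node = parse_unary(neg)
        while peek() == "&":
            advance()
            rhs = parse_unary(neg)
            node = Or(node, rhs) if neg else And(node, rhs)
        return node

    def parse_unary(neg: bool) -> Formula:
        tok, pos = advance()
        if tok == "~":
            return parse_unary(not neg)
        if tok == "(":
            node = parse_or(neg)
            closing, cpos = advance()
            if closing != ")":
                raise FormulaSyntaxError("expected ')'", cpos)
            return node
        if tok is not None and tok.startswith("p"):
            index = int(tok[1:])
            if not (1 <= index <= MAX_FEATURES):
                raise FormulaSyntaxError(f"unknown feature {tok!r}", pos)
            return Lit(index, positive=not neg)
        raise FormulaSyntaxError(
            "expected a feature, '~' or '('" if tok is None else f"unexpected token {tok!r}",
            pos,
        )

    root = parse_or(False)
    tok, pos = tokens[idx]
    if tok is not None:
        raise FormulaSyntaxError(f"unexpected token {tok!r}", pos)
    return root


def _prec(f: Formula) -> int:
    return 3 if isinstance(f, Lit) else (2 if isinstance(f, And) else 1)


def format_formula(f: Formula) -> str:
    """Render a formula so that ``parse_formula`` round-trips structurally.

    Mixed-operator children and right-children of the same operator are
    parenthesized; same-operator left chains print flat (left association).
    """
    if isinstance(f, Lit):
        return ("" if f.positive else "~") + f"p{f.feature}"
    op, p = ("&", 2) if isinstance(f, And) else ("|", 1)
    left, right = format_formula(f.left), format_formula(f.right)
    if _prec(f.left) != 3 and _prec(f.left) != p:
        left = f"({left})"
    if _prec(f.right) != 3:
        right = f"({right})"
    return f"{left} {op} {right}"


# ---------------------------------------------------------------------------
# semantics

def validate_context(ctx: FeatureContext) -> None:
    if len(ctx) == 0:
        raise ValueError("empty feature context")
    if len(set(ctx)) != len(ctx):
        raise ValueError(f"duplicate features in context {ctx}")
    for f in ctx:
        if not (1 <= f <= MAX_FEATURES):
            raise ValueError(f"feature p{f} outside the alphabet")


def eval_formula(f: Formula, v: Valuation, ctx: FeatureContext) -> bool:
    """Standard Boolean semantics of ``f`` at valuation ``v`` over ``ctx``."""
    if len(v) != len(ctx):
        raise ValueError(f"valuation length {len(v)} != context length {len(ctx)}")
    pos = {feat: i for i, feat in enumerate(ctx)}

    def ev(node: Formula) -> bool:
        if isinstance(node, Lit):
            if node.feature not in pos:
                raise ValueError(f"feature p{node.feature} not in context {ctx}")
            bit = bool(v[pos[node.feature]])
            return bit if node.positive else not bit
        if isinstance(node, And):
            return ev(node.left) and ev(node.right)
        return ev(node.left) or ev(node.right)

    return ev(f)


def formula_length(f: Formula) -> int:
    """Literal occurrences plus AND/OR occurrences; negation contributes 0."""
    if isinstance(f, Lit):
        return 1
    return 1 + formula_length(f.left) + formula_length(f.right)


def formula_vars(f: Formula) -> frozenset:
    if isinstance(f, Lit):
        return frozenset({f.feature})
    return formula_vars(f.left) | formula_vars(f.right)


def negate(f: Formula) -> Formula:
    """NNF complement by De Morgan; length-preserving."""
    if isinstance(f, Lit):
        return Lit(f.feature, not f.positive)
    if isinstance(f, And):
        return Or(negate(f.left), negate(f.right))
    return And(negate(f.left), negate(f.right))


def iter_valuations(ctx: FeatureContext) -> Iterator[Valuation]:
    """All valuations of ``ctx`` in coordinate-lexicographic order."""
    return product((0, 1), repeat=len(ctx))


def models(f: Formula, ctx: FeatureContext) -> set:
    """The set of valuations of ``ctx`` satisfying ``f`` (k ≤ 16)."""
    validate_context(ctx)
    if len(ctx) > MAX_CONTEXT:
        raise ValueError(f"context of {len(ctx)} features exceeds enumeration bound")
    if not formula_vars(f) <= frozenset(ctx):
        missing = sorted(formula_vars(f) - frozenset(ctx))
        raise ValueError(f"formula mentions features outside the context: {missing}")
    return {v for v in iter_valuations(ctx) if eval_formula(f, v, ctx)}


def project(v: Valuation, ctx: FeatureContext, subset) -> Valuation:
    """Sub-tuple of ``v`` restricted to ``subset``, in context order."""
    subset = frozenset(subset)
    if not subset <= frozenset(ctx):
        raise ValueError(f"{sorted(subset - frozenset(ctx))} not in context {ctx}")
    return tuple(bit for bit, feat in zip(v, ctx) if feat in subset)


def flip(v: Valuation, ctx: FeatureContext, features) -> Valuation:
    """Complement the coordinates named in ``features``; an involution."""
    features = frozenset(features)
    if not features <= frozenset(ctx):
        raise ValueError(f"{sorted(features - frozenset(ctx))} not in context {ctx}")
    return tuple(1 - bit if feat in features else bit for bit, feat in zip(v, ctx))


def substitute(f: Formula, mapping: dict) -> Formula:
    """Rename features via ``mapping`` (old index → new index)."""
    if isinstance(f, Lit):
        return Lit(mapping.get(f.feature, f.feature), f.positive)
    cls = And if isinstance(f, And) else Or
    return cls(substitute(f.left, mapping), substitute(f.right, mapping))
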