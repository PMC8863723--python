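"""Exact minimal description length of Boolean concepts, with witnesses.

A concept over k features is a truth table — a 2^k-bit mask whose bit i
is the value at the i-th valuation in coordinate-lexicographic order.
The MDL of a concept is the length (literals + AND/OR occurrences,
negation free) of the shortest NNF formula whose table equals the mask.

The engine is a bottom-up dynamic program: every literal seeds its mask
at length 1; for increasing odd target length L = a + b + 1 every pair of
already-minimal functions of lengths a and b is combined under AND (mask
intersection) and OR (mask union), and masks not yet assigned receive
length L.  Because any formula of length L splits into two strictly
shorter subformulas whose masks the DP has already assigned at their own
minimal lengths, the first assignment of a mask is provably its MDL.
All assigned lengths are odd (a binary tree with n leaves has length
2n−1).  Exact mode is limited to k ≤ 4 (65 536 functions); over 3
variables every one of the 256 functions is assigned by length 19, which
is therefore the default cap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .logic import (
    And,
    Formula,
    Lit,
    Or,
    eval_formula,
    format_formula,
    formula_length,
    formula_vars,
    iter_valuations,
    substitute,
)

MAX_EXACT_VARS = 4
DEFAULT_CAP = 19


@dataclass(frozen=True)
class MdlResult:
    """Minimal length of a concept plus one witnessing formula."""

    length: int
    witness: Formula
    exact: bool = True


class UnsupportedConceptError(ValueError):
    """Concept support exceeds the exact-mode bound of 4 variables."""


def mask_of(f: Formula, ctx) -> int:
    """Truth-table mask of ``f`` over ``ctx`` (bit i = i-th valuation)."""
    mask = 0
    for i, v in enumerate(iter_valuations(ctx)):
        if eval_formula(f, v, ctx):
            mask |= 1 << i
    return mask


class _DpState:
    """Incremental per-k DP state, extendable to larger length caps."""

    def __init__(self, k: int):
        self.k = k
        self.cap = 1
        self.assigned: dict = {}  # mask -> (length, witness)
        self.buckets: dict = {1: {}}  # length -> {mask: witness}, newly assigned
        candidates: dict = {}
        for var in range(1, k + 1):
            for positive in (True, False):
                lit = Lit(var, positive)
                self._offer(candidates, mask_of(lit, tuple(range(1, k + 1))), lit)
        self._commit(candidates, 1)

    def _offer(self, candidates: dict, mask: int, witness: Formula) -> None:
        if mask in self.assigned:
            return
        key = format_formula(witness)
        prev = candidates.get(mask)
        if prev is None or key < prev[0]:
            candidates[mask] = (key, witness)

    def _commit(self, candidates: dict, length: int) -> None:
        bucket = {}
        for mask, (_, witness) in candidates.items():
            self.assigned[mask] = (length, witness)
            bucket[mask] = witness
        self.buckets[length] = bucket

    def extend(self, cap: int) -> None:
        total = 1 << (1 << self.k)
        while self.cap < cap and len(self.assigned) < total:
            length = self.cap + 2
            candidates: dict = {}
            for a in range(1, length - 1, 2):
                b = length - 1 - a
                if b < a:
                    break
                for m1, f1 in self.buckets.get(a, {}).items():
                    for m2, f2 in self.buckets.get(b, {}).items():
                        for mask, w1, w2 in (
                            (m1 & m2, And(f1, f2), And(f2, f1)),
                            (m1 | m2, Or(f1, f2), Or(f2, f1)),
                        ):
                            self._offer(candidates, mask, w1)
                            self._offer(candidates, mask, w2)
            self._commit(candidates, length)
            self.cap = length


_STATES: dict = {}


def _state(k: int) -> _DpState:
    if not (1 <= k <= MAX_EXACT_VARS):
        raise UnsupportedConceptError(
            f"exact MDL supports 1..{MAX_EXACT_VARS} variables, got {k}"
        )
    if k not in _STATES:
        _STATES[k] = _DpState(k)
    return _STATES[k]


def mdl_all(k: int, length_cap: int = DEFAULT_CAP) -> dict:
    """MDL table for all assigned masks over ``k`` variables up to the cap.

    Returns ``{mask: MdlResult}``.  Masks whose shortest formula exceeds
    ``length_cap`` are absent.  Witness tie-breaking is lexicographic on
    the formatted formula string, so the table is deterministic.
    """
    if length_cap < 1:
        raise ValueError("length_cap must be >= 1")
    state = _state(k)
    state.extend(length_cap)
    return {
        mask: MdlResult(length, witness)
        for mask, (length, witness) in state.assigned.items()
        if length <= length_cap
    }


def mdl_of(f: Formula) -> MdlResult:
    """Exact MDL of the concept defined by ``f`` over its support variables.

    The witness is expressed over the original feature indices and its
    truth table equals ``f``'s; ``result.length <= formula_length(f)``.
    """
    support = tuple(sorted(formula_vars(f)))
    k = len(support)
    state = _state(k)
    # Evaluate f over its own support: position i holds feature support[i].
    mask = mask_of(f, support)
    state.extend(formula_length(f))
    length, witness = state.assigned[mask]
    remap = {i + 1: feat for i, feat in enumerate(support)}
    return MdlResult(length, substitute(witness, remap))


def is_minimal(f: Formula) -> bool:
    """True iff ``f`` is a shortest formula for its own concept."""
    return formula_length(f) == mdl_of(f).length
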