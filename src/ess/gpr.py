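"""Gene-protein-reaction (GPR) boolean logic.

A GPR rule is a negation-free boolean expression over gene identifiers with
AND/OR connectives. A reaction is available iff its rule evaluates true with
deleted genes assigned false and all other genes true. Because the expressions
are monotone, every rule has a unique minimal disjunctive normal form whose
disjuncts are the minimal gene sets sufficient to keep the reaction active;
:meth:`GPRRule.to_dnf` computes it and is the basis of the model-level logical
transformation used before gene-level lethality enumeration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Set, Tuple, Union

__all__ = ["GPRRule", "GPRParseError", "parse_gpr", "evaluate_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


# Expression tree: a gene id (str) or an ("and"|"or", (children...)) node.
Expr = Union[str, Tuple[str, Tuple["Expr", ...]]]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN.findall(text)


class _Parser:
    """Recursive-descent parser for ``a and (b or c)`` style rules."""

    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {self.source!r}")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise GPRParseError(
                f"trailing token {self.peek()!r} in GPR rule: {self.source!r}"
            )
        return expr

    def parse_or(self) -> Expr:
        parts = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() in ("or", "|"):
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else ("or", tuple(parts))

    def parse_and(self) -> Expr:
        parts = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() in ("and", "&"):
            self.next()
            parts.append(self.parse_atom())
        return parts[0] if len(parts) == 1 else ("and", tuple(parts))

    def parse_atom(self) -> Expr:
        tok = self.next()
        if tok == "(":
            inner = self.parse_or()
            if self.next() != ")":
                raise GPRParseError(f"unbalanced parentheses in {self.source!r}")
            return inner
        if tok == ")" or tok.lower() in ("and", "or", "&", "|"):
            raise GPRParseError(
                f"unexpected token {tok!r} in GPR rule: {self.source!r}"
            )
        return tok


def _expr_genes(expr: Expr, acc: Set[str]) -> None:
    if isinstance(expr, str):
        acc.add(expr)
    else:
        for child in expr[1]:
            _expr_genes(child, acc)


def _expr_eval(expr: Expr, deleted: Set[str]) -> bool:
    if isinstance(expr, str):
        return expr not in deleted
    op, children = expr
    if op == "and":
        return all(_expr_eval(c, deleted) for c in children)
    return any(_expr_eval(c, deleted) for c in children)


def _expr_dnf(expr: Expr) -> FrozenSet[FrozenSet[str]]:
    if isinstance(expr, str):
        return frozenset([frozenset([expr])])
    op, children = expr
    child_dnfs = [_expr_dnf(c) for c in children]
    if op == "or":
        disjuncts: Set[FrozenSet[str]] = set()
        for d in child_dnfs:
            disjuncts |= d
    else:  # and: cross-product union of disjuncts
        disjuncts = {frozenset()}
        for d in child_dnfs:
            disjuncts = {a | b for a in disjuncts for b in d}
    return _prune_supersets(disjuncts)


def _prune_supersets(disjuncts: Iterable[FrozenSet[str]]) -> FrozenSet[FrozenSet[str]]:
    # For monotone boolean expressions the minimal (prime-implicant) DNF is
    # obtained by dropping every disjunct that contains another disjunct.
    items = sorted(set(disjuncts), key=lambda s: (len(s), sorted(s)))
    kept: list[FrozenSet[str]] = []
    for s in items:
        if not any(k <= s for k in kept):
            kept.append(s)
    return frozenset(kept)


def _expr_str(expr: Expr, parent: str | None = None) -> str:
    if isinstance(expr, str):
        return expr
    op, children = expr
    joined = f" {op} ".join(_expr_str(c, op) for c in children)
    if parent is not None and parent != op:
        return f"({joined})"
    return joined


@dataclass(frozen=True)
class GPRRule:
    """A parsed GPR expression.

    Instances are immutable; build them with :func:`parse_gpr` or
    :meth:`from_dnf`.
    """

    expr: Expr

    @property
    def genes(self) -> FrozenSet[str]:
        acc: Set[str] = set()
        _expr_genes(self.expr, acc)
        return frozenset(acc)

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """True iff the reaction stays active when ``deleted_genes`` are lost."""
        return _expr_eval(self.expr, set(deleted_genes))

    def to_dnf(self) -> FrozenSet[FrozenSet[str]]:
        """Minimal DNF as a set of minimal sufficient gene sets."""
        return _expr_dnf(self.expr)

    @classmethod
    def from_dnf(cls, disjuncts: Iterable[Iterable[str]]) -> "GPRRule":
        sets = _prune_supersets(frozenset(map(frozenset, disjuncts)))
        if not sets:
            raise GPRParseError("cannot build a GPR rule from an empty DNF")
        terms: list[Expr] = []
        for s in sorted(sets, key=lambda s: (len(s), sorted(s))):
            genes = sorted(s)
            terms.append(genes[0] if len(genes) == 1 else ("and", tuple(genes)))
        expr: Expr = terms[0] if len(terms) == 1 else ("or", tuple(terms))
        return cls(expr)

    def transformed(self) -> "GPRRule":
        """Equivalent rule in canonical minimal DNF."""
        return GPRRule.from_dnf(self.to_dnf())

    def __str__(self) -> str:
        return _expr_str(self.expr)


def parse_gpr(text: str) -> GPRRule | None:
    """Parse a GPR string; empty/whitespace strings mean "no rule" (None)."""
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    return GPRRule(_Parser(tokens, text).parse())


def evaluate_gpr(rule: GPRRule | None, deleted_genes: Iterable[str]) -> bool:
    """Availability of a reaction under a gene deletion set.

    Reactions without a rule are never disabled by gene deletion.
    """
    if rule is None:
        return True
    return rule.evaluate(deleted_genes)
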