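"""Gene–protein–reaction (GPR) boolean rules.

A GPR links genes to the availability of a reaction: leaves are gene ids,
internal nodes are AND (all subunits required, e.g. a complex) or OR
(isoenzymes). An empty rule means the reaction has no known gene
association and is never silenced by gene deletion.

Rules are parsed from the conventional string syntax with parentheses and
the (case-insensitive) keywords ``and`` / ``or``, e.g.
``"(YGR240C or YMR205C) and YIL107C"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator

__all__ = ["Gpr", "GprParseError", "parse_gpr"]


class GprParseError(ValueError):
    """Raised when a GPR rule string cannot be parsed."""


@dataclass(frozen=True)
class Gpr:
    """A node of a GPR tree.

    ``op`` is ``"and"`` or ``"or"`` for internal nodes (with ≥2 children),
    or ``None`` for a leaf, in which case ``gene`` holds the gene id.
    """

    op: str | None = None
    children: tuple["Gpr", ...] = ()
    gene: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.op is None

    def genes(self) -> frozenset[str]:
        """All gene ids appearing as leaves."""
        if self.is_leaf:
            return frozenset({self.gene})
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, gene_state: Callable[[str], bool]) -> bool:
        """Evaluate the rule with per-gene truth values."""
        if self.is_leaf:
            return bool(gene_state(self.gene))
        vals = (c.evaluate(gene_state) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def active_after_deletion(self, deleted: set[str] | frozenset[str]) -> bool:
        """True if the reaction stays available when ``deleted`` genes are removed."""
        return self.evaluate(lambda g: g not in deleted)

    def fold(self, values: dict[str, float], missing: float) -> float:
        """Map gene-level scores to a reaction-level score.

        AND nodes take the minimum of their children (a complex is only as
        available as its scarcest subunit); OR nodes take the maximum
        (any isoenzyme suffices). Genes absent from ``values`` contribute
        ``missing``.
        """
        if self.is_leaf:
            return values.get(self.gene, missing)
        child = [c.fold(values, missing) for c in self.children]
        return min(child) if self.op == "and" else max(child)

    def to_string(self) -> str:
        if self.is_leaf:
            return self.gene
        sep = f" {self.op} "
        return "(" + sep.join(c.to_string() for c in self.children) + ")"

    def truth_table(self) -> tuple[tuple[str, ...], frozenset[int]]:
        """Canonical truth table: (sorted genes, set of satisfying rows).

        Row ``i`` assigns gene ``j`` TRUE iff bit ``j`` of ``i`` is set.
        Used for semantic equality of rules; intended for rules with a
        modest number of genes (real GPRs rarely exceed a dozen).
        """
        genes = tuple(sorted(self.genes()))
        if len(genes) > 20:
            raise ValueError(f"truth table over {len(genes)} genes is too large")
        idx = {g: j for j, g in enumerate(genes)}
        rows = frozenset(
            i for i in range(1 << len(genes))
            if self.evaluate(lambda g: bool(i >> idx[g] & 1))
        )
        return genes, rows

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN = re.compile(r"\s*(\(|\)|[Aa][Nn][Dd]\b|[Oo][Rr]\b|[^\s()]+)")


def _tokenize(rule: str) -> Iterator[str]:
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        pos = m.end()
        yield m.group(1)


def parse_gpr(rule: str | None) -> Gpr | None:
    """Parse a rule string into a :class:`Gpr` tree; empty input gives ``None``.

    Grammar (standard precedence, AND binds tighter than OR)::

        expr    := term ("or" term)*
        term    := factor ("and" factor)*
        factor  := gene | "(" expr ")"
    """
    if rule is None or not rule.strip():
        return None
    tokens = list(_tokenize(rule))
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def expr() -> Gpr:
        node = term()
        parts = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            parts.append(term())
        if len(parts) == 1:
            return node
        return Gpr(op="or", children=tuple(parts))

    def term() -> Gpr:
        node = factor()
        parts = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            parts.append(factor())
        if len(parts) == 1:
            return node
        return Gpr(op="and", children=tuple(parts))

    def factor() -> Gpr:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise GprParseError(f"missing ')' in rule: {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected {tok!r} in rule: {rule!r}")
        return Gpr(gene=take())

    node = expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in rule: {rule!r}")
    return node
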