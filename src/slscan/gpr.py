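"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which genes must be present for a reaction's enzyme to be
available: ``and`` joins subunits of a complex, ``or`` joins isozymes.  Rules
are parsed into an explicit boolean tree so they can be evaluated under gene
knockouts and mapped to expression values (AND -> min, OR -> max).

Gene identifiers are opaque strings; in particular numeric
"entrez.transcript" ids such as ``"1234.1"`` pass through unmodified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Optional, Set, Union


class GprParseError(ValueError):
    """Raised for malformed GPR text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class GeneLeaf:
    gene: str

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene identifier must be non-empty")


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple  # of GprNode

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown boolean operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("boolean node needs at least two children")


GprNode = Union[GeneLeaf, BoolOp]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str):
    for m in _TOKEN_RE.finditer(text):
        tok = m.group(0)
        low = tok.lower()
        if tok == "(" or tok == ")":
            yield tok, m.start()
        elif low in ("and", "or"):
            yield low, m.start()
        else:
            yield ("gene", tok), m.start()


@dataclass(frozen=True)
class GprExpression:
    """Boolean expression tree over gene ids; ``root is None`` means
    "always active" (a reaction with no gene requirement)."""

    root: Optional[GprNode] = None
    source: str = ""

    @property
    def always_active(self) -> bool:
        return self.root is None

    def genes(self) -> Set[str]:
        out: Set[str] = set()

        def walk(node: GprNode) -> None:
            if isinstance(node, GeneLeaf):
                out.add(node.gene)
            else:
                for c in node.children:
                    walk(c)

        if self.root is not None:
            walk(self.root)
        return out

    def evaluate(self, knocked_out: Set[str]) -> bool:
        """True iff the reaction remains catalysable with ``knocked_out``
        genes removed.  A leaf is true iff its gene is not knocked out."""
        if self.root is None:
            return True

        def ev(node: GprNode) -> bool:
            if isinstance(node, GeneLeaf):
                return node.gene not in knocked_out
            vals = (ev(c) for c in node.children)
            return all(vals) if node.op == "and" else any(vals)

        return ev(self.root)

    def aggregate(self, values: Mapping[str, float], missing: float) -> float:
        """Map gene-level values to a reaction-level value: AND -> min,
        OR -> max.  Genes absent from ``values`` contribute ``missing``."""
        if self.root is None:
            raise ValueError("cannot aggregate an always-active expression")

        def ag(node: GprNode) -> float:
            if isinstance(node, GeneLeaf):
                return values.get(node.gene, missing)
            agg = min if node.op == "and" else max
            return agg(ag(c) for c in node.children)

        return ag(self.root)

    def to_string(self) -> str:
        """Canonical textual form; re-parsing it yields an equal tree."""
        if self.root is None:
            return ""

        def fmt(node: GprNode, parent_op: Optional[str]) -> str:
            if isinstance(node, GeneLeaf):
                return node.gene
            inner = f" {node.op} ".join(fmt(c, node.op) for c in node.children)
            # OR nested under AND needs parentheses; same-op nesting does not.
            if parent_op == "and" and node.op == "or":
                return f"({inner})"
            return inner

        return fmt(self.root, None)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR rule string ("g1 and (g2 or g3)") into a boolean tree.

    Blank or empty text yields the distinguished always-active expression.
    ``or`` binds more loosely than ``and``; both are case-insensitive.
    Raises :class:`GprParseError` naming the offending offset.
    """
    if text is None or not text.strip():
        return GprExpression(root=None, source=text or "")

    tokens = list(_tokenize(text))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, len(text))

    def parse_or() -> GprNode:
        nonlocal pos
        parts = [parse_and()]
        while peek()[0] == "or":
            pos += 1
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else BoolOp("or", tuple(parts))

    def parse_and() -> GprNode:
        nonlocal pos
        parts = [parse_atom()]
        while peek()[0] == "and":
            pos += 1
            parts.append(parse_atom())
        return parts[0] if len(parts) == 1 else BoolOp("and", tuple(parts))

    def parse_atom() -> GprNode:
        nonlocal pos
        tok, off = peek()
        if tok == "(":
            pos += 1
            node = parse_or()
            tok2, off2 = peek()
            if tok2 != ")":
                raise GprParseError("unbalanced parenthesis: expected ')'", off2)
            pos += 1
            return node
        if isinstance(tok, tuple) and tok[0] == "gene":
            pos += 1
            return GeneLeaf(tok[1])
        if tok is None:
            raise GprParseError("unexpected end of rule", off)
        raise GprParseError(f"unexpected token {tok!r}", off)

    root = parse_or()
    tok, off = peek()
    if tok is not None:
        raise GprParseError(f"stray token {tok!r} after expression", off)
    return GprExpression(root=root, source=text)


def evaluate_gpr(expr: GprExpression, knocked_out: Set[str]) -> bool:
    """Functional form of :meth:`GprExpression.evaluate`."""
    return expr.evaluate(knocked_out)
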