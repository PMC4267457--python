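"""Gene-protein-reaction (GPR) boolean expressions.

A GPR is a boolean tree over gene identifiers that says which gene products
must be present for a reaction to carry flux: ``(g1 and g2) or g3`` means the
reaction is catalysed either by the g1/g2 complex or by the g3 isozyme.
Deleting a gene set disables every reaction whose GPR evaluates false with
those genes absent.

The grammar is the COBRA notes-field convention: case-insensitive ``and`` /
``or`` keywords, parentheses, and gene tokens as maximal runs of characters
that are neither whitespace nor parentheses.  ``and`` binds tighter than
``or``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import FormatError

__all__ = ["Gpr", "Gene", "And", "Or", "parse_gpr"]


class Gpr:
    """Abstract GPR node. Concrete nodes: :class:`Gene`, :class:`And`, :class:`Or`."""

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> set[str]:
        return set(self._iter_genes())

    def _iter_genes(self) -> Iterator[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self.to_string()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Gpr) and self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


@dataclass(frozen=True, eq=False)
class Gene(Gpr):
    id: str

    def evaluate(self, deleted):
        return self.id not in deleted

    def _iter_genes(self):
        yield self.id

    def to_string(self):
        return self.id


@dataclass(frozen=True, eq=False)
class And(Gpr):
    children: tuple[Gpr, ...]

    def evaluate(self, deleted):
        return all(c.evaluate(deleted) for c in self.children)

    def _iter_genes(self):
        for c in self.children:
            yield from c._iter_genes()

    def to_string(self):
        return " and ".join(
            f"({c})" if isinstance(c, Or) else str(c) for c in self.children
        )


@dataclass(frozen=True, eq=False)
class Or(Gpr):
    children: tuple[Gpr, ...]

    def evaluate(self, deleted):
        return any(c.evaluate(deleted) for c in self.children)

    def _iter_genes(self):
        for c in self.children:
            yield from c._iter_genes()

    def to_string(self):
        return " or ".join(
            f"({c})" if isinstance(c, And) else str(c) for c in self.children
        )


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch in "()":
            if buf:
                tokens.append("".join(buf))
                buf = []
            tokens.append(ch)
        elif ch.isspace():
            if buf:
                tokens.append("".join(buf))
                buf = []
        else:
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


class _Parser:
    # precedence: or < and < atom
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise FormatError(f"unexpected end of GPR expression: {self.source!r}")
        self.pos += 1
        return tok

    def parse_or(self) -> Gpr:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Gpr:
        factors = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom(self) -> Gpr:
        tok = self.next()
        if tok == "(":
            node = self.parse_or()
            closing = self.next()
            if closing != ")":
                raise FormatError(f"expected ')' in GPR expression: {self.source!r}")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise FormatError(f"unexpected token {tok!r} in GPR expression: {self.source!r}")
        return Gene(tok)


def parse_gpr(text: str | None) -> Gpr | None:
    """Parse a GPR string; empty/whitespace/``None`` means no gene association."""
    if text is None:
        return None
    tokens = _tokenize(text)
    if not tokens:
        return None
    parser = _Parser(tokens, text)
    node = parser.parse_or()
    if parser.peek() is not None:
        raise FormatError(f"trailing tokens in GPR expression: {text!r}")
    return node
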