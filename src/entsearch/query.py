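"""Query parsing: Boolean operators, phrases, boosts, year filter.

The raw query string is lexed with the index tokenizer so query terms and
index keys always agree.  Supported syntax::

    imatinib resistance          bare terms (implicit OR for retrieval)
    resistant AND imatinib       Boolean operators AND / OR / NOT (uppercase)
    "chronic myeloid leukemia"   quoted phrase (one query element)
    imatinib^3                   term boost
    year:[1990 TO 2005]          inclusive year range; * opens an end
    year:[*—2005]                em/en dash accepted as the separator

Stop words (a fixed 33-word English list, e.g. "to", "the", "of") are
removed from bare term leaves at parse time only — the index keeps them.
A query whose positive leaves are all stop words is rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence, Union

from ._text import tokenize

if TYPE_CHECKING:  # pragma: no cover
    from .index import DocumentRecord, InvertedIndex

#: the classic 33-word English stop list used by Lucene-style engines
STOP_WORDS = frozenset(
    "a an and are as at be but by for if in into is it no not of on or "
    "such that the their then there these they this to was will with".split()
)


class QueryParseError(ValueError):
    pass


class EmptyQueryError(QueryParseError):
    """The query reduced to zero positive terms."""


@dataclass(frozen=True)
class Term:
    text: str
    boost: float = 1.0

    def key(self) -> tuple:
        return ("term", self.text)


@dataclass(frozen=True)
class Phrase:
    tokens: tuple[str, ...]
    boost: float = 1.0

    def key(self) -> tuple:
        return ("phrase", self.tokens)


@dataclass(frozen=True)
class Not:
    child: "Node"


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


Node = Union[Term, Phrase, Not, And, Or]


@dataclass(frozen=True)
class QueryAST:
    """Parsed query: Boolean tree, optional year filter and type filter.

    ``positive_leaves`` are the distinct non-negated leaves; their count is
    |q|, the denominator of the coordination factor.
    """

    root: Node
    year_filter: tuple[int | None, int | None] | None = None
    type_filter: str | None = None

    @property
    def positive_leaves(self) -> tuple[Node, ...]:
        seen: dict[tuple, Node] = {}
        for leaf in _positive_leaves(self.root):
            seen.setdefault(leaf.key(), leaf)
        return tuple(seen.values())

    @property
    def n_elements(self) -> int:
        return len(self.positive_leaves)

    def format(self) -> str:
        """Canonical serialization; ``parse_query(format())`` round-trips."""
        s = _format(self.root)
        if self.year_filter is not None:
            lo, hi = self.year_filter
            s += " AND (year:[%s TO %s])" % (
                "*" if lo is None else lo, "*" if hi is None else hi)
        return s


def _positive_leaves(node: Node) -> Iterable[Union[Term, Phrase]]:
    if isinstance(node, (Term, Phrase)):
        yield node
    elif isinstance(node, (And, Or)):
        for c in node.children:
            yield from _positive_leaves(c)
    # Not subtrees contribute nothing positive


def _format(node: Node) -> str:
    if isinstance(node, Term):
        return node.text + (f"^{node.boost:g}" if node.boost != 1.0 else "")
    if isinstance(node, Phrase):
        s = '"%s"' % " ".join(node.tokens)
        return s + (f"^{node.boost:g}" if node.boost != 1.0 else "")
    if isinstance(node, Not):
        return "NOT (%s)" % _format(node.child)
    op = " AND " if isinstance(node, And) else " OR "
    return "(" + op.join(_format(c) for c in node.children) + ")"


# -- lexer ------------------------------------------------------------------

_YEAR_RE = re.compile(
    r"year:\[\s*(\*|\d{1,4})\s*(?:TO|—|–|-)\s*(\*|\d{1,4})\s*\]",
    re.IGNORECASE,
)
_YEARISH_RE = re.compile(r"year:\S*")
_LEX_RE = re.compile(
    r"""\(|\)|"(?P<phrase>[^"]*)"(?:\^(?P<pboost>\d+(?:\.\d+)?))?"""
    r"""|(?P<yr>year:\[[^\]]*\])"""
    r"""|(?P<word>[^\s()"]+)""",
)


def _lex(raw: str) -> list[tuple[str, object]]:
    tokens: list[tuple[str, object]] = []
    for m in _LEX_RE.finditer(raw):
        tok = m.group()
        if tok == "(":
            tokens.append(("LP", None))
        elif tok == ")":
            tokens.append(("RP", None))
        elif m.group("phrase") is not None:
            boost = float(m.group("pboost")) if m.group("pboost") else 1.0
            tokens.append(("PHRASE", (m.group("phrase"), boost)))
        elif m.group("yr") is not None:
            tokens.append(("YEAR", _parse_year(m.group("yr"))))
        else:
            word = m.group("word")
            if word in ("AND", "OR", "NOT"):
                tokens.append((word, None))
                continue
            if _YEARISH_RE.fullmatch(word):
                raise QueryParseError(f"malformed year range: {word!r}")
            boost = 1.0
            if "^" in word:
                word, _, bs = word.partition("^")
                try:
                    boost = float(bs)
                except ValueError:
                    raise QueryParseError(f"malformed boost: {bs!r}") from None
                if boost <= 0:
                    raise QueryParseError(f"boost must be positive: {bs!r}")
            for t in tokenize(word):
                tokens.append(("WORD", (t, boost)))
    return tokens


def _parse_year(fragment: str) -> tuple[int | None, int | None]:
    m = _YEAR_RE.fullmatch(fragment)
    if not m:
        raise QueryParseError(f"malformed year range: {fragment!r}")
    lo = None if m.group(1) == "*" else int(m.group(1))
    hi = None if m.group(2) == "*" else int(m.group(2))
    if lo is not None and hi is not None and lo > hi:
        raise QueryParseError(f"year range lower bound exceeds upper: {fragment!r}")
    return lo, hi


# -- parser -----------------------------------------------------------------


class _Parser:
    """Recursive descent; precedence NOT > AND > implicit/OR."""

    def __init__(self, tokens: list[tuple[str, object]]):
        self.tokens = tokens
        self.pos = 0
        self.year_filter: tuple[int | None, int | None] | None = None

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, object]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Node | None:
        node = self.or_expr()
        if self.peek() is not None:
            raise QueryParseError("unbalanced parentheses in query")
        return node

    def or_expr(self) -> Node | None:
        children = []
        left = self.and_expr()
        if left is not None:
            children.append(left)
        while self.peek() == "OR":
            self.take()
            right = self.and_expr()
            if right is not None:
                children.append(right)
        if not children:
            return None
        return children[0] if len(children) == 1 else Or(tuple(children))

    def and_expr(self) -> Node | None:
        children = []
        explicit_and = False
        while True:
            if self.peek() == "AND":
                self.take()
                explicit_and = True
                continue
            node = self.unary()
            if node is _SKIPPED:
                continue
            if node is None:
                break
            children.append(node)
        if not children:
            return None
        if len(children) == 1:
            return children[0]
        if explicit_and:
            return And(tuple(children))
        # bare adjacency is OR-of-terms for retrieval, but NOT children
        # still subtract (Lucene-style "a NOT b" == a AND NOT b)
        positives = tuple(c for c in children if not isinstance(c, Not))
        negatives = tuple(c for c in children if isinstance(c, Not))
        if not negatives:
            return Or(children=tuple(children))
        if not positives:
            return And(tuple(children))
        pos = positives[0] if len(positives) == 1 else Or(positives)
        return And((pos,) + negatives)

    def unary(self) -> Node | None:
        kind = self.peek()
        if kind == "NOT":
            self.take()
            # NOT binds to the next atom only; NOT over a removed leaf
            # (stop word, year filter) dissolves without consuming more
            child = self.unary() if self.peek() == "NOT" else self.atom()
            if child is _SKIPPED:
                return _SKIPPED
            if child is None:
                raise QueryParseError("NOT lacks an operand")
            return Not(child)
        return self.atom()

    def atom(self):
        kind = self.peek()
        if kind == "LP":
            self.take()
            node = self.or_expr()
            if self.peek() != "RP":
                raise QueryParseError("unbalanced parentheses in query")
            self.take()
            return node if node is not None else _SKIPPED
        if kind == "WORD":
            _, (text, boost) = self.take()
            if text in STOP_WORDS:
                return _SKIPPED
            return Term(text, boost)
        if kind == "PHRASE":
            _, (text, boost) = self.take()
            toks = tuple(tokenize(text))
            if not toks:
                return _SKIPPED
            if len(toks) == 1:
                return Term(toks[0], boost)
            return Phrase(toks, boost)
        if kind == "YEAR":
            _, yr = self.take()
            if self.year_filter is not None and self.year_filter != yr:
                raise QueryParseError("multiple conflicting year filters")
            self.year_filter = yr
            return _SKIPPED
        return None


_SKIPPED = object()  # sentinel for removed leaves (stop words, year filter)


def parse_query(raw: str, type_filter: str | None = None) -> QueryAST:
    """Parse a raw query string into a :class:`QueryAST`.

    Raises :class:`EmptyQueryError` when no positive searchable leaf
    survives stop-word removal, and :class:`QueryParseError` on malformed
    syntax (naming the offending fragment).
    """
    if not raw or not raw.strip():
        raise EmptyQueryError("empty query string")
    parser = _Parser(_lex(raw))
    root = parser.parse()
    if root is None:
        raise EmptyQueryError(
            "query contains no searchable terms (all stop words or filters)"
        )
    ast = QueryAST(root=root, year_filter=parser.year_filter,
                   type_filter=type_filter)
    if not ast.positive_leaves:
        raise EmptyQueryError("query has no positive (non-negated) terms")
    return ast


# -- retrieval --------------------------------------------------------------


def match_documents(ast: QueryAST, index: "InvertedIndex") -> set[str]:
    """Doc ids satisfying the Boolean tree and the year filter."""
    universe = set(index.documents)
    docs = _eval(ast.root, index, universe)
    if ast.year_filter is not None:
        kept = apply_year_filter(
            (index.documents[d] for d in docs), ast.year_filter
        )
        docs = {d.doc_id for d in kept}
    return docs


def _eval(node: Node, index: "InvertedIndex", universe: set[str]) -> set[str]:
    if isinstance(node, Term):
        return set(index.term_docs.get(node.text, ()))
    if isinstance(node, Phrase):
        return index.phrase_docs(node.tokens)
    if isinstance(node, Not):
        return universe - _eval(node.child, index, universe)
    sets = [_eval(c, index, universe) for c in node.children]
    if isinstance(node, And):
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    return set().union(*sets)


def apply_year_filter(
    docs: Iterable["DocumentRecord"],
    year_filter: tuple[int | None, int | None] | None,
) -> list["DocumentRecord"]:
    """Keep documents whose pub_year lies in the inclusive range.

    With an active filter, documents lacking a year are excluded; with no
    filter this is the identity.
    """
    docs = list(docs)
    if year_filter is None:
        return docs
    lo, hi = year_filter
    out = []
    for d in docs:
        if d.pub_year is None:
            continue
        if lo is not None and d.pub_year < lo:
            continue
        if hi is not None and d.pub_year > hi:
            continue
        out.append(d)
    return out
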