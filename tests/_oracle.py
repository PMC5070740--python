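"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's index/matcher data paths: matching
is done by exhaustive substring enumeration, statistics by linear rescans
of raw document text, and ranking by re-deriving every quantity from first
principles.  They are only meant for small inputs.
"""

from __future__ import annotations

import math
import re

from entsearch.dictionary import Dictionary, extract_mutations
from entsearch.index import DocumentRecord
from entsearch.query import And, Not, Or, Phrase, QueryAST, Term

_WORD = re.compile(r"[0-9A-Za-z]+(?:-[0-9A-Za-z]+)*")


def oracle_tokens(text: str) -> list[str]:
    return [m.group().lower() for m in _WORD.finditer(text)]


def oracle_match_spans(text: str, dictionary: Dictionary):
    """All candidate dictionary matches by exhaustive substring enumeration
    over every token-boundary-delimited slice, then greedy leftmost-longest
    selection."""
    spans = [(m.start(), m.end()) for m in _WORD.finditer(text)]
    # exhaustive: every (i, j) token window
    candidates = []
    for i in range(len(spans)):
        for j in range(i, len(spans)):
            a, b = spans[i][0], spans[j][1]
            slice_ = text[a:b]
            cid = _lookup(slice_, dictionary)
            if cid is not None:
                candidates.append((a, b, cid))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    picked = []
    last = -1
    for a, b, cid in candidates:
        if a >= last:
            picked.append((a, b, cid))
            last = b
    return picked


def _lookup(surface: str, dictionary: Dictionary) -> str | None:
    """Name lookup honouring the short-all-uppercase case rule, but by
    scanning every concept's name list rather than the built index."""
    best = None
    toks = tuple(t.lower() for t in
                 (m.group() for m in _WORD.finditer(surface)))
    for cid in sorted(dictionary.concepts):
        for name in sorted(dictionary.concepts[cid].names):
            name_toks = tuple(m.group() for m in _WORD.finditer(name))
            if not name_toks:
                continue
            if name.isupper() and len(name) <= 4:
                raw = tuple(m.group() for m in _WORD.finditer(surface))
                if raw == name_toks:
                    best = _prefer(best, cid, dictionary)
            else:
                if toks == tuple(t.lower() for t in name_toks):
                    best = _prefer(best, cid, dictionary)
    return best


def _prefer(best, cid, dictionary):
    from entsearch.dictionary import GROUP_PRIORITY
    if best is None:
        return cid
    ka = (GROUP_PRIORITY[dictionary.concepts[best].group], best)
    kb = (GROUP_PRIORITY[dictionary.concepts[cid].group], cid)
    return best if ka <= kb else cid


def oracle_rank(
    docs: list[DocumentRecord],
    dictionary: Dictionary,
    ast: QueryAST,
    powers=(1.0, 1.0, 1.0, 1.0),
    reference_month: int | None = None,
    k: int = 10,
):
    """Re-derive the entity ranking from raw documents.

    Returns [(concept_id, score)] sorted by the same tie-break contract as
    the engine (score desc, doc count desc, concept_id asc).
    """
    pt, pn, pq, pr = powers
    tokens = {d.doc_id: oracle_tokens(d.text) for d in docs}
    entities = {}
    for d in docs:
        ments = oracle_match_spans(d.text, dictionary)
        mut = [(m.start, m.end, m.concept_id) for m in extract_mutations(d.text)]
        allm = sorted(set(ments) | set(mut), key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
        picked, last = [], -1
        for a, b, cid in allm:
            if a >= last:
                picked.append(cid)
                last = b
        ordered = []
        for cid in picked:
            if cid not in ordered:
                ordered.append(cid)
        entities[d.doc_id] = ordered

    if reference_month is None:
        months = [d.pub_year * 12 + (d.pub_month or 1)
                  for d in docs if d.pub_year is not None]
        reference_month = max(months) if months else 0
    max_if = max([d.impact_factor for d in docs
                  if d.impact_factor is not None] or [0.0])
    n_docs = len(docs)

    def leaf_tf(leaf, toks):
        if isinstance(leaf, Term):
            return toks.count(leaf.text)
        w = list(leaf.tokens)
        return sum(1 for i in range(len(toks) - len(w) + 1)
                   if toks[i:i + len(w)] == w)

    def docset(node):
        if isinstance(node, (Term, Phrase)):
            return {d.doc_id for d in docs if leaf_tf(node, tokens[d.doc_id]) > 0}
        if isinstance(node, Not):
            return {d.doc_id for d in docs} - docset(node.child)
        sets = [docset(c) for c in node.children]
        if isinstance(node, And):
            out = sets[0]
            for s in sets[1:]:
                out &= s
            return out
        return set().union(*sets)

    cand = docset(ast.root)
    if ast.year_filter is not None:
        lo, hi = ast.year_filter
        cand = {
            did for did in cand
            for d in [next(x for x in docs if x.doc_id == did)]
            if d.pub_year is not None
            and (lo is None or d.pub_year >= lo)
            and (hi is None or d.pub_year <= hi)
        }

    scores: dict[str, float] = {}
    ndocs: dict[str, int] = {}
    by_id = {d.doc_id: d for d in docs}
    for did in cand:
        ents = entities[did]
        if not ents:
            continue
        toks = tokens[did]
        matched = [(lf, leaf_tf(lf, toks)) for lf in ast.positive_leaves
                   if leaf_tf(lf, toks) > 0]
        if not matched:
            continue  # retrieved via negation only; T is undefined
        coord = len(matched) / ast.n_elements
        tfidf = 0.0
        for lf, tf in matched:
            df = sum(1 for t in tokens.values() if leaf_tf(lf, t) > 0)
            tfidf += lf.boost * math.sqrt(tf) * (1 + math.log(n_docs / (df + 1))) ** 2
        t_score = coord * tfidf
        n_score = 1.0 / min(len(ents), 10)
        d = by_id[did]
        if d.impact_factor is None or d.impact_factor == 0:
            q_score = 1.0
        else:
            q_score = 1.0 + d.impact_factor / max_if * 9.0
        md = (d.pub_year * 12 + (d.pub_month or 1)) if d.pub_year else None
        age = 96 if md is None else min(max(reference_month - md, 0), 96)
        r_score = 0.5 ** (age / 24)
        sd = (t_score ** pt) * (n_score ** pn) * (q_score ** pq) * (r_score ** pr)
        for cid in ents:
            scores[cid] = scores.get(cid, 0.0) + sd
            ndocs[cid] = ndocs.get(cid, 0) + 1

    items = list(scores.items())
    if ast.type_filter is not None:
        items = [
            (cid, s) for cid, s in items
            if (cid in dictionary.concepts
                and ast.type_filter in dictionary.concepts[cid].types)
            or (cid.startswith("MUT:") and ast.type_filter == "mutation")
        ]
    items.sort(key=lambda cs: (-cs[1], -ndocs[cs[0]], cs[0]))
    return items[:k]
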