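"""Entity dictionary construction and dictionary-based mention extraction.

The dictionary is built from multi-source records of (source database,
surface name, entity type, cross-reference IDs).  Records sharing a
cross-reference ID are synonyms of one concept (transitive closure), so
e.g. "Gleevec" and "imatinib" with the same DrugBank ID collapse into a
single concept.  Entity types live in priority-ordered groups:

    gene_group    > chem_group > disease_group > pathway_group
    (gene/protein, target, transcription factor, miRNA)
    (chemical compound, drug, toxin) / (disease) / (pathway)

A concept may carry several types within one group but never across groups;
when a merged concept accumulates types from different groups, only the
types of the highest-priority group are kept.  A fifth group,
mutation_group, is reserved for pattern-derived mutation mentions and never
appears in source records.

Mention extraction is gazetteer matching on word boundaries: at each
position the longest dictionary name wins, matching is case-insensitive
except for short all-uppercase names (gene-symbol style, e.g. "TP53"),
which must match exactly.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._text import token_spans

# -- type system ------------------------------------------------------------

GENE_GROUP = "gene_group"
CHEM_GROUP = "chem_group"
DISEASE_GROUP = "disease_group"
PATHWAY_GROUP = "pathway_group"
MUTATION_GROUP = "mutation_group"

#: entity type -> group, in declaration order of the closed type set
TYPE_TO_GROUP: dict[str, str] = {
    "gene/protein": GENE_GROUP,
    "target": GENE_GROUP,
    "transcription factor": GENE_GROUP,
    "miRNA": GENE_GROUP,
    "chemical compound": CHEM_GROUP,
    "drug": CHEM_GROUP,
    "toxin": CHEM_GROUP,
    "disease": DISEASE_GROUP,
    "pathway": PATHWAY_GROUP,
    "mutation": MUTATION_GROUP,
}

#: smaller rank = higher priority
GROUP_PRIORITY: dict[str, int] = {
    GENE_GROUP: 0,
    CHEM_GROUP: 1,
    DISEASE_GROUP: 2,
    PATHWAY_GROUP: 3,
    MUTATION_GROUP: 4,
}

VALID_TYPES = frozenset(t for t in TYPE_TO_GROUP if t != "mutation")

#: maximum character length of an all-uppercase name matched case-sensitively
_CASE_SENSITIVE_MAXLEN = 4


class DictionaryError(ValueError):
    """Raised for invalid source records or dictionary inconsistencies."""


@dataclass(frozen=True)
class SourceRecord:
    """One row of a source database dump."""

    source: str
    surface: str
    entity_type: str
    xrefs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        surface = _normalize_surface(self.surface)
        if not surface:
            raise DictionaryError(
                f"record from {self.source!r} has an empty surface"
            )
        object.__setattr__(self, "surface", surface)
        if self.entity_type not in VALID_TYPES:
            raise DictionaryError(
                f"record {self.surface!r} from {self.source!r} has unknown "
                f"entity type {self.entity_type!r}; expected one of "
                f"{sorted(VALID_TYPES)}"
            )
        object.__setattr__(self, "xrefs", frozenset(self.xrefs))


@dataclass(frozen=True)
class EntityConcept:
    """A canonical entity: a synonym set with types from a single group."""

    concept_id: str
    names: frozenset[str]
    types: frozenset[str]
    group: str

    def preferred_name(self) -> str:
        """Deterministic display name: shortest, then lexicographic."""
        return min(self.names, key=lambda n: (len(n), n))


@dataclass(frozen=True)
class Mention:
    """An entity occurrence: 0-based half-open character span."""

    concept_id: str
    start: int
    end: int
    matched_surface: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _normalize_surface(surface: str) -> str:
    return " ".join(unicodedata.normalize("NFC", surface).split())


def assign_group(types: Iterable[str]) -> tuple[str, frozenset[str]]:
    """Resolve a type set to its highest-priority group.

    Returns ``(group, kept_types)`` where *kept_types* are the input types
    belonging to that group; types from lower-priority groups are dropped.
    """
    types = frozenset(types)
    if not types:
        raise DictionaryError("assign_group requires a non-empty type set")
    unknown = types - set(TYPE_TO_GROUP)
    if unknown:
        raise DictionaryError(f"unknown entity types: {sorted(unknown)}")
    group = min((TYPE_TO_GROUP[t] for t in types), key=GROUP_PRIORITY.__getitem__)
    kept = frozenset(t for t in types if TYPE_TO_GROUP[t] == group)
    return group, kept


# -- dictionary -------------------------------------------------------------


class Dictionary:
    """Concept store plus the surface lookup used by the matcher.

    ``name_index`` maps case-folded surfaces to a single concept_id;
    ambiguous surfaces are resolved at build time (highest-priority group,
    then smallest concept_id) so lookups are deterministic.
    """

    def __init__(self, concepts: Sequence[EntityConcept]):
        self.concepts: dict[str, EntityConcept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise DictionaryError(f"duplicate concept_id {c.concept_id!r}")
            self.concepts[c.concept_id] = c
        self.name_index: dict[str, str] = {}
        # token-tuple lookup tables used by extract_entities
        self._ci: dict[tuple[str, ...], str] = {}   # case-insensitive names
        self._cs: dict[tuple[str, ...], str] = {}   # short all-upper names
        self._max_tokens = 0
        for cid in sorted(self.concepts):
            c = self.concepts[cid]
            for name in c.names:
                self._register(name, cid)

    def _register(self, name: str, cid: str) -> None:
        folded = name.casefold()
        prev = self.name_index.get(folded)
        if prev is not None and prev != cid:
            cid = self._resolve_ambiguous(prev, cid)
        self.name_index[folded] = cid
        toks = tuple(t for _, _, t in token_spans(name))
        if not toks:
            return
        self._max_tokens = max(self._max_tokens, len(toks))
        if name.isupper() and len(name) <= _CASE_SENSITIVE_MAXLEN:
            self._cs[toks] = self._pick(self._cs.get(toks), cid)
        else:
            key = tuple(t.casefold() for t in toks)
            self._ci[key] = self._pick(self._ci.get(key), cid)

    def _pick(self, prev: str | None, cid: str) -> str:
        return cid if prev is None else self._resolve_ambiguous(prev, cid)

    def _resolve_ambiguous(self, a: str, b: str) -> str:
        """Higher-priority group wins; within a group, smaller concept_id."""
        ka = (GROUP_PRIORITY[self.concepts[a].group], a)
        kb = (GROUP_PRIORITY[self.concepts[b].group], b)
        return a if ka <= kb else b

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> EntityConcept:
        return self.concepts[concept_id]

    # -- persistence: one concept per line ---------------------------------

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for cid in sorted(self.concepts):
                c = self.concepts[cid]
                fh.write(json.dumps({
                    "concept_id": c.concept_id,
                    "group": c.group,
                    "types": sorted(c.types),
                    "names": sorted(c.names),
                }, ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        concepts = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                concepts.append(EntityConcept(
                    concept_id=rec["concept_id"],
                    names=frozenset(rec["names"]),
                    types=frozenset(rec["types"]),
                    group=rec["group"],
                ))
        return cls(concepts)


def merge_records(
    records: Sequence[SourceRecord],
    stop_surfaces: Iterable[str] = (),
) -> Dictionary:
    """Merge source records into concepts.

    Two records fall into the same concept when they share a cross-reference
    ID (transitively) or, lacking shared xrefs, when their case-folded
    surfaces are identical and their types belong to the same group.
    ``stop_surfaces`` is an exclusion list (case-folded comparison) applied
    after merging; it stands in for a manual curation pass.
    """
    records = list(records)
    if not records:
        raise DictionaryError("merge_records requires at least one record")

    parent = list(range(len(records)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    by_xref: dict[str, int] = {}
    by_surface: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        for x in rec.xrefs:
            if x in by_xref:
                union(i, by_xref[x])
            else:
                by_xref[x] = i
        skey = (rec.surface.casefold(), TYPE_TO_GROUP[rec.entity_type])
        if skey in by_surface:
            union(i, by_surface[skey])
        else:
            by_surface[skey] = i

    clusters: dict[int, list[SourceRecord]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(find(i), []).append(rec)

    stop = {_normalize_surface(s).casefold() for s in stop_surfaces}
    drafts = []
    for members in clusters.values():
        group, types = assign_group({m.entity_type for m in members})
        names: dict[str, str] = {}  # casefold -> first surface seen
        for m in sorted(members, key=lambda m: m.surface):
            names.setdefault(m.surface.casefold(), m.surface)
        kept = frozenset(
            surf for folded, surf in names.items() if folded not in stop
        )
        if not kept:
            continue
        drafts.append((group, kept, types))

    # stable ids independent of record order: sort by group then name set
    drafts.sort(key=lambda d: (GROUP_PRIORITY[d[0]], sorted(n.casefold() for n in d[1])))
    concepts = [
        EntityConcept(concept_id=f"C{i:06d}", names=names, types=types, group=group)
        for i, (group, names, types) in enumerate(drafts, start=1)
    ]
    return Dictionary(concepts)


def read_source_tsv(path: str | Path) -> list[SourceRecord]:
    """Read source records from a TSV with header source/name/type/xrefs."""
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for col in ("source", "name", "type", "xrefs"):
            if col not in idx:
                raise DictionaryError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            xrefs = frozenset(
                x for x in fields[idx["xrefs"]].split("|") if x
            ) if len(fields) > idx["xrefs"] else frozenset()
            try:
                records.append(SourceRecord(
                    source=fields[idx["source"]],
                    surface=fields[idx["name"]],
                    entity_type=fields[idx["type"]],
                    xrefs=xrefs,
                ))
            except DictionaryError as exc:
                raise DictionaryError(f"{path}:{lineno}: {exc}") from exc
    return records


# -- mention extraction -----------------------------------------------------


def extract_entities(text: str, dictionary: Dictionary) -> list[Mention]:
    """Find dictionary mentions: leftmost-longest, non-overlapping.

    Matching operates on the word-token stream, so matches always start and
    end on word boundaries and internal hyphens stay inside one token.
    """
    if not text:
        return []
    spans = token_spans(text)
    mentions: list[Mention] = []
    i = 0
    n = len(spans)
    while i < n:
        hit: tuple[int, str] | None = None  # (n_tokens, concept_id)
        limit = min(dictionary._max_tokens, n - i)
        for width in range(limit, 0, -1):
            window = tuple(t for _, _, t in spans[i:i + width])
            cid = dictionary._cs.get(window)
            if cid is None:
                cid = dictionary._ci.get(tuple(t.casefold() for t in window))
            if cid is not None:
                hit = (width, cid)
                break
        if hit is None:
            i += 1
            continue
        width, cid = hit
        start = spans[i][0]
        end = spans[i + width - 1][1]
        mentions.append(Mention(cid, start, end, text[start:end]))
        i += width
    return mentions


_POINT_MUTATION_RE = re.compile(
    r"(?<![0-9A-Za-z])[A-Z][0-9]+[A-Z](?![0-9A-Za-z])"
)
_CODING_CHANGE_RE = re.compile(
    r"(?<![0-9A-Za-z])c\.[0-9]+[ACGT]>[ACGT](?![0-9A-Za-z])"
)

MUTATION_ID_PREFIX = "MUT:"


def mutation_concept(surface: str) -> EntityConcept:
    """Concept for a pattern-derived mutation, keyed by uppercase surface."""
    norm = surface.upper()
    return EntityConcept(
        concept_id=MUTATION_ID_PREFIX + norm,
        names=frozenset({norm}),
        types=frozenset({"mutation"}),
        group=MUTATION_GROUP,
    )


def extract_mutations(text: str) -> list[Mention]:
    """Pattern-match protein point mutations (T315I) and simple coding
    changes (c.944C>T); each normalized uppercase surface is its own
    mutation_group concept."""
    candidates = []
    for pat in (_POINT_MUTATION_RE, _CODING_CHANGE_RE):
        for m in pat.finditer(text):
            candidates.append((m.start(), m.end(), m.group()))
    picked = resolve_overlaps(
        [Mention(MUTATION_ID_PREFIX + s.upper(), a, b, s) for a, b, s in candidates]
    )
    return picked


def resolve_overlaps(mentions: Iterable[Mention]) -> list[Mention]:
    """Greedy leftmost-longest selection of non-overlapping mentions."""
    ordered = sorted(mentions, key=lambda m: (m.start, -(m.end - m.start), m.concept_id))
    out: list[Mention] = []
    last_end = -1
    for m in ordered:
        if m.start >= last_end:
            out.append(m)
            last_end = m.end
    return out


def extract_all(text: str, dictionary: Dictionary) -> list[Mention]:
    """Dictionary mentions plus mutation mentions, overlap-resolved."""
    return resolve_overlaps(
        list(extract_entities(text, dictionary)) + list(extract_mutations(text))
    )
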