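"""Readers and writers for the on-disk formats.

Corpus: line-delimited JSON records with fields id, text, journal,
impact_factor, year, month.  MEDLINE citation XML is also accepted
(ArticleTitle + AbstractText become the text; impact factors come from a
separate journal -> IF TSV since MEDLINE does not carry them).  Gold
annotations are TSV (doc_id, start, end, surface, concept_id).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from lxml import etree

from .dictionary import Mention
from .index import DocumentRecord

_MONTHS = {m: i + 1 for i, m in enumerate(
    "Jan Feb Mar Apr May Jun Jul Aug Sep Oct Nov Dec".split())}


def read_corpus(path: str | Path) -> list[DocumentRecord]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            docs.append(DocumentRecord(
                doc_id=str(rec["id"]),
                text=rec.get("text", ""),
                journal=rec.get("journal", "") or "",
                impact_factor=rec.get("impact_factor"),
                pub_year=rec.get("year"),
                pub_month=rec.get("month"),
            ))
    return docs


def write_corpus(docs: Iterable[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({
                "id": d.doc_id, "text": d.text, "journal": d.journal,
                "impact_factor": d.impact_factor,
                "year": d.pub_year, "month": d.pub_month,
            }, ensure_ascii=False) + "\n")


def read_journal_impact_factors(path: str | Path) -> dict[str, float]:
    """TSV of journal name -> impact factor (no header)."""
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            name, _, value = line.rstrip("\n").rpartition("\t")
            out[name.strip()] = float(value)
    return out


def read_medline_xml(
    path: str | Path,
    impact_factors: Mapping[str, float] | None = None,
) -> list[DocumentRecord]:
    """Parse MEDLINE citation XML into document records.

    PMID -> id; ArticleTitle + AbstractText -> text; Journal/Title ->
    journal; PubDate Year/Month -> date.  Articles without a PMID are
    skipped.
    """
    impact_factors = impact_factors or {}
    tree = etree.parse(str(path))
    docs = []
    for cit in tree.iter("MedlineCitation"):
        pmid = cit.findtext("PMID")
        if not pmid:
            continue
        title = cit.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            "".join(node.itertext())
            for node in cit.findall(".//Abstract/AbstractText")
        )
        journal = cit.findtext(".//Journal/Title") or ""
        year_text = cit.findtext(".//JournalIssue/PubDate/Year")
        month_text = cit.findtext(".//JournalIssue/PubDate/Month")
        month = None
        if month_text:
            month = _MONTHS.get(month_text.strip()[:3].title())
            if month is None and month_text.strip().isdigit():
                month = int(month_text)
        docs.append(DocumentRecord(
            doc_id=pmid.strip(),
            text=(title + " " + abstract).strip(),
            journal=journal,
            impact_factor=impact_factors.get(journal),
            pub_year=int(year_text) if year_text else None,
            pub_month=month,
        ))
    return docs


def read_gold_tsv(path: str | Path) -> dict[str, list[Mention]]:
    gold: dict[str, list[Mention]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated fields"
                )
            doc_id, start, end, surface, cid = fields
            gold.setdefault(doc_id, []).append(
                Mention(cid, int(start), int(end), surface)
            )
    return gold


def write_gold_tsv(gold: Mapping[str, list[Mention]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in sorted(gold):
            for m in gold[doc_id]:
                fh.write(
                    f"{doc_id}\t{m.start}\t{m.end}\t{m.matched_surface}"
                    f"\t{m.concept_id}\n"
                )


def read_relevance_json(path: str | Path) -> dict[str, set[str]]:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {query: set(names) for query, names in raw.items()}


def write_relevance_json(
    relevance: Mapping[str, set[str]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {q: sorted(names) for q, names in relevance.items()},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
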