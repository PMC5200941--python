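"""Bibliographic citation records and their on-disk representations.

The audit consumes a local citation corpus: one record per article with the
fields the linkage stage needs (title, abstract, publication date, MeSH
descriptors and subheadings, publication types, and the secondary-ID field
where registry accession numbers cited in an article are recorded). The
native format is JSON lines; an adapter reads PubMed's standard XML
citation export into the same records.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from lxml import etree

from .dates import PartialDate, parse_partial_date

__all__ = ["CitationRecord", "read_citations", "write_citations", "read_pubmed_xml"]


@dataclass(frozen=True)
class CitationRecord:
    """One bibliographic record."""

    pmid: str
    title: str
    abstract: str
    pub_date: PartialDate
    mesh_terms: frozenset[str] = frozenset()
    publication_types: frozenset[str] = frozenset()
    subheadings: frozenset[str] = frozenset()
    secondary_ids: frozenset[str] = frozenset()


def _to_json(citation: CitationRecord) -> dict:
    return {
        "pmid": citation.pmid,
        "title": citation.title,
        "abstract": citation.abstract,
        "pub_date": citation.pub_date.isoformat(),
        "mesh_terms": sorted(citation.mesh_terms),
        "publication_types": sorted(citation.publication_types),
        "subheadings": sorted(citation.subheadings),
        "secondary_ids": sorted(citation.secondary_ids),
    }


def write_citations(citations: Iterable[CitationRecord], path: Union[str, Path]) -> None:
    """Write a citation corpus as JSON lines (one record per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for citation in citations:
            fh.write(json.dumps(_to_json(citation), sort_keys=False) + "\n")


def read_citations(path: Union[str, Path]) -> list[CitationRecord]:
    """Read a JSON-lines citation corpus.

    Raises :class:`ValueError` on a duplicate PMID (PMIDs must be unique
    within a corpus) or a malformed line.
    """
    records: list[CitationRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            pmid = str(raw["pmid"])
            if pmid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pmid {pmid}")
            seen.add(pmid)
            records.append(
                CitationRecord(
                    pmid=pmid,
                    title=raw.get("title", ""),
                    abstract=raw.get("abstract", ""),
                    pub_date=parse_partial_date(raw["pub_date"]),
                    mesh_terms=frozenset(raw.get("mesh_terms", ())),
                    publication_types=frozenset(raw.get("publication_types", ())),
                    subheadings=frozenset(raw.get("subheadings", ())),
                    secondary_ids=frozenset(raw.get("secondary_ids", ())),
                )
            )
    return records


_PUBMED_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


def _pubmed_date(article: etree._Element) -> PartialDate:
    node = article.find(".//Journal/JournalIssue/PubDate")
    if node is None:
        raise ValueError("citation has no PubDate")
    year = node.findtext("Year")
    if year is None:
        raise ValueError("citation PubDate has no Year")
    month_text = (node.findtext("Month") or "1").strip().lower()
    month = _PUBMED_MONTHS.get(month_text[:3])
    if month is None:
        try:
            month = int(month_text)
        except ValueError:
            month = 1
    day = node.findtext("Day")
    return PartialDate(int(year), month, int(day) if day else None)


def read_pubmed_xml(path: Union[str, Path]) -> list[CitationRecord]:
    """Adapter: read a PubMed XML citation export (``PubmedArticleSet``)."""
    root = etree.parse(str(path)).getroot()
    records: list[CitationRecord] = []
    for article in root.iter("PubmedArticle"):
        pmid = article.findtext(".//MedlineCitation/PMID")
        if pmid is None:
            continue
        title = article.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            (el.text or "") for el in article.iter("AbstractText")
        ).strip()
        mesh = frozenset(
            el.text for el in article.iter("DescriptorName") if el.text
        )
        subheadings = frozenset(
            el.text for el in article.iter("QualifierName") if el.text
        )
        pub_types = frozenset(
            el.text for el in article.iter("PublicationType") if el.text
        )
        secondary = frozenset(
            el.text for el in article.iter("AccessionNumber") if el.text
        )
        records.append(
            CitationRecord(
                pmid=pmid,
                title=title,
                abstract=abstract,
                pub_date=_pubmed_date(article),
                mesh_terms=mesh,
                publication_types=pub_types,
                subheadings=subheadings,
                secondary_ids=secondary,
            )
        )
    return records
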