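"""Fielded boolean queries over local citation records.

A small evaluator for PubMed-style fielded searches, sufficient to express
the validated "therapy" clinical-query filters used to keep treatment-study
reports and drop protocols, commentary and secondary analyses. Queries are
explicit ASTs — ``Term`` leaves tagged with a field, combined by ``And`` /
``Or`` — evaluated against one citation at a time:

* ``title_abstract`` terms match whitespace-delimited, case-insensitive,
  punctuation-stripped tokens of title+abstract; a truncated term
  (``random*``) matches any token with that prefix;
* ``mesh`` / ``publication_type`` / ``subheading`` terms are
  case-insensitive set membership against the record's own lists (a local
  corpus has no MeSH-tree explosion).
"""
from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Union

from .citations import CitationRecord

__all__ = [
    "Term",
    "And",
    "Or",
    "FieldedQuery",
    "TITLE_ABSTRACT",
    "MESH",
    "PUBLICATION_TYPE",
    "SUBHEADING",
    "tokenize",
    "evaluate_query",
    "BROAD_THERAPY",
    "NARROW_THERAPY",
    "THERAPY_FILTERS",
]

TITLE_ABSTRACT = "title_abstract"
MESH = "mesh"
PUBLICATION_TYPE = "publication_type"
SUBHEADING = "subheading"
_FIELDS = frozenset({TITLE_ABSTRACT, MESH, PUBLICATION_TYPE, SUBHEADING})


@dataclass(frozen=True)
class Term:
    text: str
    field: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.field not in _FIELDS:
            raise ValueError(f"unknown query field: {self.field!r}")


@dataclass(frozen=True)
class And:
    children: tuple["FieldedQuery", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["FieldedQuery", ...]


FieldedQuery = Union[Term, And, Or]


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip leading/trailing punctuation."""
    tokens = []
    for raw in text.lower().split():
        token = raw.strip(string.punctuation)
        if token:
            tokens.append(token)
    return tokens


def _match_term(term: Term, citation: CitationRecord) -> bool:
    needle = term.text.lower()
    if term.field == TITLE_ABSTRACT:
        tokens = tokenize(citation.title + " " + citation.abstract)
        if term.truncated:
            return any(tok.startswith(needle) for tok in tokens)
        return needle in tokens
    if term.field == MESH:
        values = citation.mesh_terms
    elif term.field == PUBLICATION_TYPE:
        values = citation.publication_types
    else:
        values = citation.subheadings
    return needle in {v.lower() for v in values}


def evaluate_query(query: FieldedQuery, citation: CitationRecord) -> bool:
    """Does ``citation`` satisfy ``query``?"""
    if isinstance(query, Term):
        return _match_term(query, citation)
    if isinstance(query, And):
        return all(evaluate_query(child, citation) for child in query.children)
    if isinstance(query, Or):
        return any(evaluate_query(child, citation) for child in query.children)
    raise TypeError(f"not a query node: {query!r}")


# The standard validated PubMed therapy clinical queries.
# Broad (sensitive):
#   ((clinical[Title/Abstract] AND trial[Title/Abstract]) OR
#    "clinical trials as topic"[MeSH] OR "clinical trial"[Publication Type] OR
#    random*[Title/Abstract] OR "random allocation"[MeSH] OR
#    "therapeutic use"[Subheading])
BROAD_THERAPY: FieldedQuery = Or((
    And((Term("clinical", TITLE_ABSTRACT), Term("trial", TITLE_ABSTRACT))),
    Term("clinical trials as topic", MESH),
    Term("clinical trial", PUBLICATION_TYPE),
    Term("random", TITLE_ABSTRACT, truncated=True),
    Term("random allocation", MESH),
    Term("therapeutic use", SUBHEADING),
))

# Narrow (specific):
#   ("randomized controlled trial"[Publication Type] OR
#    (randomized[Title/Abstract] AND controlled[Title/Abstract] AND
#     trial[Title/Abstract]))
NARROW_THERAPY: FieldedQuery = Or((
    Term("randomized controlled trial", PUBLICATION_TYPE),
    And((
        Term("randomized", TITLE_ABSTRACT),
        Term("controlled", TITLE_ABSTRACT),
        Term("trial", TITLE_ABSTRACT),
    )),
))

#: Selectable therapy-filter variants; "broad" is the audit default.
THERAPY_FILTERS: dict[str, FieldedQuery] = {
    "broad": BROAD_THERAPY,
    "narrow": NARROW_THERAPY,
}
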