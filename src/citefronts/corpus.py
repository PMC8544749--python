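"""Publication-record corpora: schema, validation, I/O, and query filtering.

A corpus is a list of :class:`PublicationRecord` — one per paper, carrying an
opaque identifier, the publication year, title, abstract, and the list of ids
the paper cites.  The canonical on-disk format is JSONL (one JSON object per
line with keys ``id``/``year``/``title``/``abstract``/``references``); TSV and
PubMed/MEDLINE XML are supported as alternate read formats (TSV also writes).

Query filtering emulates a boolean AND of prefix-wildcard terms over the
title+abstract token stream.  PubMed's stemming and MeSH expansion are *not*
emulated: ``*`` is a plain token-prefix match, which keeps the semantics local
and deterministic.  Matching uses the raw word splitter without stopword or
minimum-length filtering — queries such as ``immun* AND t lymph*`` contain
single-character tokens that term extraction would discard.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "PublicationRecord",
    "Query",
    "QueryClause",
    "CorpusValidationError",
    "CorpusFormatError",
    "split_words",
    "parse_query",
    "match_query",
    "filter_corpus",
    "read_corpus",
    "write_corpus",
]


class CorpusValidationError(ValueError):
    """A record or corpus violates the schema invariants."""


class CorpusFormatError(ValueError):
    """A corpus file could not be parsed."""


@dataclass
class PublicationRecord:
    """One publication: identifier, year, title, abstract, outgoing references."""

    id: str
    year: int | None
    title: str
    abstract: str = ""
    references: list[str] = field(default_factory=list)


# --- tokenization primitive shared with keyword extraction -------------------

# word = run of letters/digits, optionally chained by internal hyphens
_WORD_HYPH = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)
_WORD_PLAIN = re.compile(r"[^\W_]+", re.UNICODE)


def split_words(text: str, keep_hyphenated: bool = True) -> list[str]:
    """Lowercased, NFKC-normalized word stream; punctuation stripped except
    internal hyphens when *keep_hyphenated*."""
    norm = unicodedata.normalize("NFKC", text).casefold()
    rx = _WORD_HYPH if keep_hyphenated else _WORD_PLAIN
    return rx.findall(norm)


# --- validation ---------------------------------------------------------------


def validate_corpus(records: list[PublicationRecord]) -> list[PublicationRecord]:
    """Check corpus invariants in place and return the list.

    Duplicate or empty ids raise; self-references are removed (count logged);
    years must be positive integers when present.
    """
    seen: dict[str, int] = {}
    dupes: list[str] = []
    for rec in records:
        if not rec.id:
            raise CorpusValidationError("record with empty id")
        if rec.id in seen:
            dupes.append(rec.id)
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if dupes:
        raise CorpusValidationError(f"duplicate record ids: {sorted(set(dupes))}")
    n_self = 0
    for rec in records:
        if rec.year is not None:
            if not isinstance(rec.year, int) or rec.year <= 0:
                raise CorpusValidationError(
                    f"record {rec.id!r}: year must be a positive integer, got {rec.year!r}"
                )
        if rec.id in rec.references:
            n_self += rec.references.count(rec.id)
            rec.references = [r for r in rec.references if r != rec.id]
    if n_self:
        logger.info("dropped %d self-reference(s) during validation", n_self)
    return records


# --- readers / writers --------------------------------------------------------

_FIELDS = ("id", "year", "title", "abstract", "references")


def _record_from_dict(obj: dict, where: str) -> PublicationRecord:
    try:
        year = obj.get("year")
        if year in ("", None):
            year = None
        else:
            year = int(year)
        refs = obj.get("references") or []
        if isinstance(refs, str):
            refs = [r for r in refs.split("|") if r]
        return PublicationRecord(
            id=str(obj["id"]),
            year=year,
            title=str(obj.get("title", "")),
            abstract=str(obj.get("abstract", "")),
            references=[str(r) for r in refs],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"malformed record at {where}: {exc}") from exc


def _read_jsonl(path: str) -> list[PublicationRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"invalid JSON at line {lineno}: {exc}") from exc
            out.append(_record_from_dict(obj, f"line {lineno}"))
    return out


def _read_tsv(path: str) -> list[PublicationRecord]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_FIELDS) <= set(reader.fieldnames):
            raise CorpusFormatError(
                f"TSV header must contain columns {_FIELDS}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, 2):
            out.append(_record_from_dict(row, f"line {i}"))
    return out


def _read_pubmed_xml(path: str) -> list[PublicationRecord]:
    """Import PubMed/MEDLINE XML: PMID→id, ArticleTitle→title, concatenated
    AbstractText→abstract, PubDate/Year→year, cited PMIDs→references."""
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"invalid XML: {exc}") from exc
    out = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//MedlineCitation/PMID")
        if pmid is None:
            raise CorpusFormatError("PubmedArticle without PMID")
        title = art.findtext(".//Article/ArticleTitle") or ""
        abstract = " ".join(
            (el.text or "") for el in art.findall(".//Article/Abstract/AbstractText")
        ).strip()
        year_txt = art.findtext(".//Article/Journal/JournalIssue/PubDate/Year")
        year = int(year_txt) if year_txt else None
        refs = [
            el.text
            for el in art.findall(".//ReferenceList//ArticleId[@IdType='pubmed']")
            if el.text
        ]
        out.append(
            PublicationRecord(
                id=pmid, year=year, title=title, abstract=abstract, references=refs
            )
        )
    return out


_READERS = {"jsonl": _read_jsonl, "tsv": _read_tsv, "pubmed_xml": _read_pubmed_xml}


def read_corpus(path: str, format: str = "jsonl") -> list[PublicationRecord]:
    """Read and validate a corpus from *path* in the given *format*
    (``jsonl``, ``tsv`` or ``pubmed_xml``)."""
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {sorted(_READERS)}")
    return validate_corpus(reader(path))


def write_corpus(records: list[PublicationRecord], path: str, format: str = "jsonl") -> None:
    """Write a corpus so that :func:`read_corpus` reproduces it field-for-field."""
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(
                    json.dumps(
                        {
                            "id": rec.id,
                            "year": rec.year,
                            "title": rec.title,
                            "abstract": rec.abstract,
                            "references": rec.references,
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_FIELDS)
            for rec in records:
                writer.writerow(
                    [
                        rec.id,
                        "" if rec.year is None else rec.year,
                        rec.title,
                        rec.abstract,
                        "|".join(rec.references),
                    ]
                )
    else:
        raise ValueError(f"unknown write format {format!r}; expected 'jsonl' or 'tsv'")


# --- query semantics ----------------------------------------------------------


@dataclass(frozen=True)
class QueryClause:
    """One AND clause: a contiguous token sequence; the last token may be a
    prefix when *wildcard* is set."""

    tokens: tuple[str, ...]
    wildcard: bool = False


@dataclass(frozen=True)
class Query:
    clauses: tuple[QueryClause, ...]


def parse_query(text: str) -> Query:
    """Parse ``"immun* AND t lymph*"``-style queries: clauses joined by AND,
    ``*`` allowed only at the end of a clause."""
    parts = [p.strip() for p in re.split(r"\s+AND\s+", text, flags=re.IGNORECASE)]
    clauses = []
    for part in parts:
        if not part:
            raise ValueError(f"empty clause in query {text!r}")
        wildcard = part.endswith("*")
        body = part[:-1] if wildcard else part
        if "*" in body:
            raise ValueError(f"wildcard allowed only at clause end: {part!r}")
        tokens = tuple(split_words(body))
        if not tokens:
            raise ValueError(f"clause {part!r} contains no tokens")
        clauses.append(QueryClause(tokens=tokens, wildcard=wildcard))
    if not clauses:
        raise ValueError("query has no clauses")
    return Query(clauses=tuple(clauses))


def _clause_matches(tokens: list[str], clause: QueryClause) -> bool:
    k = len(clause.tokens)
    head, last = clause.tokens[:-1], clause.tokens[-1]
    for i in range(len(tokens) - k + 1):
        if tuple(tokens[i : i + k - 1]) != head:
            continue
        tok = tokens[i + k - 1]
        if tok.startswith(last) if clause.wildcard else tok == last:
            return True
    return False


def match_query(record: PublicationRecord, query: Query | str) -> bool:
    """True iff every AND clause matches the record's title+abstract tokens."""
    if isinstance(query, str):
        query = parse_query(query)
    if not query.clauses:
        raise ValueError("query has no clauses")
    tokens = split_words(record.title) + split_words(record.abstract)
    return all(_clause_matches(tokens, c) for c in query.clauses)


def filter_corpus(
    records: list[PublicationRecord], query: Query | str
) -> list[PublicationRecord]:
    """Order-preserving subset of records satisfying :func:`match_query`."""
    if isinstance(query, str):
        query = parse_query(query)
    return [r for r in records if match_query(r, query)]
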