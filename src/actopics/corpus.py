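"""Bibliographic corpus handling: reading, filtering, indexing, period slicing.

Records carry a PMID-like identifier, an ordered author list, a journal, a
publication year, title/abstract text, and a list of pre-extracted keyphrases.
Each keyphrase is an atomic vocabulary unit (bag-of-keyphrases representation);
no stemming or case folding is applied beyond whitespace normalization.

Two input dialects are supported:

* ``medline-xml`` — a MEDLINE/PubMed ``PubmedArticleSet`` subset. Keyphrases
  are read from a ``KeyphraseList/Keyphrase`` element if present, falling back
  to ``KeywordList/Keyword``, or supplied via a sidecar id → keyphrases map.
* ``tabular`` — one record per line, tab-separated fields
  ``id, authors, journal, year, title, abstract, keyphrases``, with authors
  and keyphrases internally delimited by ``" | "``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

FIELD_SEP = "\t"
LIST_SEP = " | "

__all__ = [
    "Document",
    "Corpus",
    "PeriodPartition",
    "DEFAULT_PERIODS",
    "read_records",
    "write_tabular",
    "filter_abstracts",
    "slice_periods",
    "ratio_table",
    "corpus_statistics",
]

#: The study's four five-year eras (inclusive year ranges).
DEFAULT_PERIODS = ((1996, 2000), (2001, 2005), (2006, 2010), (2011, 2015))


def _norm(label: str) -> str:
    """Trim and collapse internal whitespace; case is preserved."""
    return " ".join(label.split())


@dataclass
class Document:
    """One bibliographic record.

    ``tokens`` holds the record's keyphrases, each treated as a single
    vocabulary unit of length ``n_tokens`` (N_d); ``authors`` has length
    ``n_authors`` (A_d) and must be non-empty for a record to enter the model.
    """

    id: str
    authors: list[str]
    journal: str
    year: int
    title: str = ""
    abstract: str = ""
    tokens: list[str] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def n_authors(self) -> int:
        return len(self.authors)


class Registry:
    """Dense bijection label ↔ integer index (insertion-ordered)."""

    def __init__(self, labels: Iterable[str] = ()) -> None:
        self._index: dict[str, int] = {}
        for lab in labels:
            self.add(lab)

    def add(self, label: str) -> int:
        idx = self._index.get(label)
        if idx is None:
            idx = len(self._index)
            self._index[label] = idx
        return idx

    def __getitem__(self, label: str) -> int:
        return self._index[label]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self._index)

    @property
    def labels(self) -> list[str]:
        return list(self._index)

    def __iter__(self):
        return iter(self._index)


class Corpus:
    """An indexed document collection.

    Builds dense integer registries for the vocabulary (size ``V``), authors
    (size ``A``) and journals (size ``J``) and stores per-document index
    arrays alongside the original :class:`Document` objects.
    """

    def __init__(
        self,
        documents: Sequence[Document],
        vocabulary: Iterable[str] | None = None,
        authors: Iterable[str] | None = None,
        journals: Iterable[str] | None = None,
    ) -> None:
        self.documents = list(documents)
        self.vocabulary = Registry(vocabulary or ())
        self.authors = Registry(authors or ())
        self.journals = Registry(journals or ())
        self.token_ids: list[np.ndarray] = []
        self.author_ids: list[np.ndarray] = []
        self.journal_id: np.ndarray
        journal_ids = []
        for doc in self.documents:
            if doc.n_authors < 1:
                raise ValueError(f"document {doc.id!r} has no authors")
            self.token_ids.append(
                np.array([self.vocabulary.add(t) for t in doc.tokens], dtype=np.int64)
            )
            self.author_ids.append(
                np.array([self.authors.add(a) for a in doc.authors], dtype=np.int64)
            )
            journal_ids.append(self.journals.add(doc.journal))
        self.journal_id = np.array(journal_ids, dtype=np.int64)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def A(self) -> int:
        return len(self.authors)

    @property
    def J(self) -> int:
        return len(self.journals)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(t) for t in self.token_ids))

    def modeled(self) -> "Corpus":
        """Corpus restricted to documents with at least one token, sharing
        this corpus's registries (zero-keyphrase records stay in statistics
        but contribute nothing to model fitting)."""
        docs = [d for d in self.documents if d.n_tokens > 0]
        return Corpus(
            docs,
            vocabulary=self.vocabulary.labels,
            authors=self.authors.labels,
            journals=self.journals.labels,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Corpus(D={self.n_documents}, V={self.V}, A={self.A}, "
            f"J={self.J}, tokens={self.n_tokens})"
        )


@dataclass
class PeriodPartition:
    """Documents split into consecutive, disjoint year ranges."""

    boundaries: list[tuple[int, int]]
    slices: dict[int, Corpus]
    n_excluded: int

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.boundaries]


class RecordError(ValueError):
    """A malformed record, reported with its position in the source."""


def _doc_from_fields(
    rec_id: str,
    authors: list[str],
    journal: str,
    year: str | int,
    title: str,
    abstract: str,
    tokens: list[str],
    position: str,
) -> Document | None:
    """Validate mandatory fields; return None (reported drop) if any missing."""
    authors = [_norm(a) for a in authors if _norm(a)]
    journal = _norm(str(journal))
    tokens = [_norm(t) for t in tokens if _norm(t)]
    try:
        year_i = int(year)
    except (TypeError, ValueError):
        year_i = 0
    missing = []
    if not _norm(str(rec_id)):
        missing.append("id")
    if not authors:
        missing.append("authors")
    if not journal:
        missing.append("journal")
    if not (1000 <= year_i <= 9999):
        missing.append("year")
    if missing:
        logger.warning("dropping record at %s: missing %s", position, ", ".join(missing))
        return None
    return Document(
        id=_norm(str(rec_id)),
        authors=authors,
        journal=journal,
        year=year_i,
        title=title or "",
        abstract=abstract or "",
        tokens=tokens,
    )


def _read_tabular(source) -> tuple[list[Document], int]:
    docs: list[Document] = []
    dropped = 0
    for lineno, raw in enumerate(source, start=1):
        if isinstance(raw, bytes):
            raw = raw.decode("utf-8")
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split(FIELD_SEP)
        if len(parts) != 7:
            raise RecordError(
                f"tabular record at line {lineno}: expected 7 tab-separated "
                f"fields, got {len(parts)}"
            )
        rec_id, authors, journal, year, title, abstract, keyphrases = parts
        doc = _doc_from_fields(
            rec_id,
            authors.split(LIST_SEP),
            journal,
            year,
            title,
            abstract,
            keyphrases.split(LIST_SEP) if keyphrases.strip() else [],
            position=f"line {lineno}",
        )
        if doc is None:
            dropped += 1
        else:
            docs.append(doc)
    return docs, dropped


def _xml_text(node, path: str) -> str:
    found = node.find(path)
    return "".join(found.itertext()) if found is not None else ""


def _read_medline_xml(
    source, keyphrases: Mapping[str, Sequence[str]] | None
) -> tuple[list[Document], int]:
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise RecordError(f"malformed MEDLINE XML: {exc}") from exc
    docs: list[Document] = []
    dropped = 0
    articles = tree.findall(".//PubmedArticle")
    for pos, art in enumerate(articles, start=1):
        pmid = _xml_text(art, ".//MedlineCitation/PMID")
        authors = []
        for au in art.findall(".//AuthorList/Author"):
            last = _xml_text(au, "LastName")
            fore = _xml_text(au, "ForeName")
            coll = _xml_text(au, "CollectiveName")
            name = f"{last} {fore}".strip() or coll
            if name:
                authors.append(name)
        journal = _xml_text(art, ".//Article/Journal/Title")
        year = _xml_text(art, ".//Article/Journal/JournalIssue/PubDate/Year")
        if not year:
            year = _xml_text(art, ".//Article/Journal/JournalIssue/PubDate/MedlineDate")[:4]
        title = _xml_text(art, ".//Article/ArticleTitle")
        abstract = " ".join(
            "".join(ab.itertext()) for ab in art.findall(".//Abstract/AbstractText")
        ).strip()
        toks: list[str] = [
            "".join(k.itertext()) for k in art.findall(".//KeyphraseList/Keyphrase")
        ]
        if not toks:
            toks = ["".join(k.itertext()) for k in art.findall(".//KeywordList/Keyword")]
        if not toks and keyphrases is not None:
            toks = list(keyphrases.get(pmid, []))
        doc = _doc_from_fields(
            pmid, authors, journal, year, title, abstract, toks,
            position=f"PubmedArticle #{pos}",
        )
        if doc is None:
            dropped += 1
        else:
            docs.append(doc)
    return docs, dropped


def read_records(
    source,
    format: str = "tabular",
    keyphrases: Mapping[str, Sequence[str]] | None = None,
    return_dropped: bool = False,
):
    """Read bibliographic records from a path, file object, or byte stream.

    Records missing a mandatory field (id, journal, 4-digit year, at least one
    author) are logged and dropped. ``keyphrases`` optionally supplies a
    sidecar id → keyphrase-list map for XML sources without an inline
    keyphrase element.

    Returns the document list, or ``(documents, n_dropped)`` when
    ``return_dropped`` is true.
    """
    if isinstance(source, (str, bytes)) and format == "tabular" and isinstance(source, bytes):
        source = io.StringIO(source.decode("utf-8"))
    close = False
    if isinstance(source, str):
        source = open(source, "rb")
        close = True
    try:
        if format == "tabular":
            if isinstance(source, io.BufferedIOBase) or (
                hasattr(source, "mode") and "b" in getattr(source, "mode", "")
            ):
                source = io.TextIOWrapper(source, encoding="utf-8")
            docs, dropped = _read_tabular(source)
        elif format == "medline-xml":
            docs, dropped = _read_medline_xml(source, keyphrases)
        else:
            raise ValueError(f"unknown record format {format!r}")
    finally:
        if close:
            source.close()
    return (docs, dropped) if return_dropped else docs


def write_tabular(docs: Iterable[Document], path) -> None:
    """Write documents in the tabular dialect (inverse of ``read_records``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                FIELD_SEP.join(
                    [
                        d.id,
                        LIST_SEP.join(d.authors),
                        d.journal,
                        str(d.year),
                        d.title.replace(FIELD_SEP, " "),
                        d.abstract.replace(FIELD_SEP, " "),
                        LIST_SEP.join(d.tokens),
                    ]
                )
                + "\n"
            )


def filter_abstracts(docs: Sequence[Document]) -> list[Document]:
    """Keep only documents with a non-empty abstract, order preserved."""
    return [d for d in docs if d.abstract.strip()]


def slice_periods(
    docs: Sequence[Document],
    boundaries: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
) -> PeriodPartition:
    """Assign each document to the unique inclusive year range containing it.

    Documents falling outside every range are excluded and counted.
    Overlapping ranges raise ``ValueError``.
    """
    bounds = [(int(lo), int(hi)) for lo, hi in boundaries]
    for lo, hi in bounds:
        if lo > hi:
            raise ValueError(f"invalid period ({lo}, {hi})")
    ordered = sorted(bounds)
    for (_, hi_prev), (lo_next, _) in zip(ordered, ordered[1:]):
        if lo_next <= hi_prev:
            raise ValueError("period ranges overlap")
    per_slice: dict[int, list[Document]] = {i: [] for i in range(len(bounds))}
    excluded = 0
    for doc in docs:
        for i, (lo, hi) in enumerate(bounds):
            if lo <= doc.year <= hi:
                per_slice[i].append(doc)
                break
        else:
            excluded += 1
    return PeriodPartition(
        boundaries=bounds,
        slices={i: Corpus(ds) for i, ds in per_slice.items()},
        n_excluded=excluded,
    )


def ratio_table(
    counts: Mapping[str, int] | pd.Series, order: str = "count"
) -> pd.DataFrame:
    """Percentage-share table from pre-tabulated group counts.

    ``order`` is ``"count"`` (descending, ties alphabetical) or ``"group"``
    (chronological/lexicographic). Shares are rounded to two decimals.
    """
    s = pd.Series(dict(counts)) if not isinstance(counts, pd.Series) else counts
    table = s.rename_axis("group").reset_index(name="count")
    if order == "count":
        table = table.sort_values(
            ["count", "group"], ascending=[False, True], kind="mergesort"
        )
    elif order == "group":
        table = table.sort_values("group", key=lambda c: c.astype(str), kind="mergesort")
    else:
        raise ValueError(f"unknown ordering {order!r}")
    table["ratio_pct"] = (100.0 * table["count"] / int(s.sum())).round(2)
    return table.reset_index(drop=True)


def corpus_statistics(
    docs: Sequence[Document],
    group_by: str = "journal",
    boundaries: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Count documents per journal, year, or period with percentage shares.

    Ratio is ``100 * count / total`` rounded to two decimals. Journal tables
    are ranked by count descending (ties alphabetical); year and period
    tables are chronological.
    """
    if group_by == "journal":
        keys = [d.journal for d in docs]
    elif group_by == "year":
        keys = [d.year for d in docs]
    elif group_by == "period":
        labels = {i: f"{lo}-{hi}" for i, (lo, hi) in enumerate(boundaries)}
        keys = []
        for d in docs:
            for i, (lo, hi) in enumerate(boundaries):
                if lo <= d.year <= hi:
                    keys.append(labels[i])
                    break
            else:
                keys.append("outside")
        # chronological ordering uses first year of the label
    else:
        raise ValueError(f"unknown grouping {group_by!r}")
    counts = pd.Series(keys, dtype=object).value_counts()
    total = int(counts.sum())
    table = counts.rename_axis(group_by).reset_index(name="count")
    if group_by == "journal":
        table = table.sort_values(
            ["count", "journal"], ascending=[False, True], kind="mergesort"
        )
    else:
        table = table.sort_values(group_by, key=lambda s: s.astype(str), kind="mergesort")
    table["ratio_pct"] = (100.0 * table["count"] / total).round(2)
    return table.reset_index(drop=True)
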