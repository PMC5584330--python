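"""RDF export: reconstructing triples from the wiki page model.

Each fact on each page becomes one triple.  With ``origuris`` on (the
default), the Equivalent-URI links recorded at import time restore the
*original* subject, predicate and object URIs, which is what makes a full
import→export cycle lossless.  With it off, wiki-minted URIs of the form
``<base>/Special:URIResolver/<title>`` are emitted instead, mimicking
SMW's internal resource URIs.

An export can also carry the wiki's own bookkeeping (Equivalent-URI links,
property datatypes, modification dates) as additional triples; an export
is then a strict superset of what was imported.  ``filter_metadata`` strips
exactly that bookkeeping, so the round-trip consistency check compares only
the triples that were imported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from urllib.parse import quote

from .pages import WikiPage
from .rdf_io import IRI, Literal, PrefixMap, Term, Triple, TripleSet, XSD
from .titles import TitleIndex, WikiTitle

__all__ = [
    "ExportOptions",
    "export_rdf",
    "filter_metadata",
    "mint_uri",
    "METADATA_PREDICATES",
    "SWIVT",
    "OWL_SAMEAS",
]

SWIVT = "http://semantic-mediawiki.org/swivt/1.0#"
OWL_SAMEAS = "http://www.w3.org/2002/07/owl#sameAs"
MODIFICATION_DATE = SWIVT + "wikiPageModificationDate"
CREATION_DATE = SWIVT + "creationDate"
DISPLAY_TITLE = SWIVT + "wikiPageDisplayTitle"
SPECIAL_TYPE = SWIVT + "type"

#: Predicates the wiki adds on its own; removable with :func:`filter_metadata`.
METADATA_PREDICATES = frozenset(
    {OWL_SAMEAS, MODIFICATION_DATE, CREATION_DATE, DISPLAY_TITLE, SPECIAL_TYPE}
)

DEFAULT_RESOLVER_BASE = "http://localhost/wiki"
_EXPORT_TIMESTAMP = "1970-01-01T00:00:00Z"


@dataclass(frozen=True)
class ExportOptions:
    origuris: bool = True
    format: str = "ntriples"
    include_metadata: bool = False
    resolver_base: str = DEFAULT_RESOLVER_BASE

    def __post_init__(self) -> None:
        if self.format not in ("ntriples", "turtle"):
            raise ValueError(f"unsupported export format: {self.format!r}")


def mint_uri(title: WikiTitle, base: str = DEFAULT_RESOLVER_BASE) -> IRI:
    """SMW-style internal URI for a page: spaces become underscores, the
    rest is percent-encoded under ``<base>/Special:URIResolver/``."""
    slug = quote(title.full.replace(" ", "_"), safe="")
    return IRI(f"{base}/Special:URIResolver/{slug}")


def _subject_uri(page: WikiPage, opts: ExportOptions) -> IRI:
    if opts.origuris:
        if page.equivalent_uri:
            return IRI(page.equivalent_uri)
        warnings.warn(
            f"page {page.title.full!r} has no equivalent URI; "
            "emitting a wiki-minted URI instead",
            stacklevel=3,
        )
    return mint_uri(page.title, opts.resolver_base)


def _term_uri(title: WikiTitle, index: TitleIndex, opts: ExportOptions) -> IRI:
    if opts.origuris:
        uri = index.get_uri(title)
        if uri is not None and not uri.startswith("urn:rdfwikiforge:reserved:"):
            return IRI(uri)
        warnings.warn(
            f"title {title.full!r} has no equivalent URI; "
            "emitting a wiki-minted URI instead",
            stacklevel=3,
        )
    return mint_uri(title, opts.resolver_base)


def export_rdf(
    pages: list[WikiPage],
    index: TitleIndex,
    opts: ExportOptions | None = None,
    prefixes: PrefixMap | None = None,
) -> TripleSet:
    """Turn wiki pages back into a :class:`TripleSet`.

    Every fact yields a triple; pages whose facts are packed in a template
    call export identically to unpacked ones (the model keeps the facts).
    Equivalent-URI links and type annotations are consumed to restore URIs;
    they are emitted as additional metadata triples only when
    ``opts.include_metadata`` is set, along with a (fixed) modification
    date per imported page.
    """
    opts = opts or ExportOptions()
    triples: list[Triple] = []
    for page in sorted(pages, key=lambda p: p.title):
        if not page.facts and not opts.include_metadata:
            continue
        subject = _subject_uri(page, opts)
        for fact in page.facts:
            predicate = _term_uri(fact.property, index, opts)
            obj: Term
            if isinstance(fact.value, WikiTitle):
                obj = _term_uri(fact.value, index, opts)
            else:
                obj = fact.value
            triples.append(Triple(subject, predicate, obj))
        if opts.include_metadata:
            if page.equivalent_uri:
                triples.append(
                    Triple(
                        subject,
                        IRI(OWL_SAMEAS),
                        mint_uri(page.title, opts.resolver_base),
                    )
                )
            triples.append(
                Triple(
                    subject,
                    IRI(MODIFICATION_DATE),
                    Literal(_EXPORT_TIMESTAMP, datatype=IRI(XSD + "dateTime")),
                )
            )
            if page.smw_type:
                triples.append(
                    Triple(subject, IRI(SPECIAL_TYPE), Literal(page.smw_type))
                )
    return TripleSet(triples, prefixes or PrefixMap())


def filter_metadata(
    ts: TripleSet, predicates: frozenset[str] = METADATA_PREDICATES
) -> TripleSet:
    """Drop the wiki's own bookkeeping triples (modification/creation dates,
    display titles, Equivalent-URI links, auto-added property types) so a
    consistency check sees only the imported data.  The predicate set is
    explicit and overridable."""
    return TripleSet(
        (t for t in ts if t.predicate.value not in predicates), ts.prefixes
    )
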