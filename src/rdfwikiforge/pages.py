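"""From per-subject triple groups to a wiki page structure.

Each subject resource becomes one :class:`WikiPage`; its predicate–object
pairs become property–value facts; predicates become Property-namespace
pages annotated with an inferred SMW datatype; resources that only ever
appear as objects still get (empty) pages so links never dangle.  Every
imported page carries its original URI as ``equivalent_uri`` — the key that
makes the later RDF export lossless.

Typed subjects (``rdf:type``) can additionally have their facts packed into
an auto-generated template call, one template per type, giving entities of
the same class a uniform page layout.  ``rdf:type`` statements are also kept
as ordinary facts (property "Rdf type") so export reconstructs them.

Imports can run in chunks with a restartable offset, and re-imports merge
facts in place without disturbing manual edits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Union

from .rdf_io import (
    IRI,
    Literal,
    PrefixMap,
    RDF_TYPE,
    Term,
    Triple,
    TripleSet,
    XSD,
    aggregate_by_subject,
)
from .titles import (
    Namespace,
    ResolverConfig,
    TitleIndex,
    WikiTitle,
    disambiguate,
    resolve_title,
    sanitize_title,
)

__all__ = [
    "Fact",
    "WikiPage",
    "TemplateSpec",
    "TemplateCall",
    "ImportOptions",
    "MergeConflictError",
    "build_pages",
    "infer_property_type",
    "synthesize_templates",
    "chunk_stream",
    "merge_pages",
    "WikiSite",
    "EQUIVALENT_URI_PROPERTY",
    "HAS_TYPE_PROPERTY",
]

# Special SMW properties emitted by the import itself.  Their names are
# claimed in the title index under sentinel URIs so no data property can
# shadow them.
EQUIVALENT_URI_PROPERTY = "Equivalent URI"
HAS_TYPE_PROPERTY = "Has type"
_RESERVED = {
    "urn:rdfwikiforge:reserved:equivalent-uri": WikiTitle(
        Namespace.PROPERTY, EQUIVALENT_URI_PROPERTY
    ),
    "urn:rdfwikiforge:reserved:has-type": WikiTitle(Namespace.PROPERTY, HAS_TYPE_PROPERTY),
}


FactValue = Union[WikiTitle, Literal]


@dataclass(frozen=True)
class Fact:
    """One property–value pair on a page.  The value is either a link to
    another page (for URI objects) or a literal kept verbatim."""

    property: WikiTitle
    value: FactValue

    def sort_key(self) -> tuple[str, str, str]:
        if isinstance(self.value, WikiTitle):
            return (self.property.name, "P", self.value.full)
        return (self.property.name, "L", self.value.nt())


def _sorted_facts(facts: Iterable[Fact]) -> list[Fact]:
    return sorted(set(facts), key=Fact.sort_key)


@dataclass
class WikiPage:
    title: WikiTitle
    facts: list[Fact] = field(default_factory=list)
    equivalent_uri: str | None = None
    free_text: str = ""
    template_call: "TemplateCall | None" = None
    smw_type: str | None = None

    def __post_init__(self) -> None:
        self.facts = _sorted_facts(self.facts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WikiPage):
            return NotImplemented
        return (
            self.title == other.title
            and set(self.facts) == set(other.facts)
            and self.equivalent_uri == other.equivalent_uri
            and self.free_text == other.free_text
            and self.template_call == other.template_call
            and self.smw_type == other.smw_type
        )


@dataclass(frozen=True)
class TemplateSpec:
    """An auto-generated template: one per rdf:type, one parameter per
    property used by subjects of that type."""

    name: WikiTitle  # Template namespace
    parameters: tuple[tuple[str, WikiTitle], ...]  # (param name, property title)

    def param_names(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.parameters)


@dataclass
class TemplateCall:
    template: WikiTitle
    arguments: dict[str, str]  # param name -> rendered value(s), ';'-joined

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemplateCall):
            return NotImplemented
        return self.template == other.template and self.arguments == other.arguments


@dataclass(frozen=True)
class ImportOptions:
    """Chunked-import controls: ``chunksize`` triples per batch, ``offset``
    triples skipped at the start (restart support)."""

    chunksize: int = 1000
    offset: int = 0

    def __post_init__(self) -> None:
        if self.chunksize < 1:
            raise ValueError("chunksize must be >= 1")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


class MergeConflictError(ValueError):
    pass


# --- Datatype inference ------------------------------------------------------

_NUMBER_TYPES = frozenset(XSD + t for t in ("integer", "decimal", "double", "float"))
_DATE_TYPES = frozenset(XSD + t for t in ("date", "dateTime"))


def _smw_category(obj: Term) -> str:
    if isinstance(obj, IRI):
        return "Page"
    if obj.language is not None or obj.datatype is None:
        return "Text"
    dt = obj.datatype.value
    if dt in _NUMBER_TYPES:
        return "Number"
    if dt in _DATE_TYPES:
        return "Date"
    if dt == XSD + "boolean":
        return "Boolean"
    if dt == XSD + "anyURI":
        return "URL"
    return "Text"


def _type_from_categories(cats: set[str]) -> str:
    if len(cats) == 1:
        return next(iter(cats))
    if "Page" in cats:
        warnings.warn(
            "property has both page and literal values; typing as Page",
            stacklevel=2,
        )
        return "Page"
    return "Text"


def infer_property_type(objects: list[Term]) -> str:
    """SMW datatype for a property given every value observed for it.

    Homogeneous categories map directly (IRIs → Page; xsd numeric types →
    Number; xsd:date/dateTime → Date; xsd:boolean → Boolean; xsd:anyURI →
    URL; anything else → Text).  Mixed literal categories degrade to Text;
    a mix of pages and literals resolves to Page with a warning, because a
    wiki link is the more structural reading.
    """
    if not objects:
        raise ValueError("cannot infer a property type from zero values")
    return _type_from_categories({_smw_category(o) for o in objects})


# --- Page construction -------------------------------------------------------

def _reserve_special_properties(index: TitleIndex) -> None:
    for uri, title in _RESERVED.items():
        if index.get_title(uri) is None:
            index.register(uri, title)


def build_pages(
    groups: Mapping[IRI, list[Triple]],
    cfg: ResolverConfig,
    index: TitleIndex,
) -> list[WikiPage]:
    """Convert per-subject triple groups into wiki pages.

    Resolution order is fixed for determinism: predicates first (Property
    namespace), then subjects, then remaining object URIs, each set in
    lexicographic order.  ``rdf:type`` maps to the configured type property
    name rather than going through the strategy chain.  Returns subject
    pages, property pages (with inferred SMW type) and empty pages for
    object-only resources, sorted by title.
    """
    _reserve_special_properties(index)
    all_triples = [t for g in groups.values() for t in g]
    predicates = sorted({t.predicate for t in all_triples}, key=lambda i: i.value)
    objects_by_pred: dict[IRI, list[Term]] = {}
    for t in all_triples:
        objects_by_pred.setdefault(t.predicate, []).append(t.object)

    prop_titles: dict[IRI, WikiTitle] = {}
    for p in predicates:
        if p.value == RDF_TYPE:
            existing = index.get_title(RDF_TYPE)
            if existing is None:
                name = sanitize_title(cfg.rdf_type_property_name)
                existing = disambiguate(name, p, index, Namespace.PROPERTY)
            prop_titles[p] = existing
        else:
            prop_titles[p] = resolve_title(
                p, list(groups.get(p, [])), cfg, index, Namespace.PROPERTY
            )

    subjects = sorted(groups, key=lambda i: i.value)
    for s in subjects:
        resolve_title(s, list(groups[s]), cfg, index, Namespace.MAIN)

    object_iris = sorted(
        {t.object for t in all_triples if isinstance(t.object, IRI)},
        key=lambda i: i.value,
    )
    for o in object_iris:
        resolve_title(o, list(groups.get(o, [])), cfg, index, Namespace.MAIN)

    pages: dict[WikiTitle, WikiPage] = {}
    for s in subjects:
        title = index.get_title(s.value)
        assert title is not None
        facts = []
        for t in groups[s]:
            value: FactValue
            if isinstance(t.object, IRI):
                obj_title = index.get_title(t.object.value)
                assert obj_title is not None
                value = obj_title
            else:
                value = t.object
            facts.append(Fact(prop_titles[t.predicate], value))
        if len(facts) > cfg.fact_count_warning_threshold:
            warnings.warn(
                f"page {title.full!r} carries {len(facts)} facts "
                f"(threshold {cfg.fact_count_warning_threshold}); "
                "manual editing may be cumbersome",
                stacklevel=2,
            )
        pages[title] = WikiPage(title=title, facts=facts, equivalent_uri=s.value)

    for p in predicates:
        title = prop_titles[p]
        page = pages.get(title)
        if page is None:
            page = WikiPage(title=title, equivalent_uri=p.value)
            pages[title] = page
        page.smw_type = infer_property_type(objects_by_pred[p])

    for o in object_iris:
        title = index.get_title(o.value)
        assert title is not None
        if title not in pages:
            pages[title] = WikiPage(title=title, equivalent_uri=o.value)

    return [pages[t] for t in sorted(pages)]


# --- Template synthesis ------------------------------------------------------

def synthesize_templates(
    pages: list[WikiPage],
    index: TitleIndex,
    cfg: ResolverConfig,
) -> tuple[list[TemplateSpec], list[WikiPage]]:
    """Generate one template per rdf:type and pack typed pages' facts into
    calls to it.

    A page is "typed" when it carries a type fact (property named per
    ``cfg.rdf_type_property_name``) with a page value; that value's title
    names the template.  Each spec gets one parameter per property used by
    any page of the type (sorted union).  Multi-valued properties join
    their rendered values with ``;`` — template expansion splits them back,
    so packing loses nothing.  Pages with several types call the template
    of the lexicographically first type.  Untyped pages are left untouched.
    """
    from . import wikitext  # local import: wikitext depends on these types

    type_prop = sanitize_title(cfg.rdf_type_property_name)
    pages_by_type: dict[WikiTitle, list[WikiPage]] = {}
    page_types: dict[int, list[WikiTitle]] = {}
    for page in pages:
        types = sorted(
            f.value
            for f in page.facts
            if f.property.name == type_prop and isinstance(f.value, WikiTitle)
        )
        if types:
            page_types[id(page)] = types
            for ty in types:
                pages_by_type.setdefault(ty, []).append(page)

    specs: list[TemplateSpec] = []
    spec_by_type: dict[WikiTitle, TemplateSpec] = {}
    for ty in sorted(pages_by_type):
        props: dict[str, WikiTitle] = {}
        for page in pages_by_type[ty]:
            for f in page.facts:
                props[f.property.name] = f.property
        spec = TemplateSpec(
            name=WikiTitle(Namespace.TEMPLATE, ty.name),
            parameters=tuple((name, props[name]) for name in sorted(props)),
        )
        specs.append(spec)
        spec_by_type[ty] = spec

    for page in pages:
        types = page_types.get(id(page))
        if not types:
            continue
        spec = spec_by_type[types[0]]
        by_prop: dict[str, list[str]] = {}
        for f in page.facts:
            by_prop.setdefault(f.property.name, []).append(
                wikitext.render_fact_value(f.value)
            )
        arguments = {
            param: ";".join(by_prop[param])
            for param, _ in spec.parameters
            if param in by_prop
        }
        page.template_call = TemplateCall(template=spec.name, arguments=arguments)

    return specs, pages


# --- Chunking & merging ------------------------------------------------------

def chunk_stream(ts: TripleSet, opts: ImportOptions) -> Iterator[TripleSet]:
    """Yield consecutive chunks of at most ``chunksize`` triples in canonical
    order, after skipping the first ``offset`` triples.  An offset beyond the
    set yields nothing."""
    triples = ts.triples[opts.offset:]
    for i in range(0, len(triples), opts.chunksize):
        yield TripleSet(triples[i : i + opts.chunksize], ts.prefixes)


def merge_pages(existing: list[WikiPage], incoming: list[WikiPage]) -> list[WikiPage]:
    """Update facts in place without overwriting manual changes.

    Pages are matched by ``equivalent_uri``; incoming facts are appended
    only when absent (set union), existing free text and manually added
    facts stay untouched, and nothing is ever deleted (removal detection is
    out of scope).  If the union changed a page's facts, its template call
    is dropped — it is re-synthesized at render time.  Matching URIs bound
    to different titles raise :class:`MergeConflictError`.
    """
    out: dict[WikiTitle, WikiPage] = {}
    by_uri: dict[str, WikiPage] = {}
    for page in existing:
        copy = WikiPage(
            title=page.title,
            facts=list(page.facts),
            equivalent_uri=page.equivalent_uri,
            free_text=page.free_text,
            template_call=page.template_call,
            smw_type=page.smw_type,
        )
        out[copy.title] = copy
        if copy.equivalent_uri:
            by_uri[copy.equivalent_uri] = copy

    for inc in incoming:
        target = by_uri.get(inc.equivalent_uri) if inc.equivalent_uri else out.get(inc.title)
        if target is None:
            copy = WikiPage(
                title=inc.title,
                facts=list(inc.facts),
                equivalent_uri=inc.equivalent_uri,
                free_text=inc.free_text,
                template_call=inc.template_call,
                smw_type=inc.smw_type,
            )
            if copy.title in out:
                raise MergeConflictError(
                    f"title {copy.title.full!r} exists with a different "
                    f"equivalent URI than <{inc.equivalent_uri}>"
                )
            out[copy.title] = copy
            if copy.equivalent_uri:
                by_uri[copy.equivalent_uri] = copy
            continue
        if target.title != inc.title:
            raise MergeConflictError(
                f"<{inc.equivalent_uri}> bound to both {target.title.full!r} "
                f"and {inc.title.full!r}"
            )
        before = set(target.facts)
        union = _sorted_facts(list(target.facts) + list(inc.facts))
        if set(union) != before:
            target.facts = union
            target.template_call = None
        if target.smw_type is None:
            target.smw_type = inc.smw_type

    return [out[t] for t in sorted(out)]


# --- Site: the end-to-end import surface -------------------------------------

class WikiSite:
    """An in-memory wiki: pages, the URI↔title index and resolver config.

    Imports *accumulate* triples; the page structure is (re)built lazily
    from the full accumulated graph the next time it is accessed.  Two
    consequences, both deliberate: a page's title reflects everything the
    wiki has ever been told about its resource (a label arriving in a later
    chunk still names the page), and the final site is a pure function of
    the set of imported triples — independent of how the import was split
    into chunks or batches, and idempotent under re-import.

    Manually created or edited pages live in an overlay.  Rebuilds seed the
    title index from the overlay's Equivalent-URI links (an existing page
    for a URI is always reused) and merge overlay content via
    :func:`merge_pages`, so manual facts and free text survive re-imports.
    """

    def __init__(self, cfg: ResolverConfig | None = None):
        self.cfg = cfg or ResolverConfig()
        self.index = TitleIndex()
        self._store = TripleSet()
        self._overlay: dict[WikiTitle, WikiPage] = {}
        self._pages: dict[WikiTitle, WikiPage] = {}
        self._dirty = False
        _reserve_special_properties(self.index)

    @property
    def pages(self) -> dict[WikiTitle, WikiPage]:
        self._ensure_built()
        return self._pages

    @property
    def imported_triples(self) -> TripleSet:
        return self._store

    def import_triples(self, ts: TripleSet) -> int:
        """Ingest one (chunk of a) triple set; returns triples taken in."""
        self._store = self._store.union(ts)
        self._dirty = True
        return len(ts)

    def import_chunked(self, ts: TripleSet, opts: ImportOptions) -> int:
        total = 0
        for chunk in chunk_stream(ts, opts):
            total += self.import_triples(chunk)
        return total

    def add_manual_page(self, page: WikiPage) -> None:
        """Record a manually created/edited page; its facts and free text
        take precedence over (and are never overwritten by) imports."""
        self._overlay[page.title] = page
        self._dirty = True

    def _ensure_built(self) -> None:
        if not self._dirty:
            return
        index = TitleIndex()
        _reserve_special_properties(index)
        overlay = [self._overlay[t] for t in sorted(self._overlay)]
        for p in overlay:
            if p.equivalent_uri:
                index.register(p.equivalent_uri, p.title)
        cfg = ResolverConfig(
            label_properties=self.cfg.label_properties,
            prefixes=self.cfg.prefixes.merged(self._store.prefixes),
            namespace_separator=self.cfg.namespace_separator,
            rdf_type_property_name=self.cfg.rdf_type_property_name,
            fact_count_warning_threshold=self.cfg.fact_count_warning_threshold,
        )
        built = build_pages(aggregate_by_subject(self._store), cfg, index)
        merged = merge_pages(overlay, built)
        self._pages = {p.title: p for p in merged}
        self.index = index
        self._dirty = False

    def page_list(self) -> list[WikiPage]:
        self._ensure_built()
        return [self._pages[t] for t in sorted(self._pages)]

    def synthesize(self) -> list[TemplateSpec]:
        specs, _ = synthesize_templates(self.page_list(), self.index, self.cfg)
        return specs

    def to_dump(self, timestamp: str | None = None, templates: bool = True):
        """Render every page (template pages included) into a
        :class:`~rdfwikiforge.dump_xml.DumpDocument`."""
        from . import dump_xml, wikitext

        specs = self.synthesize() if templates else []
        rendered = [wikitext.render_template_page(s) for s in specs]
        rendered += [wikitext.render_page(p, specs) for p in self.page_list()]
        kwargs = {} if timestamp is None else {"timestamp": timestamp}
        return dump_xml.DumpDocument(pages=rendered, **kwargs)

    @classmethod
    def from_dump(cls, doc, cfg: ResolverConfig | None = None) -> "WikiSite":
        """Reconstruct a site from a dump: template pages are parsed first
        to recover the specs, then every other page; Equivalent-URI links
        rebuild the title index.  The dump's pages become existing wiki
        state (overlay), so a later import merges into them in place."""
        from . import wikitext

        site = cls(cfg)
        specs = []
        others = []
        for r in doc.pages:
            if r.title.namespace == Namespace.TEMPLATE:
                spec = wikitext.parse_template_page(r)
                if spec is not None:
                    specs.append(spec)
                continue
            others.append(r)
        for r in others:
            site.add_manual_page(wikitext.parse_page(r, specs))
        return site
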