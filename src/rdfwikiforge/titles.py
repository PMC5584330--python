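"""URI → wiki page title resolution.

Every RDF resource that becomes a page, property or template needs a
human-friendly, MediaWiki-legal, unique title.  Resolution tries an ordered
chain of strategies and stops at the first that yields a non-empty name:

0. the URI is already in the title index (e.g. bound by an earlier chunk or
   an Equivalent-URI link on an existing page) — reuse that title;
1. the value of a label-like property on the resource (``dc:title`` by
   default, then ``rdfs:label``, ``skos:prefLabel``, ``foaf:name``;
   configurable), smallest value lexicographically when there are several;
2. a CURIE formed from a namespace abbreviation declared in the dataset
   (longest namespace wins), written with a space separator because ``:``
   is MediaWiki namespace syntax;
3. the local part of the URI — the substring after the last ``/`` or ``#``.

The winning raw name is sanitized to title legality, disambiguated with a
numeric `` (k)`` suffix on collision, and registered in the bidirectional
URI↔title index, which stays an exact bijection at all times.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import yaml

from .rdf_io import IRI, Literal, PrefixMap, Triple

__all__ = [
    "Namespace",
    "WikiTitle",
    "TitleIndex",
    "ResolverConfig",
    "TitleResolutionError",
    "resolve_title",
    "abbreviate_uri",
    "local_part",
    "sanitize_title",
    "disambiguate",
]

DC_TITLE = "http://purl.org/dc/elements/1.1/title"
RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
SKOS_PREF_LABEL = "http://www.w3.org/2004/02/skos/core#prefLabel"
FOAF_NAME = "http://xmlns.com/foaf/0.1/name"

DEFAULT_LABEL_PROPERTIES = (DC_TITLE, RDFS_LABEL, SKOS_PREF_LABEL, FOAF_NAME)


class Namespace(enum.IntEnum):
    """MediaWiki namespaces used by the converter, with their standard
    numeric ids (Property is SMW's)."""

    MAIN = 0
    TEMPLATE = 10
    PROPERTY = 102


_NS_PREFIX = {Namespace.MAIN: "", Namespace.TEMPLATE: "Template:", Namespace.PROPERTY: "Property:"}


@dataclass(frozen=True)
class WikiTitle:
    namespace: Namespace
    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("wiki title name must be non-empty")
        if len(self.name.encode("utf-8")) > 255:
            raise ValueError("wiki title exceeds 255 bytes")

    @property
    def full(self) -> str:
        """The full page name including namespace prefix, e.g. ``Property:PKa``."""
        return _NS_PREFIX[self.namespace] + self.name

    @classmethod
    def from_full(cls, full: str, namespace: Namespace | None = None) -> "WikiTitle":
        if namespace is not None:
            prefix = _NS_PREFIX[namespace]
            name = full[len(prefix):] if prefix and full.startswith(prefix) else full
            return cls(namespace, name)
        for ns, prefix in _NS_PREFIX.items():
            if prefix and full.startswith(prefix):
                return cls(ns, full[len(prefix):])
        return cls(Namespace.MAIN, full)

    def __str__(self) -> str:
        return self.full

    def __lt__(self, other: "WikiTitle") -> bool:
        return (int(self.namespace), self.name) < (int(other.namespace), other.name)


class TitleResolutionError(ValueError):
    def __init__(self, uri: str):
        self.uri = uri
        super().__init__(f"no title strategy produced a usable name for <{uri}>")


class TitleIndex:
    """Bidirectional URI↔title registry.

    Maintains the invariant that ``uri_to_title`` and ``title_to_uri`` are
    exact inverses: every registration is checked on both sides, so a URI
    can never acquire two titles nor a title two URIs.
    """

    def __init__(self) -> None:
        self.uri_to_title: dict[str, WikiTitle] = {}
        self.title_to_uri: dict[WikiTitle, str] = {}
        self._next_suffix: dict[WikiTitle, int] = {}

    def register(self, uri: str, title: WikiTitle) -> None:
        bound = self.uri_to_title.get(uri)
        if bound is not None:
            if bound != title:
                raise ValueError(f"<{uri}> already bound to {bound.full!r}")
            return
        holder = self.title_to_uri.get(title)
        if holder is not None and holder != uri:
            raise ValueError(f"title {title.full!r} already bound to <{holder}>")
        self.uri_to_title[uri] = title
        self.title_to_uri[title] = uri

    def get_title(self, uri: str) -> WikiTitle | None:
        return self.uri_to_title.get(uri)

    def get_uri(self, title: WikiTitle) -> str | None:
        return self.title_to_uri.get(title)

    def __len__(self) -> int:
        return len(self.uri_to_title)

    def is_bijection(self) -> bool:
        return all(
            self.title_to_uri.get(t) == u for u, t in self.uri_to_title.items()
        ) and len(self.uri_to_title) == len(self.title_to_uri)

    def to_tsv(self) -> str:
        """Two-column audit dump (URI <TAB> full title), sorted by URI."""
        lines = [f"{u}\t{t.full}" for u, t in sorted(self.uri_to_title.items())]
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class ResolverConfig:
    """Settings that steer title resolution and fact naming."""

    label_properties: tuple[str, ...] = DEFAULT_LABEL_PROPERTIES
    prefixes: PrefixMap = field(default_factory=PrefixMap)
    namespace_separator: str = " "
    rdf_type_property_name: str = "Rdf type"
    fact_count_warning_threshold: int = 1000

    @classmethod
    def from_yaml(cls, text: str) -> "ResolverConfig":
        data = yaml.safe_load(text) or {}
        kwargs = {}
        if "label_properties" in data:
            kwargs["label_properties"] = tuple(data["label_properties"])
        if "prefixes" in data:
            kwargs["prefixes"] = PrefixMap(dict(data["prefixes"]))
        for key in ("namespace_separator", "rdf_type_property_name",
                    "fact_count_warning_threshold"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


# --- Strategy primitives -----------------------------------------------------

def local_part(uri: IRI) -> str:
    """Substring after the last ``/`` or ``#`` (whichever occurs later);
    empty when the URI ends with the separator."""
    value = uri.value
    cut = max(value.rfind("/"), value.rfind("#"))
    return value[cut + 1:] if cut >= 0 else value


def abbreviate_uri(uri: IRI, prefixes: PrefixMap, separator: str = " ") -> str | None:
    """CURIE-style shortening: replace the longest declared namespace that
    prefixes *uri* by its label plus *separator*; None when nothing matches
    or the remainder would be empty."""
    m = prefixes.longest_match(uri.value)
    if m is None:
        return None
    label, ns = m
    remainder = uri.value[len(ns):]
    return f"{label}{separator}{remainder}"


# MediaWiki's illegal title characters plus ';' and '=', which the fact /
# template-argument syntax reserves (multi-value separator, param=value).
_FORBIDDEN = set("#<>[]|{};=")
_WS_RE = re.compile(r"\s+")


def sanitize_title(raw: str) -> str:
    """Make a raw name MediaWiki-title legal.

    Forbidden characters (``# < > [ ] | { }`` and non-whitespace control
    characters) become ``-``; colon runs collapse to a single colon (``::``
    is the fact-syntax separator); underscores become spaces; whitespace
    runs collapse to single spaces; the result is trimmed, first-letter
    uppercased and truncated to 255 UTF-8 bytes on a character boundary.
    Idempotent; may return "" (the caller treats that as strategy failure).
    """
    raw = re.sub(r":{2,}", ":", raw)
    out = []
    for ch in raw:
        if ch in _FORBIDDEN or (ord(ch) < 0x20 and not ch.isspace()) or ch == "\x7f":
            out.append("-")
        elif ch == "_":
            out.append(" ")
        else:
            out.append(ch)
    s = _WS_RE.sub(" ", "".join(out)).strip()
    if s:
        s = s[0].upper() + s[1:]
    while len(s.encode("utf-8")) > 255:
        s = s[:-1]
    return s.strip()


def disambiguate(candidate: str, uri: IRI, index: TitleIndex,
                 namespace: Namespace = Namespace.MAIN) -> WikiTitle:
    """Bind *candidate* (already sanitized, non-empty) to *uri* in *index*,
    appending the smallest free `` (k)`` (k ≥ 2) on collision.  Registration
    is atomic with resolution, so concurrent resolutions in one run can
    never race to the same title."""
    title = WikiTitle(namespace, candidate)
    holder = index.get_uri(title)
    if holder is None or holder == uri.value:
        index.register(uri.value, title)
        return title
    # Monotone counter per base name: titles are only ever added, so the
    # first free k is also the smallest.
    k = index._next_suffix.get(title, 2)
    while True:
        suffixed = WikiTitle(namespace, f"{candidate} ({k})")
        if index.get_uri(suffixed) in (None, uri.value):
            index._next_suffix[title] = k + 1
            index.register(uri.value, suffixed)
            return suffixed
        k += 1


def _label_candidate(subject_triples: list[Triple], cfg: ResolverConfig) -> str | None:
    for prop in cfg.label_properties:
        values = sorted(
            t.object.lexical
            for t in subject_triples
            if t.predicate.value == prop and isinstance(t.object, Literal)
        )
        if values:
            return values[0]
    return None


def resolve_title(
    uri: IRI,
    subject_triples: list[Triple],
    cfg: ResolverConfig,
    index: TitleIndex,
    namespace: Namespace = Namespace.MAIN,
) -> WikiTitle:
    """Resolve *uri* to a registered :class:`WikiTitle` via the strategy
    chain (index reuse → label property → CURIE → local part).

    *subject_triples* are the triples whose subject is *uri* (empty for
    object-only resources).  The first strategy whose sanitized result is
    non-empty wins; the result is disambiguated and registered before
    returning.  Raises :class:`TitleResolutionError` when every strategy
    sanitizes to empty.
    """
    existing = index.get_title(uri.value)
    if existing is not None:
        return existing
    candidates = (
        _label_candidate(subject_triples, cfg),
        abbreviate_uri(uri, cfg.prefixes, cfg.namespace_separator),
        local_part(uri),
    )
    for raw in candidates:
        if raw is None:
            continue
        name = sanitize_title(raw)
        if name:
            return disambiguate(name, uri, index, namespace)
    raise TitleResolutionError(uri.value)
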