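"""RDF terms, triple sets and (de)serialization.

The triple is the unit of everything this package does: import turns triples
into wiki pages, export turns pages back into triples.  N-Triples is the
canonical on-disk format — parsing is line-oriented with precise error
locations and serialization is byte-canonical (sorted, deduplicated), so any
two equal graphs produce identical files.  A pragmatic Turtle subset
(``@prefix``/``@base``, prefixed names, ``;``/``,`` abbreviation, the ``a``
keyword, typed and language-tagged literals) is accepted on input; its
``@prefix`` directives feed the CURIE-based page-title strategy.

Blank nodes are skolemized on input to IRIs under ``urn:bnode:<import-id>:``
so every resource can become an addressable wiki page; the import id is
derived from a hash of the input text, keeping re-parses byte-stable.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Union

import rdflib

__all__ = [
    "IRI",
    "Literal",
    "Triple",
    "TripleSet",
    "PrefixMap",
    "RdfParseError",
    "parse_ntriples",
    "parse_turtle",
    "parse_rdf",
    "write_ntriples",
    "write_turtle",
    "aggregate_by_subject",
    "XSD",
    "RDF_TYPE",
]

XSD = "http://www.w3.org/2001/XMLSchema#"
RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"

_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S*$")


class RdfParseError(ValueError):
    """Malformed RDF input; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class IRI:
    """An absolute IRI."""

    value: str

    def __post_init__(self) -> None:
        if not _IRI_RE.match(self.value):
            raise ValueError(f"not an absolute IRI: {self.value!r}")

    def nt(self) -> str:
        return f"<{self.value}>"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


@dataclass(frozen=True)
class Literal:
    """An RDF literal: lexical form plus optional datatype IRI or language tag.

    Datatype and language are mutually exclusive, as in RDF 1.0 (the
    implicit ``rdf:langString``/``xsd:string`` datatypes are not
    materialized; a plain literal has neither field set).
    """

    lexical: str
    datatype: IRI | None = None
    language: str | None = None

    def __post_init__(self) -> None:
        if self.datatype is not None and self.language is not None:
            raise ValueError("literal cannot carry both datatype and language")

    def nt(self) -> str:
        out = f'"{escape_nt(self.lexical)}"'
        if self.language is not None:
            out += f"@{self.language}"
        elif self.datatype is not None:
            out += f"^^{self.datatype.nt()}"
        return out


Term = Union[IRI, Literal]


@dataclass(frozen=True)
class Triple:
    subject: IRI
    predicate: IRI
    object: Term

    def nt(self) -> str:
        return f"{self.subject.nt()} {self.predicate.nt()} {self.object.nt()} ."

    def sort_key(self) -> tuple[str, str, str]:
        return (self.subject.value, self.predicate.value, self.object.nt())


class PrefixMap:
    """Namespace abbreviations (prefix label -> namespace IRI).

    Drives the CURIE title strategy; longest-namespace match wins when
    several declared namespaces prefix the same IRI.
    """

    def __init__(self, entries: Mapping[str, str] | None = None):
        self._entries: dict[str, str] = {}
        if entries:
            for label, ns in entries.items():
                self.bind(label, ns)

    def bind(self, label: str, namespace: str) -> None:
        if ":" in label:
            raise ValueError(f"prefix label must not contain ':': {label!r}")
        self._entries[label] = namespace

    def items(self) -> Iterable[tuple[str, str]]:
        return sorted(self._entries.items())

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, label: str) -> bool:
        return label in self._entries

    def __getitem__(self, label: str) -> str:
        return self._entries[label]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PrefixMap) and self._entries == other._entries

    def __repr__(self) -> str:
        return f"PrefixMap({self._entries!r})"

    def merged(self, other: "PrefixMap") -> "PrefixMap":
        out = PrefixMap(dict(self._entries))
        for label, ns in other.items():
            out.bind(label, ns)
        return out

    def longest_match(self, iri: str) -> tuple[str, str] | None:
        """Return (label, namespace) of the longest declared namespace that
        is a proper prefix of *iri*, or None."""
        best: tuple[str, str] | None = None
        for label, ns in sorted(self._entries.items()):
            if iri.startswith(ns) and len(ns) < len(iri):
                if best is None or len(ns) > len(best[1]):
                    best = (label, ns)
        return best


class TripleSet:
    """A deduplicated, canonically ordered collection of triples plus the
    prefix map harvested from the source document.

    Equality is set-equality on the triples (prefixes are advisory:
    the same logical graph written in Turtle and N-Triples is equal).
    """

    def __init__(self, triples: Iterable[Triple] = (), prefixes: PrefixMap | None = None):
        self.triples: tuple[Triple, ...] = tuple(
            sorted(set(triples), key=Triple.sort_key)
        )
        self.prefixes = prefixes if prefixes is not None else PrefixMap()

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __contains__(self, t: Triple) -> bool:
        return t in set(self.triples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TripleSet) and set(self.triples) == set(other.triples)

    def __repr__(self) -> str:
        return f"TripleSet({len(self.triples)} triples, {len(self.prefixes)} prefixes)"

    def union(self, other: "TripleSet") -> "TripleSet":
        return TripleSet(
            self.triples + other.triples, self.prefixes.merged(other.prefixes)
        )

    def difference(self, other: "TripleSet") -> "TripleSet":
        rest = set(self.triples) - set(other.triples)
        return TripleSet(rest, self.prefixes)

    def issubset(self, other: "TripleSet") -> bool:
        return set(self.triples) <= set(other.triples)


# --- N-Triples escapes -------------------------------------------------------

_NT_ESCAPES = {"\\": "\\\\", '"': '\\"', "\n": "\\n", "\r": "\\r", "\t": "\\t"}
_NT_UNESCAPE_RE = re.compile(r"\\(u[0-9A-Fa-f]{4}|U[0-9A-Fa-f]{8}|[tbnrf\"'\\])")
_NT_UNESCAPE_MAP = {
    "t": "\t",
    "b": "\b",
    "n": "\n",
    "r": "\r",
    "f": "\f",
    '"': '"',
    "'": "'",
    "\\": "\\",
}


def escape_nt(s: str) -> str:
    out = []
    for ch in s:
        if ch in _NT_ESCAPES:
            out.append(_NT_ESCAPES[ch])
        elif ord(ch) < 0x20:
            out.append("\\u%04X" % ord(ch))
        else:
            out.append(ch)
    return "".join(out)


def unescape_nt(s: str) -> str:
    def repl(m: re.Match) -> str:
        body = m.group(1)
        if body[0] in "uU":
            return chr(int(body[1:], 16))
        return _NT_UNESCAPE_MAP[body]

    return _NT_UNESCAPE_RE.sub(repl, s)


# --- N-Triples parser --------------------------------------------------------

_NT_IRI = r"<([^<>\"\s{}|^`\\]*)>"
_NT_BNODE = r"_:([A-Za-z0-9][A-Za-z0-9._\-]*)"
_NT_LIT = r'"((?:[^"\\]|\\.)*)"(?:@([A-Za-z][A-Za-z0-9\-]*)|\^\^<([^<>"\s]*)>)?'
_NT_LINE_RE = re.compile(
    rf"^(?:{_NT_IRI}|{_NT_BNODE})\s+{_NT_IRI}\s+"
    rf"(?:{_NT_IRI}|{_NT_BNODE}|{_NT_LIT})\s*\.\s*$"
)


def _import_id(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:8]


def _skolem(import_id: str, label: str) -> IRI:
    return IRI(f"urn:bnode:{import_id}:{label}")


def parse_ntriples(text: str) -> TripleSet:
    """Parse N-Triples text into a :class:`TripleSet`.

    Comment lines (``#``) and blank lines are allowed; duplicate statements
    collapse; blank-node labels are skolemized (with a warning reporting the
    count).  Malformed statements raise :class:`RdfParseError` naming the
    1-based line number.
    """
    triples: list[Triple] = []
    import_id = _import_id(text)
    n_bnodes = 0
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _NT_LINE_RE.match(line)
        if not m:
            raise RdfParseError(f"malformed N-Triples statement: {line!r}", lineno)
        (s_iri, s_bn, p_iri, o_iri, o_bn, o_lex, o_lang, o_dt) = m.groups()
        try:
            if s_bn is not None:
                subject = _skolem(import_id, s_bn)
                n_bnodes += 1
            else:
                subject = IRI(unescape_nt(s_iri))
            predicate = IRI(unescape_nt(p_iri))
            obj: Term
            if o_iri is not None:
                obj = IRI(unescape_nt(o_iri))
            elif o_bn is not None:
                obj = _skolem(import_id, o_bn)
                n_bnodes += 1
            else:
                obj = Literal(
                    unescape_nt(o_lex),
                    datatype=IRI(unescape_nt(o_dt)) if o_dt else None,
                    language=o_lang,
                )
        except ValueError as exc:
            raise RdfParseError(str(exc), lineno) from exc
        triples.append(Triple(subject, predicate, obj))
    if n_bnodes:
        warnings.warn(
            f"skolemized {n_bnodes} blank-node occurrence(s) under "
            f"urn:bnode:{import_id}:",
            stacklevel=2,
        )
    return TripleSet(triples)


# --- Turtle subset parser (rdflib-backed) ------------------------------------

_TTL_STRING_RE = re.compile(
    r'"""(?:[^"\\]|\\.|"(?!""))*"""|'
    r"'''(?:[^'\\]|\\.|'(?!''))*'''|"
    r'"(?:[^"\\\n]|\\.)*"|'
    r"'(?:[^'\\\n]|\\.)*'|"
    r"<[^<>\s]*>",
    re.S,
)
_RDFLIB_BNODE_RE = re.compile(r"^n[0-9a-f]{32}b(\d+)$")


def _check_turtle_subset(text: str) -> None:
    """Reject Turtle constructs outside the supported subset.

    Collections ``( ... )`` and anonymous blank-node property lists
    ``[ ... ]`` are not supported: they would silently become skolemized
    structure a wiki user cannot interpret, so they fail loudly instead.
    """
    stripped = _TTL_STRING_RE.sub(lambda m: " " * len(m.group(0)), text)
    for lineno, line in enumerate(stripped.split("\n"), start=1):
        line = line.split("#", 1)[0]
        for col, ch in enumerate(line, start=1):
            if ch == "(":
                raise RdfParseError(
                    f"unsupported Turtle construct: collection '(...)' at column {col}",
                    lineno,
                )
            if ch == "[":
                raise RdfParseError(
                    "unsupported Turtle construct: anonymous blank-node "
                    f"property list '[...]' at column {col}",
                    lineno,
                )


def _from_rdflib_term(term: object, import_id: str) -> Term:
    if isinstance(term, rdflib.BNode):
        m = _RDFLIB_BNODE_RE.match(str(term))
        label = f"b{m.group(1)}" if m else str(term)
        return _skolem(import_id, label)
    if isinstance(term, rdflib.Literal):
        return Literal(
            str(term),
            datatype=IRI(str(term.datatype)) if term.datatype else None,
            language=term.language,
        )
    if isinstance(term, rdflib.URIRef):
        try:
            return IRI(str(term))
        except ValueError as exc:
            raise RdfParseError(str(exc)) from exc
    raise RdfParseError(f"unsupported RDF term: {term!r}")


def parse_turtle(text: str) -> TripleSet:
    """Parse the supported Turtle subset into a :class:`TripleSet`.

    Every ``@prefix`` directive lands in the result's prefix map, where the
    title resolver picks it up for CURIE abbreviation.  Labeled blank nodes
    are skolemized deterministically in parse order; collections and
    anonymous property lists are rejected (see :func:`_check_turtle_subset`).
    """
    _check_turtle_subset(text)
    g = rdflib.Graph(bind_namespaces="none")
    # Literal lexical forms must survive verbatim (round-trip guarantee);
    # rdflib otherwise rewrites e.g. "5.9e-01"^^xsd:double to "0.59".
    saved_normalize = rdflib.NORMALIZE_LITERALS
    rdflib.NORMALIZE_LITERALS = False
    try:
        g.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises plugin-specific subclasses
        line = getattr(exc, "lines", None)
        raise RdfParseError(f"Turtle parse error: {exc}", line or None) from exc
    finally:
        rdflib.NORMALIZE_LITERALS = saved_normalize
    import_id = _import_id(text)
    triples = []
    n_bnodes = 0
    for s, p, o in g:
        subject = _from_rdflib_term(s, import_id)
        predicate = _from_rdflib_term(p, import_id)
        obj = _from_rdflib_term(o, import_id)
        if isinstance(s, rdflib.BNode):
            n_bnodes += 1
        if isinstance(o, rdflib.BNode):
            n_bnodes += 1
        if isinstance(subject, Literal) or isinstance(predicate, Literal):
            raise RdfParseError("literal in subject/predicate position")
        triples.append(Triple(subject, predicate, obj))
    if n_bnodes:
        warnings.warn(
            f"skolemized {n_bnodes} blank-node occurrence(s) under "
            f"urn:bnode:{import_id}:",
            stacklevel=2,
        )
    prefixes = PrefixMap()
    for label, ns in g.namespaces():
        prefixes.bind(str(label), str(ns))
    return TripleSet(triples, prefixes)


def parse_rdf(text: str, fmt: str) -> TripleSet:
    """Dispatch on format name ('ntriples'/'nt' or 'turtle'/'ttl')."""
    fmt = fmt.lower()
    if fmt in ("ntriples", "nt", "n-triples"):
        return parse_ntriples(text)
    if fmt in ("turtle", "ttl"):
        return parse_turtle(text)
    raise ValueError(f"unsupported RDF format: {fmt!r}")


# --- Serialization -----------------------------------------------------------

def write_ntriples(ts: TripleSet) -> str:
    """Canonical N-Triples: one sorted statement per line, trailing newline
    iff non-empty.  ``parse_ntriples(write_ntriples(ts)) == ts``."""
    if not ts.triples:
        return ""
    return "\n".join(t.nt() for t in ts.triples) + "\n"


# PN_LOCAL without escapes: when a namespace remainder falls outside this,
# the full <iri> form is written instead of a prefixed name.
_PN_LOCAL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-]*$")


def _turtle_iri(iri: IRI, prefixes: PrefixMap) -> str:
    m = prefixes.longest_match(iri.value)
    if m is not None:
        label, ns = m
        remainder = iri.value[len(ns):]
        if _PN_LOCAL_RE.match(remainder) and not remainder.endswith("."):
            return f"{label}:{remainder}"
    return iri.nt()


def _turtle_term(term: Term, prefixes: PrefixMap) -> str:
    if isinstance(term, IRI):
        return _turtle_iri(term, prefixes)
    out = f'"{escape_nt(term.lexical)}"'
    if term.language is not None:
        return out + f"@{term.language}"
    if term.datatype is not None:
        return out + f"^^{_turtle_iri(term.datatype, prefixes)}"
    return out


def write_turtle(ts: TripleSet) -> str:
    """Turtle serialization reusing the set's prefix map, so exports stay
    human-readable with the importer's abbreviations.

    Written by hand rather than through a generic serializer because the
    output must preserve every literal's exact lexical form (generic
    Turtle writers abbreviate numeric literals to bare tokens, rewriting
    e.g. ``"1.0e0"^^xsd:double``); ``parse_turtle(write_turtle(ts)) == ts``
    holds lexically, not just by value.  Statements are grouped per subject
    with ``;``/``,`` abbreviation, in canonical order.
    """
    lines = [f"@prefix {label}: <{ns}> ." for label, ns in ts.prefixes.items()]
    if lines:
        lines.append("")
    by_subject: dict[IRI, dict[IRI, list[Term]]] = {}
    for t in ts.triples:  # canonical order
        by_subject.setdefault(t.subject, {}).setdefault(t.predicate, []).append(
            t.object
        )
    for subject, preds in by_subject.items():
        s = _turtle_iri(subject, ts.prefixes)
        pred_parts = []
        for predicate, objects in preds.items():
            p = _turtle_iri(predicate, ts.prefixes)
            o = " , ".join(_turtle_term(obj, ts.prefixes) for obj in objects)
            pred_parts.append(f"{p} {o}")
        lines.append(f"{s} " + " ;\n    ".join(pred_parts) + " .")
    return "\n".join(lines) + ("\n" if lines else "")


def aggregate_by_subject(ts: TripleSet) -> dict[IRI, list[Triple]]:
    """Group triples per subject resource — the unit that becomes one wiki
    page.  Keys come out in lexicographic subject order; within a group,
    triples are sorted by (predicate, object)."""
    groups: dict[IRI, list[Triple]] = {}
    for t in ts.triples:  # already canonically sorted
        groups.setdefault(t.subject, []).append(t)
    return groups
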