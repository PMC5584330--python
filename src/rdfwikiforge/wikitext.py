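"""The SMW wikitext dialect: rendering pages to text and parsing them back.

Both pipeline directions share this layer.  The dialect is deliberately
small and canonical so that ``parse_page(render_page(p))`` is an identity
on the page model:

* one inline fact per line, ``[[Property name::value]]``;
* page values are written as full titles, literal values are escaped and
  always carry a trailing comment marker preserving their RDF typing —
  ``<!--^^xsd:decimal-->`` for XSD datatypes, ``<!--^^<iri>-->`` for other
  datatypes, ``<!--@en-->`` for language tags, ``<!--^^-->`` for plain
  literals.  The marker doubles as the syntactic distinction between link
  and literal, so parsing needs no out-of-band property-type table;
* the page's source URI as ``[[Equivalent URI::<iri>]]``, exactly once on
  every imported page;
* property pages add ``[[Has type::<SMW type>]]``;
* template calls span lines: ``{{Name``, one ``|param=value`` line each,
  ``}}``.  Auto-generated template bodies hold one fact per parameter
  (``[[Prop::{{{param|}}}]]``) so expansion is trivially invertible.

Parsing is total: anything that is not recognized syntax is preserved as
free text (wikis are messy; a page never fails to parse), and ``{{#set:}}``
fact blocks are accepted on input even though rendering never emits them.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .rdf_io import IRI, Literal, XSD
from .pages import (
    EQUIVALENT_URI_PROPERTY,
    Fact,
    FactValue,
    HAS_TYPE_PROPERTY,
    TemplateCall,
    TemplateSpec,
    WikiPage,
)
from .titles import Namespace, WikiTitle

__all__ = [
    "RenderedPage",
    "render_page",
    "parse_page",
    "render_template_page",
    "parse_template_page",
    "render_fact_value",
    "parse_fact_value",
    "escape_literal",
    "unescape_literal",
]


@dataclass(frozen=True)
class RenderedPage:
    title: WikiTitle
    text: str


# --- Literal escaping --------------------------------------------------------

# Characters that could forge fact/template/marker syntax, HTML-entity
# encoded.  '&' is included so unescaping is a true inverse.
_ESCAPE_TABLE = str.maketrans(
    {
        "&": "&#38;",
        "|": "&#124;",
        "[": "&#91;",
        "]": "&#93;",
        "{": "&#123;",
        "}": "&#125;",
        "<": "&#60;",
        ">": "&#62;",
        ";": "&#59;",
        "=": "&#61;",
        "\n": "&#10;",
        "\r": "&#13;",
    }
)
_ENTITY_RE = re.compile(r"&#(\d+);")


def escape_literal(lexical: str) -> str:
    return lexical.translate(_ESCAPE_TABLE)


def unescape_literal(s: str) -> str:
    return _ENTITY_RE.sub(lambda m: chr(int(m.group(1))), s)


# --- Fact values -------------------------------------------------------------

def render_fact_value(value: FactValue) -> str:
    if isinstance(value, WikiTitle):
        return value.full
    lex = escape_literal(value.lexical)
    if value.language is not None:
        return f"{lex}<!--@{value.language}-->"
    if value.datatype is not None:
        dt = value.datatype.value
        if dt.startswith(XSD):
            return f"{lex}<!--^^xsd:{dt[len(XSD):]}-->"
        return f"{lex}<!--^^<{dt}>-->"
    return f"{lex}<!--^^-->"


_VALUE_MARKER_RE = re.compile(
    r"^(?P<lex>.*?)<!--(?:\^\^(?P<dt>[^>]*|<[^>]*>)|@(?P<lang>[A-Za-z][A-Za-z0-9\-]*))-->$",
    re.S,
)


def parse_fact_value(s: str) -> FactValue:
    """Inverse of :func:`render_fact_value`: a trailing typing marker means
    literal, anything else is read as a page title."""
    m = _VALUE_MARKER_RE.match(s)
    if m is None:
        return WikiTitle.from_full(s)
    lex = unescape_literal(m.group("lex"))
    lang = m.group("lang")
    if lang is not None:
        return Literal(lex, language=lang)
    dt = m.group("dt")
    if dt == "":
        return Literal(lex)
    if dt.startswith("xsd:"):
        return Literal(lex, datatype=IRI(XSD + dt[4:]))
    if dt.startswith("<") and dt.endswith(">"):
        return Literal(lex, datatype=IRI(dt[1:-1]))
    raise ValueError(f"unrecognized literal type marker: {dt!r}")


# --- Page rendering ----------------------------------------------------------

def _fact_line(fact: Fact) -> str:
    return f"[[{fact.property.name}::{render_fact_value(fact.value)}]]"


def _call_lines(call: TemplateCall) -> list[str]:
    lines = ["{{" + call.template.name]
    lines += [f"|{param}={value}" for param, value in call.arguments.items()]
    lines.append("}}")
    return lines


def render_page(page: WikiPage, specs: list[TemplateSpec] | None = None) -> RenderedPage:
    """Render a page to wikitext.

    When the page carries a template call, the call replaces the inline
    facts (they are encoded in its arguments); otherwise one sorted fact
    line each.  The Equivalent-URI fact, the property-page type annotation
    and the free text follow, in that order.
    """
    lines: list[str] = []
    if page.template_call is not None:
        lines += _call_lines(page.template_call)
    else:
        lines += [_fact_line(f) for f in page.facts]
    if page.equivalent_uri:
        lines.append(f"[[{EQUIVALENT_URI_PROPERTY}::{page.equivalent_uri}]]")
    if page.smw_type:
        lines.append(f"[[{HAS_TYPE_PROPERTY}::{page.smw_type}]]")
    if page.free_text:
        lines.append(page.free_text)
    return RenderedPage(page.title, "\n".join(lines))


# --- Page parsing ------------------------------------------------------------

_FACT_RE = re.compile(r"^\[\[(?P<prop>[^\[\]|]+?)::(?P<value>.*)\]\]$")
_CALL_OPEN_RE = re.compile(r"^\{\{(?P<name>[^#|{}\n][^|{}\n]*)$")
_CALL_ARG_RE = re.compile(r"^\|(?P<param>[^=|]+)=(?P<value>.*)$")
_SET_RE = re.compile(r"^\{\{#set:(?P<body>.*)\}\}$")


def split_joined_values(joined: str) -> list[str]:
    """Split a ``;``-joined multi-value template argument.

    Escaped literal values contain ``;`` only as HTML-entity terminators
    (``&#124;`` etc.) and sanitized titles contain none at all, so exactly
    the semicolons *outside* entity spans separate values."""
    entity_spans = [m.span() for m in _ENTITY_RE.finditer(joined)]
    pieces = []
    start = 0
    for i, ch in enumerate(joined):
        if ch != ";":
            continue
        if any(a <= i < b for a, b in entity_spans):
            continue
        pieces.append(joined[start:i])
        start = i + 1
    pieces.append(joined[start:])
    return pieces


def _expand_call(
    call: TemplateCall, spec: TemplateSpec
) -> list[Fact]:
    facts = []
    props = dict(spec.parameters)
    for param, joined in call.arguments.items():
        prop = props.get(param)
        if prop is None:
            warnings.warn(
                f"template argument {param!r} has no parameter in "
                f"{spec.name.full!r}; ignored",
                stacklevel=3,
            )
            continue
        for piece in split_joined_values(joined):
            if piece:
                facts.append(Fact(prop, parse_fact_value(piece)))
    return facts


def parse_page(rendered: RenderedPage, specs: list[TemplateSpec] | None = None) -> WikiPage:
    """Parse wikitext back into the page model.

    Inline facts and known template calls become facts (calls are expanded
    through their spec); the Equivalent-URI and Has-type facts land in their
    dedicated fields; every unrecognized line — including calls to unknown
    templates — survives verbatim as free text.  Never raises on arbitrary
    text; malformed fact-like syntax degrades to free text with a warning.
    """
    spec_by_name = {s.name.name: s for s in (specs or [])}
    lines = rendered.text.replace("\r\n", "\n").split("\n")
    facts: list[Fact] = []
    free: list[str] = []
    equivalent_uri: str | None = None
    smw_type: str | None = None
    template_call: TemplateCall | None = None

    i = 0
    while i < len(lines):
        line = lines[i]
        m = _CALL_OPEN_RE.match(line)
        if m and m.group("name") in spec_by_name:
            spec = spec_by_name[m.group("name")]
            args: dict[str, str] = {}
            j = i + 1
            closed = False
            while j < len(lines):
                if lines[j] == "}}":
                    closed = True
                    break
                am = _CALL_ARG_RE.match(lines[j])
                if am is None:
                    break
                args[am.group("param")] = am.group("value")
                j += 1
            if closed:
                call = TemplateCall(template=spec.name, arguments=args)
                try:
                    facts.extend(_expand_call(call, spec))
                    template_call = call
                    i = j + 1
                    continue
                except ValueError as exc:
                    warnings.warn(f"malformed template call: {exc}", stacklevel=2)
        sm = _SET_RE.match(line)
        if sm:
            ok = True
            parsed = []
            for part in sm.group("body").split("|"):
                part = part.strip()
                if not part:
                    continue
                if "=" not in part:
                    ok = False
                    break
                prop, value = part.split("=", 1)
                try:
                    parsed.append(
                        Fact(WikiTitle(Namespace.PROPERTY, prop.strip()), parse_fact_value(value))
                    )
                except ValueError:
                    ok = False
                    break
            if ok:
                facts.extend(parsed)
                i += 1
                continue
            warnings.warn("malformed #set block treated as free text", stacklevel=2)
        fm = _FACT_RE.match(line)
        if fm:
            prop_name = fm.group("prop")
            value = fm.group("value")
            try:
                if prop_name == EQUIVALENT_URI_PROPERTY and equivalent_uri is None:
                    equivalent_uri = value
                elif prop_name == HAS_TYPE_PROPERTY and smw_type is None:
                    smw_type = value
                else:
                    facts.append(
                        Fact(WikiTitle(Namespace.PROPERTY, prop_name), parse_fact_value(value))
                    )
                i += 1
                continue
            except ValueError as exc:
                warnings.warn(f"malformed fact syntax treated as free text: {exc}",
                              stacklevel=2)
        free.append(line)
        i += 1

    return WikiPage(
        title=rendered.title,
        facts=facts,
        equivalent_uri=equivalent_uri,
        free_text="\n".join(free),
        template_call=template_call,
        smw_type=smw_type,
    )


# --- Template pages ----------------------------------------------------------

_TEMPLATE_HEADER = (
    "<noinclude>Auto-generated template: one fact per parameter.</noinclude>"
)
_TEMPLATE_FACT_RE = re.compile(
    r"^\[\[(?P<prop>[^\[\]|]+?)::\{\{\{(?P<param>[^|{}]+)\|\}\}\}\]\]$"
)


def render_template_page(spec: TemplateSpec) -> RenderedPage:
    """The wiki page for an auto-generated template.  The body is the spec
    in executable form — one fact statement per parameter — which also lets
    :func:`parse_template_page` recover the spec from a dump."""
    lines = [_TEMPLATE_HEADER]
    lines += [
        "[[" + prop.name + "::{{{" + param + "|}}}]]"
        for param, prop in spec.parameters
    ]
    return RenderedPage(spec.name, "\n".join(lines))


def parse_template_page(rendered: RenderedPage) -> TemplateSpec | None:
    """Recover a :class:`TemplateSpec` from a template page's body, or None
    for templates that do not follow the generated one-fact-per-parameter
    shape (manual templates are simply not expanded)."""
    params = []
    for line in rendered.text.replace("\r\n", "\n").split("\n"):
        m = _TEMPLATE_FACT_RE.match(line)
        if m:
            params.append(
                (m.group("param"), WikiTitle(Namespace.PROPERTY, m.group("prop")))
            )
    if not params:
        return None
    name = WikiTitle.from_full(rendered.title.full, Namespace.TEMPLATE)
    return TemplateSpec(name=name, parameters=tuple(params))
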