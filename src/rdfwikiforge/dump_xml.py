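"""Reading and writing MediaWiki XML export dumps.

The dump is the hand-off format between the converter and a wiki: page
titles, namespace numbers and revision text wrapped in the MediaWiki
``export-0.10`` schema, with the wikitext stored as plain (XML-escaped)
text so a dump stays inspectable in a text editor.  Output is byte-stable
for a fixed timestamp; reading tolerates unknown elements and picks the
latest revision when a page has several.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .titles import Namespace, WikiTitle
from .wikitext import RenderedPage

__all__ = ["DumpDocument", "DumpFormatError", "write_dump", "read_dump",
           "EXPORT_NS", "DEFAULT_TIMESTAMP"]

EXPORT_NS = "http://www.mediawiki.org/xml/export-0.10/"
DEFAULT_TIMESTAMP = "1970-01-01T00:00:00Z"
DEFAULT_SITE_NAME = "rdfwikiforge"


class DumpFormatError(ValueError):
    pass


@dataclass
class DumpDocument:
    """An ordered set of rendered pages plus minimal site metadata."""

    pages: list[RenderedPage] = field(default_factory=list)
    site_name: str = DEFAULT_SITE_NAME
    timestamp: str = DEFAULT_TIMESTAMP

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pages:
            if p.title in seen:
                raise DumpFormatError(f"duplicate page title in dump: {p.title.full!r}")
            seen.add(p.title)


def write_dump(doc: DumpDocument) -> str:
    """Serialize to MediaWiki export XML (schema 0.10, one revision per
    page).  Deterministic: same document, same bytes."""
    ET.register_namespace("", EXPORT_NS)
    root = ET.Element(f"{{{EXPORT_NS}}}mediawiki", attrib={"version": "0.10"})
    siteinfo = ET.SubElement(root, f"{{{EXPORT_NS}}}siteinfo")
    ET.SubElement(siteinfo, f"{{{EXPORT_NS}}}sitename").text = doc.site_name
    for page in doc.pages:
        pe = ET.SubElement(root, f"{{{EXPORT_NS}}}page")
        ET.SubElement(pe, f"{{{EXPORT_NS}}}title").text = page.title.full
        ET.SubElement(pe, f"{{{EXPORT_NS}}}ns").text = str(int(page.title.namespace))
        rev = ET.SubElement(pe, f"{{{EXPORT_NS}}}revision")
        ET.SubElement(rev, f"{{{EXPORT_NS}}}timestamp").text = doc.timestamp
        ET.SubElement(rev, f"{{{EXPORT_NS}}}text").text = page.text
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True) + "\n"


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(elem: ET.Element) -> dict[str, list[ET.Element]]:
    out: dict[str, list[ET.Element]] = {}
    for child in elem:
        out.setdefault(_local(child.tag), []).append(child)
    return out


def read_dump(xml: str) -> DumpDocument:
    """Parse a MediaWiki export dump, tolerating superset schemas.

    Unknown elements are ignored; a page with multiple revisions keeps the
    text of the latest timestamp (document order breaks ties).  Missing
    title or text raises :class:`DumpFormatError` naming the page index.
    """
    try:
        root = ET.fromstring(xml)
    except ET.ParseError as exc:
        raise DumpFormatError(f"malformed XML: {exc}") from exc
    pages: list[RenderedPage] = []
    site_name = DEFAULT_SITE_NAME
    timestamp = DEFAULT_TIMESTAMP
    index = 0
    for elem in root:
        tag = _local(elem.tag)
        if tag == "siteinfo":
            for child in elem:
                if _local(child.tag) == "sitename" and child.text:
                    site_name = child.text
        if tag != "page":
            continue
        parts = _children(elem)
        titles = parts.get("title", [])
        if not titles or not titles[0].text:
            raise DumpFormatError(f"page {index}: missing title")
        ns_elems = parts.get("ns", [])
        namespace = None
        if ns_elems and ns_elems[0].text is not None:
            try:
                namespace = Namespace(int(ns_elems[0].text))
            except ValueError:
                namespace = None
        title = WikiTitle.from_full(titles[0].text, namespace)
        revisions = parts.get("revision", [])
        if not revisions:
            raise DumpFormatError(f"page {index}: no revision")
        best_text: str | None = None
        best_ts = ""
        for rev in revisions:
            rparts = _children(rev)
            ts = ""
            if rparts.get("timestamp") and rparts["timestamp"][0].text:
                ts = rparts["timestamp"][0].text
            texts = rparts.get("text", [])
            if not texts:
                continue  # revision without text cannot win
            text = texts[0].text or ""
            if best_text is None or ts >= best_ts:
                best_text = text
                best_ts = ts
        if best_text is None:
            raise DumpFormatError(f"page {index}: missing revision text")
        if best_ts:
            timestamp = best_ts
        pages.append(RenderedPage(title, best_text))
        index += 1
    return DumpDocument(pages=pages, site_name=site_name, timestamp=timestamp)
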