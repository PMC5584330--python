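"""How URIs become readable page titles.

The resolver tries strategies in a fixed order and stops at the first
that works: an existing page for the URI, a label-like property value, a
CURIE from the dataset's namespace abbreviations, and finally the URI's
local part.  Collisions get a numeric suffix; the URI-to-title map is
always an exact bijection.
"""

from rdfwikiforge import (
    IRI,
    Literal,
    PrefixMap,
    ResolverConfig,
    TitleIndex,
    Triple,
    resolve_title,
)
from rdfwikiforge.titles import DC_TITLE

VOCAB = "http://bio.example.org/onto/"
cfg = ResolverConfig(prefixes=PrefixMap({"onto": VOCAB}))

uri = IRI(VOCAB + "GeneX42")
labelled = [Triple(uri, IRI(DC_TITLE), Literal("Cytochrome P450 2D6"))]

# strategy 1: a dc:title label wins over everything below
index = TitleIndex()
print("with label:   ", resolve_title(uri, labelled, cfg, index).full)

# strategy 0: once registered, the same URI always reuses its page
print("second lookup:", resolve_title(uri, [], cfg, index).full)

# strategy 2: no label, but the namespace is abbreviated in the dataset
print("CURIE:        ", resolve_title(uri, [], cfg, TitleIndex()).full)

# strategy 3: no label, no prefix -> local part after the last / or #
print("local part:   ", resolve_title(uri, [], ResolverConfig(), TitleIndex()).full)

# collisions: three URIs sharing one label stay distinguishable
index = TitleIndex()
for i in range(3):
    t = resolve_title(IRI(VOCAB + f"iso{i}"),
                      [Triple(IRI(VOCAB + f"iso{i}"), IRI(DC_TITLE),
                              Literal("Isoform"))],
                      cfg, index)
    print(f"collision {i}:  ", t.full)
# "Isoform", "Isoform (2)", "Isoform (3)" — one page per URI, no merging.
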