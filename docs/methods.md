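# Methods

This note records how `rdfwikiforge` models the RDF↔wiki conversion, the
choices made where the design was genuinely open, and what the test suite
does and does not demonstrate.

## Data model and pipeline

A graph is a set of triples `(subject IRI, predicate IRI, object IRI |
literal)`. Literals carry a lexical form plus at most one of an XSD (or
other) datatype IRI or a BCP-47 language tag. Blank nodes are not part of
the page model: they are skolemized on input to IRIs under
`urn:bnode:<import-id>:<label>`, where `import-id` is the first 8 hex
characters of the SHA-256 of the input text — every anonymous resource
becomes addressable, and re-parsing the same bytes yields the same IRIs.
A warning reports the number of skolemized occurrences.

Import: triples are aggregated per subject; one `WikiPage` per subject,
one `Fact` per triple. Predicates resolve to Property-namespace pages,
IRI objects to page links, literal objects stay verbatim. Resources that
only appear as objects get empty pages (links never dangle). Every
imported page records its source URI as `equivalent_uri` — the single
piece of state that makes export lossless. Export inverts the mapping
fact-by-fact, consuming the Equivalent-URI links; `filter_metadata`
removes the wiki's own bookkeeping predicates so the round-trip
comparison sees only imported data.

## Canonical ordering

Every serialization and aggregation sorts lexicographically by codepoint
(subjects, then predicates, then the N-Triples form of objects). This is
a global design rule, not an optimization: it makes dump files diffable,
chunk boundaries well defined, disambiguation deterministic, and the
round-trip check byte-exact rather than merely set-equal.

## Title resolution

Strategies in order, stopping at the first non-empty sanitized result:

0. the URI already has a page (title index / Equivalent-URI link) — reuse;
1. label properties, by default `dc:title` > `rdfs:label` >
   `skos:prefLabel` > `foaf:name` (configurable); among several values of
   the winning property, the lexicographically smallest — an arbitrary but
   deterministic tie-break;
2. CURIE from the dataset's `@prefix` declarations, longest namespace
   match, written `label localpart` with a space — a colon would collide
   with MediaWiki's namespace syntax;
3. the local part after the last `/` or `#`.

Sanitization replaces MediaWiki-illegal characters (`# < > [ ] | { }`,
control characters) and additionally `;` and `=` with `-`: the fact and
template dialect reserves `;` as the multi-value separator and `=` as the
parameter assignment, and banning them from titles is what makes template
arguments parseable without quoting. Colon runs collapse to one colon so
`::` remains unambiguous as the fact separator. Names are trimmed,
first-uppercased, and truncated to 255 UTF-8 bytes on a character
boundary; the function is idempotent.

Collisions get the smallest free numeric suffix ` (2)`, ` (3)`, …,
assigned atomically with registration; the URI↔title index enforces a
bijection by construction. The special property names `Equivalent URI`
and `Has type` are pre-claimed under sentinel URIs so no data property
can shadow them.

## The wiki site: accumulate, then build

`WikiSite` ingests triples incrementally (chunks, replication batches)
but *materializes* pages lazily from the full accumulated graph. The
final wiki is therefore a pure function of the set of imported triples:
independent of chunk partitioning, idempotent under re-import, and a
label that arrives in a later chunk still names its resource's page. The
alternative — minting titles first-come per chunk — would make page names
depend on where chunk boundaries happen to fall (an object seen in chunk
1 would be named by local part even if its `dc:title` arrives in chunk
5). Manually created or edited pages live in an overlay: rebuilds seed
the title index from the overlay's Equivalent-URI links (strategy 0) and
merge overlay content via `merge_pages`, so manual facts and free text
survive re-imports. Merging is append-only — facts are never removed;
detecting deprecated triples on re-import is explicitly out of scope.

## Datatype inference

Property pages are typed from all values observed for the predicate:
IRIs → `Page`; `xsd:integer/decimal/double/float` → `Number`;
`xsd:date/dateTime` → `Date`; `xsd:boolean` → `Boolean`; `xsd:anyURI` →
`URL`; anything else (plain, language-tagged, `xsd:string`, unknown
datatypes) → `Text`. Mixed literal categories degrade to `Text`; a mix of
pages and literals types as `Page` with a warning — the link reading is
the more structural one. Derived XSD numeric types (`xsd:int`,
`xsd:long`, …) are deliberately not mapped; they fall into `Text`.

## The wikitext dialect

One canonical dialect keeps the round trip testable: inline facts
`[[Property::value]]`, one per line; `{{#set:}}` is accepted on parse but
never emitted. Page values are written as full titles. Literal values are
escaped (HTML numeric entities for `& | [ ] { } < > ; =` and line
breaks; `&` first, so unescaping is a true inverse) and always carry a
trailing typing marker: `<!--^^xsd:decimal-->`, `<!--^^<full-iri>-->`,
`<!--@en-->`, or `<!--^^-->` for plain literals. The marker serves two
purposes: it preserves datatype/language through the wiki (wikitext has
no native lexical slot for them), and it syntactically distinguishes
literal from page values, so parsing needs no out-of-band property-type
table — without the plain-literal marker, a literal under a
mixed-value (`Page`-typed) property would be unrecoverable.

Template bodies are generated as one fact per parameter
(`[[Prop::{{{param|}}}]]`), so a template call expands trivially and
invertibly; multi-valued properties join rendered values with `;` inside
a call (split again on exactly the semicolons outside entity spans).
Pages with several `rdf:type` values call the lexicographically first
type's template; every type remains present as an ordinary `Rdf type`
fact, which also means export reconstructs `rdf:type` statements whether
or not templates are enabled. Parsing wiki text is total: unrecognized
lines, malformed fact syntax and unknown templates survive verbatim as
free text — a wiki page never fails to parse.

## XML dumps

MediaWiki export schema 0.10, one revision per page, namespaces Main=0,
Template=10, Property=102. Timestamps default to a fixed epoch so dumps
are byte-stable; `--timestamp now` opts into wall-clock stamps. Reading
tolerates unknown elements and picks the latest revision by timestamp.
Page text is plain (only XML-escaped), so dumps remain inspectable.

## Export and metadata

With `origuris` (default) subjects, predicates and page-valued objects
are restored from Equivalent-URI links; pages lacking one (manual pages)
fall back to a wiki-minted URI
`<base>/Special:URIResolver/<percent-encoded title>` with a warning, and
with `origuris` off every resource is minted that way. The metadata
predicate set is explicit and configurable: `owl:sameAs` (the
Equivalent-URI link, as SMW itself exports it) plus
`swivt:wikiPageModificationDate`, `swivt:creationDate`,
`swivt:wikiPageDisplayTitle` and `swivt:type`. Known limitation: user
data that itself uses `owl:sameAs` would be stripped by the default
filter; pass a custom predicate set in that case.

## Serialization choices

N-Triples is parsed and written by a line-oriented grammar of our own:
the contract demands exact line numbers in errors, label-preserving
skolemization and byte-canonical sorted output. Turtle is parsed through
rdflib (with literal normalization disabled, so lexical forms like
`"5.9e-01"^^xsd:double` survive verbatim; rdflib's parse-order blank-node
counter provides deterministic skolem labels) after a pre-scan rejects
constructs outside the supported subset — collections and anonymous
property lists fail loudly rather than silently becoming opaque
structure. The Turtle *writer* is hand-written for the same lexical
fidelity reason: generic serializers abbreviate numeric literals to bare
tokens, rewriting the lexical form and breaking parse∘write identity.
Named graphs, RDF/XML, JSON-LD and N-Quads are out of scope.

## Pattern store and replication

Pagination over a triple store is only sound against a stable total
order; the in-memory store pages over canonical order and the SPARQL
HTTP adapter (stdlib urllib; never exercised in tests) adds
`ORDER BY ?s ?p ?o` — a stronger requirement than many endpoints give by
default, stated here as an explicit precondition. Replication advances
its offset only after a batch is safely imported, so the returned state
is always a valid restart point; a failing source returns `done=False`
rather than raising.

## Synthetic data

The generator emulates the two demonstrator shapes plus an adversarial
one. `orphanet_like`: genes and disorders connected only through
intermediate gene–disorder association nodes (n genes, n disorders,
n + n/2 associations), labels on a configurable fraction (`dc:title` on
genes, `rdfs:label` on disorders). `drugmet_like`: n compounds, all
carrying `rdf:type`, one `xsd:decimal` pKa in [0.5, 13.5] and a link to
one of max(1, n/3) publications. `random`: entities split between a
prefix-declared and an undeclared namespace (so every title strategy
fires), 1–4 statements each, objects half IRIs and half literals drawn
across the XSD spectrum including strings with `| [ ] { } ; = & #`,
tabs, newlines and non-ASCII; labels are drawn from a pool smaller than
the entity count so title collisions actually occur. Defaults:
`label_fraction = typed_fraction = 0.5`. All output is a pure function
of the recipe (seeded `random.Random`); byte-identical across runs.

What the fixtures do **not** model: blank-node-heavy real-world dumps,
IRIs with exotic percent-encodings, literals containing fact-like
wikitext in free text positions, and multi-gigabyte streams. Passing
tests therefore demonstrate correctness of the conversion logic under
realistic structure and adversarial characters, not performance or
robustness against arbitrarily malformed third-party RDF.

## Problem sizes in the checks

The acceptance measurements use 200 generated graphs of roughly 10–2,000
triples across the three kinds and varying label/type coverage;
replication mirrors sources of ~600 and ~5,000 triples at batch limits
1, 7 and 100; the throughput check converts a ~105,000-triple random
graph to XML in one process. These sizes exercise every code path at
desk scale while keeping the whole suite fast enough to run habitually.
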