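# rdfwikiforge

Lossless, deterministic round-tripping between RDF triple data and a
semantic-wiki page structure.

Biomedical and cheminformatics groups often hold linked data — rare-disease
gene associations, compound measurements, publication links — as RDF
triples, a format that is excellent for integration and terrible for
browsing and collaborative editing. Semantic wikis solve the opposite
problem: pages are easy to read, navigate and annotate, but getting
thousands of RDF statements *into* one (and faithfully back *out*) is the
hard part. `rdfwikiforge` is that bridge: it converts RDF datasets into
MediaWiki XML dumps whose pages carry Semantic-MediaWiki-style
property–value facts, and exports such page structures back to RDF,
reconstructing the originally imported triples exactly.

## How it works

Import proceeds in five steps. Triples `(s, p, o)` are **aggregated per
subject**; each subject becomes one wiki page. Every URI is resolved to a
readable page title by an ordered strategy chain — (0) an existing page
already linked to the URI, (1) a label property such as `dc:title` or
`rdfs:label`, (2) a CURIE `prefix localpart` from the dataset's namespace
abbreviations, (3) the URI's local part after the last `/` or `#` — with
numeric-suffix disambiguation keeping the URI↔title map an exact
bijection. Predicate–object pairs become facts `[[Property::value]]`
(literals kept verbatim, with their XSD datatype or language tag preserved
in a marker); each property page is typed from the observed values
(`xsd:decimal` → `Number`, IRIs → `Page`, …). Subjects sharing an
`rdf:type` get an auto-generated template and their facts are packed into
a template call. Finally the pages are wrapped in MediaWiki's XML export
schema — plain text, inspectable in an editor.

The key to losslessness is the **Equivalent URI** fact written on every
imported page: `[[Equivalent URI::<original-uri>]]`. On export, each fact
becomes a triple again with subject, predicate and page-valued object URIs
restored through those links (`--origuris`); the wiki's own bookkeeping
(Equivalent-URI links, property datatypes, modification dates) can be
emitted too, and `filter_metadata` strips exactly that set, so

```
filter_metadata(export(import(G))) == G
```

holds as byte-exact canonical N-Triples for every supported input graph.
Imports run in restartable chunks (`--chunksize`, `--offset`), re-imports
merge facts in place without touching manual edits, and a replication
driver mirrors any triple-pattern source (e.g. a SPARQL endpoint's
`?s ?p ?o`) in auto-advancing LIMIT/OFFSET batches.

## Worked example

```sh
python examples/roundtrip_demo.py
```

prints:

```
imported 1 triple(s) -> 2 wiki pages
  dump: <title>Aspirin</title>
  dump: <text>[[PKa::3.5&lt;!--^^xsd:decimal--&gt;]]
  dump: [[Equivalent URI::http://ex.org/aspirin]]</text>
  dump: <title>Property:PKa</title>
  dump: <text>[[Equivalent URI::http://ex.org/vocab/pKa]]
  dump: [[Has type::Number]]</text>
unfiltered export: 6 triples (wiki adds metadata per page)
after metadata filtering: 1 triple(s)
recovered N-Triples:
  <http://ex.org/aspirin> <http://ex.org/vocab/pKa> "3.5"^^<http://www.w3.org/2001/XMLSchema#decimal> .
round trip exact: True
```

One statement about aspirin's pKa became a readable `Aspirin` page plus a
`Property:PKa` page typed `Number`; the export emitted six triples (the
original plus per-page metadata), and filtering the metadata recovered the
input byte for byte. The other examples show title resolution
(`title_strategies.py`), per-type template generation
(`template_synthesis.py`) and batch replication with interrupt/resume
(`replication_demo.py`).

The same workflow from the shell:

```sh
rdfwikiforge fixture --kind drugmet_like --n 20 --seed 1 --out data.nt
rdfwikiforge convert --in data.nt --out dump.xml --chunksize 1000
rdfwikiforge export  --in dump.xml --out back.nt --format ntriples --origuris
rdfwikiforge roundtrip --in data.nt        # exit 0 iff triples survive
```

## Layout

- `src/rdfwikiforge/rdf_io.py` — triple model, N-Triples (canonical) and a
  Turtle subset, per-subject aggregation
- `src/rdfwikiforge/titles.py` — title strategies, sanitization, the
  bidirectional URI↔title index
- `src/rdfwikiforge/pages.py` — page/fact model, datatype inference,
  template synthesis, chunked import, in-place merge, `WikiSite`
- `src/rdfwikiforge/wikitext.py` — the SMW fact dialect, both directions
- `src/rdfwikiforge/dump_xml.py` — MediaWiki export-0.10 XML
- `src/rdfwikiforge/exporter.py` — RDF export and metadata filtering
- `src/rdfwikiforge/replicator.py` — pattern store, pagination, replication
- `src/rdfwikiforge/fixtures.py` — deterministic synthetic graph generator
- `src/rdfwikiforge/cli.py` — the `rdfwikiforge` command

See `docs/methods.md` for the design decisions and their rationale.
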