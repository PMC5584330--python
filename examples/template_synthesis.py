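"""Auto-generated templates from rdf:type.

Entities sharing an rdf:type get one MediaWiki template each: the template
has one parameter per property used by that type, and every typed page's
facts are re-expressed as a template call — uniform page layout without
losing a single fact (calls expand back to the same facts on export).
"""

from rdfwikiforge import WikiSite
from rdfwikiforge.fixtures import FixtureRecipe, generate_fixture
from rdfwikiforge.wikitext import render_page, render_template_page

# compounds carrying rdf:type, a decimal pKa and a publication link
graph = generate_fixture(
    FixtureRecipe(kind="drugmet_like", n_entities=3, seed=11, label_fraction=1.0)
)
site = WikiSite()
site.import_triples(graph)
specs = site.synthesize()

print(f"{len(graph)} triples -> {len(site.page_list())} pages, "
      f"{len(specs)} template(s)")
for spec in specs:
    print(f"\n{spec.name.full} parameters: {', '.join(spec.param_names())}")
    print(render_template_page(spec).text)

compound = next(p for p in site.page_list()
                if p.equivalent_uri and "compound/" in p.equivalent_uri)
print(f"\n{compound.title.full} rendered as a template call:")
print(render_page(compound, specs).text)
# The {{...}} call carries every fact as a parameter value; the
# [[Equivalent URI::...]] line is what later restores the original URI.
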