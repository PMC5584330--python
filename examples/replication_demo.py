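"""Mirroring a triple store batch by batch, with restart.

Replication fetches all-wildcard windows (LIMIT/OFFSET over a stable
order) from a source and feeds each batch through the import pipeline.
The recorded offset makes an interrupted run resumable, and the mirrored
wiki exports exactly the source's triples.
"""

from rdfwikiforge import ExportOptions, WikiSite, export_rdf, filter_metadata
from rdfwikiforge.fixtures import FixtureRecipe, generate_fixture
from rdfwikiforge.replicator import InMemorySource, replicate

source_graph = generate_fixture(
    FixtureRecipe(kind="orphanet_like", n_entities=20, seed=5)
)
print(f"source store: {len(source_graph)} triples")


class FlakySource(InMemorySource):
    """Pretends the endpoint drops the connection on the third request."""

    calls = 0

    def match(self, q):
        FlakySource.calls += 1
        if FlakySource.calls == 3:
            raise ConnectionError("connection reset")
        return super().match(q)


source = FlakySource(source_graph)
sink = WikiSite()

state = replicate(source, sink, batch_limit=25)
print(f"first run: done={state.done}, safe offset={state.offset}")

state = replicate(source, sink, batch_limit=25, state=state)
print(f"resumed:   done={state.done}, offset={state.offset}")

mirrored = filter_metadata(
    export_rdf(sink.page_list(), sink.index, ExportOptions(origuris=True))
)
print(f"mirror holds {len(mirrored)} triples; equals source:",
      mirrored == source_graph)
# True: interrupt plus resume produced the identical mirror.
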