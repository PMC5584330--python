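import warnings

import pytest
from hypothesis import HealthCheck, settings

from rdfwikiforge import (
    ExportOptions,
    ImportOptions,
    WikiSite,
    export_rdf,
    filter_metadata,
    read_dump,
    write_dump,
)
from rdfwikiforge.fixtures import FixtureRecipe, generate_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline-internal warnings (skolemization counts, mixed-type
    properties) are part of normal operation on adversarial fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def make_graph(kind="random", n=12, seed=0, label_fraction=0.5, typed_fraction=0.5):
    return generate_fixture(
        FixtureRecipe(
            kind=kind,
            n_entities=n,
            seed=seed,
            label_fraction=label_fraction,
            typed_fraction=typed_fraction,
        )
    )


def import_export_roundtrip(ts, chunksize=None, templates=True):
    """The full pipeline: import -> XML dump text -> parse dump -> export
    with original URIs -> strip wiki metadata.  Returns the recovered set."""
    site = WikiSite()
    if chunksize is None:
        site.import_triples(ts)
    else:
        site.import_chunked(ts, ImportOptions(chunksize=chunksize))
    xml = write_dump(site.to_dump(templates=templates))
    site2 = WikiSite.from_dump(read_dump(xml))
    exported = export_rdf(site2.page_list(), site2.index, ExportOptions(origuris=True))
    return filter_metadata(exported)
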