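"""Triple-pattern matching with stable pagination, and batch replication.

This is the algorithmic core of importing from a remote SPARQL endpoint:
an all-wildcard ``?s ?p ?o`` pattern fetched window by window (LIMIT /
OFFSET), each window fed through the normal import pipeline, with the
offset advancing automatically so an interrupted run can resume from the
recorded state.  Pagination is only sound over a stable total order, so
the in-memory store pages over the canonical triple order and the HTTP
adapter adds an ORDER BY clause.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
from dataclasses import dataclass
from typing import Protocol

from .pages import WikiSite
from .rdf_io import IRI, Literal, Term, Triple, TripleSet

__all__ = [
    "PatternQuery",
    "ReplicationState",
    "TriplePatternSource",
    "InMemorySource",
    "SparqlHttpSource",
    "match",
    "replicate",
]


@dataclass(frozen=True)
class PatternQuery:
    """A ``?s ?p ?o`` pattern with optional bound positions and a
    LIMIT/OFFSET window.  ``None`` means wildcard."""

    s: IRI | None = None
    p: IRI | None = None
    o: Term | None = None
    limit: int | None = None
    offset: int = 0

    def __post_init__(self) -> None:
        if self.limit is not None and self.limit < 1:
            raise ValueError("limit must be >= 1 when present")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass
class ReplicationState:
    """Progress of a replication run; ``offset`` only ever increases, so the
    state is always a safe restart point."""

    offset: int = 0
    batch_limit: int = 1000
    done: bool = False


class TriplePatternSource(Protocol):
    def match(self, q: PatternQuery) -> list[Triple]: ...


def match(store: TripleSet, q: PatternQuery) -> list[Triple]:
    """Triples matching every bound position, in canonical order, with the
    ``[offset, offset+limit)`` window applied.  Because the order is total
    and stable, disjoint windows partition the full result."""
    hits = [
        t
        for t in store
        if (q.s is None or t.subject == q.s)
        and (q.p is None or t.predicate == q.p)
        and (q.o is None or t.object == q.o)
    ]
    end = None if q.limit is None else q.offset + q.limit
    return hits[q.offset : end]


class InMemorySource:
    """A local triple store as a pattern source (the test/desk-scale stand-in
    for a remote endpoint)."""

    def __init__(self, ts: TripleSet):
        self.ts = ts

    def match(self, q: PatternQuery) -> list[Triple]:
        return match(self.ts, q)


class SparqlHttpSource:
    """Adapter speaking the SPARQL protocol over HTTP.

    Issues ``SELECT ?s ?p ?o WHERE { ?s ?p ?o } ORDER BY ?s ?p ?o`` with
    LIMIT/OFFSET and reads SPARQL-JSON results.  The ORDER BY clause is
    required for sound pagination and is a stronger guarantee than many
    endpoints give by default.  Exercised only against live endpoints,
    never in tests.
    """

    def __init__(self, endpoint: str, timeout: float = 60.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def match(self, q: PatternQuery) -> list[Triple]:  # pragma: no cover - network
        def term(v: Term | None, var: str) -> str:
            return v.nt() if v is not None else f"?{var}"

        where = f"{term(q.s, 's')} {term(q.p, 'p')} {term(q.o, 'o')}"
        query = f"SELECT ?s ?p ?o WHERE {{ {where} }} ORDER BY ?s ?p ?o"
        if q.limit is not None:
            query += f" LIMIT {q.limit}"
        if q.offset:
            query += f" OFFSET {q.offset}"
        url = f"{self.endpoint}?{urllib.parse.urlencode({'query': query})}"
        req = urllib.request.Request(
            url, headers={"Accept": "application/sparql-results+json"}
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            data = json.load(resp)
        out = []
        for row in data["results"]["bindings"]:
            out.append(
                Triple(
                    self._term(row.get("s"), q.s),  # type: ignore[arg-type]
                    self._term(row.get("p"), q.p),  # type: ignore[arg-type]
                    self._term(row.get("o"), q.o),
                )
            )
        return out

    @staticmethod
    def _term(binding: dict | None, bound: Term | None) -> Term:  # pragma: no cover
        if binding is None:
            assert bound is not None
            return bound
        kind = binding["type"]
        if kind == "uri":
            return IRI(binding["value"])
        if kind in ("literal", "typed-literal"):
            dt = binding.get("datatype")
            return Literal(
                binding["value"],
                datatype=IRI(dt) if dt else None,
                language=binding.get("xml:lang"),
            )
        if kind == "bnode":
            return IRI(f"urn:bnode:sparql:{binding['value']}")
        raise ValueError(f"unsupported binding type: {kind}")


def replicate(
    source: TriplePatternSource,
    sink: WikiSite,
    batch_limit: int,
    state: ReplicationState | None = None,
) -> ReplicationState:
    """Mirror *source* into *sink* in auto-advancing batches.

    Fetches all-wildcard windows of ``batch_limit`` triples, imports each
    through the full pipeline, and advances the offset by the page size
    until an empty window signals completion.  A source failure mid-run
    returns the state with ``done=False`` at the last safely imported
    offset; passing that state back in resumes exactly there.
    """
    if batch_limit < 1:
        raise ValueError("batch_limit must be >= 1")
    st = state or ReplicationState(offset=0, batch_limit=batch_limit)
    st.batch_limit = batch_limit
    while True:
        try:
            batch = source.match(
                PatternQuery(limit=batch_limit, offset=st.offset)
            )
        except Exception:
            return st
        if not batch:
            st.done = True
            return st
        sink.import_triples(TripleSet(batch))
        st.offset += len(batch)
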