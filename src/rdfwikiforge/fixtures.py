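"""Synthetic RDF graphs shaped like real linked-data demonstrators.

Three recipes, all fully deterministic for a given seed:

* ``orphanet_like`` — rare-disease style: genes and disorders joined only
  through intermediate gene–disorder association nodes, so list-style
  navigation of indirect links is exercised (a gene page never links a
  disorder directly);
* ``drugmet_like`` — cheminformatics style: compounds carrying ``rdf:type``
  and decimal pKa measurements linked to publications, so template
  synthesis and Number datatype inference are exercised;
* ``random`` — uniform graphs with tunable label and type coverage, URIs
  in both declared and undeclared namespaces, literals across the XSD
  spectrum and gnarly characters, so every title strategy and the escaping
  layer are exercised.

No blank nodes are generated; every literal carries the typing its recipe
states.  Same recipe ⇒ byte-identical N-Triples output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .rdf_io import IRI, Literal, PrefixMap, RDF_TYPE, Triple, TripleSet, XSD
from .titles import DC_TITLE, RDFS_LABEL

__all__ = ["FixtureRecipe", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("orphanet_like", "drugmet_like", "random")

_ORPH = "http://fixture.example.org/orphanet/"
_DM = "http://fixture.example.org/drugmet/"
_RND = "http://fixture.example.org/random/"
_RND_BARE = "http://fixture.example.org/bare#"


@dataclass(frozen=True)
class FixtureRecipe:
    kind: str
    n_entities: int = 10
    seed: int = 0
    label_fraction: float = 0.5
    typed_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind: {self.kind!r}")
        if self.n_entities < 1:
            raise ValueError("n_entities must be >= 1")
        for frac in (self.label_fraction, self.typed_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be within [0, 1]")


def generate_fixture(recipe: FixtureRecipe) -> TripleSet:
    rng = random.Random(recipe.seed)
    if recipe.kind == "orphanet_like":
        return _orphanet(recipe, rng)
    if recipe.kind == "drugmet_like":
        return _drugmet(recipe, rng)
    return _random_graph(recipe, rng)


def _orphanet(r: FixtureRecipe, rng: random.Random) -> TripleSet:
    n = r.n_entities
    vocab = _ORPH + "vocab/"
    genes = [IRI(_ORPH + f"gene/G{i:04d}") for i in range(n)]
    disorders = [IRI(_ORPH + f"disorder/D{i:04d}") for i in range(n)]
    p_gene = IRI(vocab + "refersToGene")
    p_disorder = IRI(vocab + "refersToDisorder")
    assoc_class = IRI(vocab + "GeneDisorderAssociation")
    triples: list[Triple] = []
    perm = list(range(n))
    rng.shuffle(perm)
    n_assoc = n + n // 2
    for k in range(n_assoc):
        assoc = IRI(_ORPH + f"assoc/A{k:04d}")
        gene = genes[k % n] if k < n else genes[rng.randrange(n)]
        disorder = disorders[perm[k % n]] if k < n else disorders[rng.randrange(n)]
        triples.append(Triple(assoc, p_gene, gene))
        triples.append(Triple(assoc, p_disorder, disorder))
        if rng.random() < r.typed_fraction:
            triples.append(Triple(assoc, IRI(RDF_TYPE), assoc_class))
    for i, gene in enumerate(genes):
        if rng.random() < r.label_fraction:
            triples.append(Triple(gene, IRI(DC_TITLE), Literal(f"Gene symbol GS{i}")))
    for i, disorder in enumerate(disorders):
        if rng.random() < r.label_fraction:
            triples.append(
                Triple(disorder, IRI(RDFS_LABEL), Literal(f"Rare disorder {i}"))
            )
    prefixes = PrefixMap({"orph": _ORPH, "orphv": vocab})
    return TripleSet(triples, prefixes)


def _drugmet(r: FixtureRecipe, rng: random.Random) -> TripleSet:
    n = r.n_entities
    vocab = _DM + "vocab/"
    compound_class = IRI(vocab + "Compound")
    publication_class = IRI(vocab + "Publication")
    p_pka = IRI(vocab + "pKa")
    p_pub = IRI(vocab + "measuredIn")
    n_pubs = max(1, n // 3)
    pubs = [IRI(_DM + f"publication/P{j:03d}") for j in range(n_pubs)]
    triples: list[Triple] = []
    for i in range(n):
        compound = IRI(_DM + f"compound/C{i:04d}")
        triples.append(Triple(compound, IRI(RDF_TYPE), compound_class))
        pka = rng.uniform(0.5, 13.5)
        triples.append(
            Triple(compound, p_pka, Literal(f"{pka:.2f}", datatype=IRI(XSD + "decimal")))
        )
        triples.append(Triple(compound, p_pub, pubs[i % n_pubs]))
        if rng.random() < r.label_fraction:
            triples.append(Triple(compound, IRI(RDFS_LABEL), Literal(f"Compound {i}")))
    for j, pub in enumerate(pubs):
        triples.append(Triple(pub, IRI(DC_TITLE), Literal(f"Measurement paper {j}")))
        if rng.random() < r.typed_fraction:
            triples.append(Triple(pub, IRI(RDF_TYPE), publication_class))
    prefixes = PrefixMap({"dm": vocab, "dmc": _DM + "compound/"})
    return TripleSet(triples, prefixes)


_TRICKY = (
    "plain value",
    "pipe|bracket[x]{y}",
    "semi;colon=eq",
    "ampersand &#38; entity",
    "tab\tand newline\nend",
    "ünïcödé ✓",
    "<not-a-tag>",
)


def _random_literal(rng: random.Random) -> Literal:
    roll = rng.randrange(10)
    if roll == 0:
        return Literal(rng.choice(_TRICKY))
    if roll == 1:
        return Literal(rng.choice(_TRICKY), language=rng.choice(("en", "de", "sv")))
    if roll == 2:
        return Literal(str(rng.randrange(10**6)), datatype=IRI(XSD + "integer"))
    if roll == 3:
        return Literal(f"{rng.uniform(-50, 50):.3f}", datatype=IRI(XSD + "decimal"))
    if roll == 4:
        return Literal(f"{rng.uniform(0, 1):.6e}", datatype=IRI(XSD + "double"))
    if roll == 5:
        return Literal(rng.choice(("true", "false")), datatype=IRI(XSD + "boolean"))
    if roll == 6:
        return Literal(
            f"20{rng.randrange(10, 30)}-0{rng.randrange(1, 10)}-1{rng.randrange(0, 10)}",
            datatype=IRI(XSD + "date"),
        )
    if roll == 7:
        return Literal(
            f"http://data.example.org/item/{rng.randrange(100)}",
            datatype=IRI(XSD + "anyURI"),
        )
    if roll == 8:
        return Literal(f"s{rng.randrange(100)}", datatype=IRI(XSD + "string"))
    return Literal(
        f"v{rng.randrange(100)}",
        datatype=IRI("http://fixture.example.org/datatype/custom"),
    )


def _random_graph(r: FixtureRecipe, rng: random.Random) -> TripleSet:
    n = r.n_entities
    vocab = _RND + "vocab/"
    entities = [
        IRI((_RND + "entity/" if rng.random() < 0.5 else _RND_BARE) + f"e{i}")
        for i in range(n)
    ]
    predicates = [IRI(vocab + f"p{k}") for k in range(max(2, n // 4))]
    classes = [IRI(vocab + f"Class{k}") for k in range(3)]
    # Label pool smaller than the entity count, so some labels collide and
    # the numeric-suffix disambiguation is exercised.
    label_pool = max(1, (2 * n) // 3)
    triples: list[Triple] = []
    for i, entity in enumerate(entities):
        for _ in range(rng.randint(1, 4)):
            pred = rng.choice(predicates)
            if rng.random() < 0.5:
                obj: IRI | Literal = rng.choice(entities)
            else:
                obj = _random_literal(rng)
            triples.append(Triple(entity, pred, obj))
        if rng.random() < r.label_fraction:
            triples.append(
                Triple(
                    entity,
                    IRI(DC_TITLE),
                    Literal(f"Entity {rng.randrange(label_pool)}"),
                )
            )
        if rng.random() < r.typed_fraction:
            triples.append(Triple(entity, IRI(RDF_TYPE), rng.choice(classes)))
    prefixes = PrefixMap({"rnd": _RND + "entity/", "rv": vocab})
    return TripleSet(triples, prefixes)
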