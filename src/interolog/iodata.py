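"""Domain types and readers/writers for interaction, ortholog, ontology,
annotation, expression and phylogeny inputs.

All readers consume plain text streams in small tab-separated dialects (or
standard OBO / Newick) and build the in-memory containers used throughout
the package.  Identifiers are case-sensitive and matched exactly; there is
no fuzzy ID mapping layer.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, TextIO

import dendropy
import networkx as nx
import obonet

__all__ = [
    "InteractionType",
    "Protein",
    "Interaction",
    "InteractionNetwork",
    "OrthologPair",
    "OrthologMapping",
    "GoCategory",
    "GoDag",
    "AnnotationStore",
    "PhyloTree",
    "ParseError",
    "parse_interaction_table",
    "write_interaction_table",
    "parse_ortholog_table",
    "write_ortholog_table",
    "parse_obo",
    "parse_newick",
    "write_newick",
    "parse_annotation_table",
    "write_annotation_table",
    "parse_expression_table",
    "write_expression_table",
]


class ParseError(ValueError):
    """Raised when an input stream violates its documented dialect."""


class InteractionType(str, Enum):
    physical = "physical"
    genetic = "genetic"
    other = "other"

    @classmethod
    def from_token(cls, token: str) -> "InteractionType":
        """Map a raw type token onto the three-way classification.

        Anything that is not literally ``physical`` or ``genetic`` (unknown,
        ambiguous, complex-derived...) collapses to ``other``.
        """
        if token in ("physical", "genetic", "other"):
            return cls(token)
        raise ParseError(
            f"unknown interaction type {token!r}; allowed: physical, genetic, other"
        )


@dataclass(frozen=True, order=True)
class Protein:
    id: str
    species: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.species:
            raise ValueError("species id must be non-empty")


@dataclass(frozen=True)
class Interaction:
    """Undirected interaction between two proteins of one species.

    Stored once, in canonical order (lexicographically smaller protein id
    first).  Self-interactions are rejected: neighborhood-based features are
    degenerate for loops.
    """

    a: Protein
    b: Protein
    itype: InteractionType
    source_db: str
    pubmed_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.a.species != self.b.species:
            raise ValueError("interaction endpoints must share a species")
        if self.a.id == self.b.id:
            raise ValueError(f"self-interaction on {self.a.id!r} not allowed")
        if self.a.id > self.b.id:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a.id, self.b.id)


class InteractionNetwork:
    """Species-tagged undirected interaction graph with evidence per edge."""

    def __init__(self, species: str, interactions: Iterable[Interaction] = ()):
        self.species = species
        self.proteins: set[Protein] = set()
        self.interactions: set[Interaction] = set()
        self._adj: dict[str, set[str]] = {}
        self._by_pair: dict[tuple[str, str], list[Interaction]] = {}
        for inter in interactions:
            self.add(inter)

    def add(self, inter: Interaction) -> None:
        if inter.a.species != self.species:
            raise ValueError(
                f"interaction species {inter.a.species!r} != network species {self.species!r}"
            )
        if inter in self.interactions:
            return
        self.interactions.add(inter)
        self.proteins.add(inter.a)
        self.proteins.add(inter.b)
        self._adj.setdefault(inter.a.id, set()).add(inter.b.id)
        self._adj.setdefault(inter.b.id, set()).add(inter.a.id)
        self._by_pair.setdefault(inter.pair, []).append(inter)

    def add_protein(self, protein: Protein) -> None:
        if protein.species != self.species:
            raise ValueError("protein species mismatch")
        self.proteins.add(protein)
        self._adj.setdefault(protein.id, set())

    def __contains__(self, protein: Protein) -> bool:
        return protein in self.proteins

    def __len__(self) -> int:
        return len(self.interactions)

    def neighbors(self, protein: Protein) -> set[str]:
        """Ids of proteins sharing an edge with *protein* (may be empty)."""
        return set(self._adj.get(protein.id, ()))

    def has_pair(self, a: Protein, b: Protein) -> bool:
        key = (a.id, b.id) if a.id < b.id else (b.id, a.id)
        return key in self._by_pair

    def edges_for_pair(self, a: Protein, b: Protein) -> list[Interaction]:
        key = (a.id, b.id) if a.id < b.id else (b.id, a.id)
        return list(self._by_pair.get(key, ()))

    def types_for_pair(self, a: Protein, b: Protein) -> set[InteractionType]:
        return {e.itype for e in self.edges_for_pair(a, b)}

    @property
    def n_pairs(self) -> int:
        """Number of distinct interacting protein pairs (any evidence)."""
        return len(self._by_pair)


@dataclass(frozen=True)
class OrthologPair:
    """A scored cross-species ortholog relation between two genes.

    ``inparalog_*`` and ``bootstrap_*`` follow the InParanoid cluster-score
    convention (fractions in [0, 1]); ``seq_identity`` is the fraction of
    identical aligned residues.  Any score may be ``None`` (missing).
    """

    g_source: Protein
    g_target: Protein
    source_db: str
    inparalog_source: float | None = None
    inparalog_target: float | None = None
    bootstrap_source: float | None = None
    bootstrap_target: float | None = None
    seq_identity: float | None = None

    def __post_init__(self) -> None:
        if self.g_source.species == self.g_target.species:
            raise ValueError("ortholog pair must span two species")
        for name in (
            "inparalog_source",
            "inparalog_target",
            "bootstrap_source",
            "bootstrap_target",
            "seq_identity",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def gene_for(self, species: str) -> Protein:
        if self.g_source.species == species:
            return self.g_source
        if self.g_target.species == species:
            return self.g_target
        raise KeyError(species)


class OrthologMapping:
    """Set of scored ortholog pairs, queryable by species pair or gene.

    n:m relations are allowed; the same gene pair may be listed by several
    ortholog databases (one record each), which downstream features count as
    ortholog support.
    """

    def __init__(self, pairs: Iterable[OrthologPair] = ()):
        self._pairs: set[OrthologPair] = set()
        self._by_species: dict[frozenset[str], set[OrthologPair]] = {}
        self._by_gene: dict[tuple[Protein, str], list[OrthologPair]] = {}
        self._by_gene_pair: dict[frozenset[Protein], list[OrthologPair]] = {}
        for p in pairs:
            self.add(p)

    def add(self, pair: OrthologPair) -> None:
        key = frozenset((pair.g_source.id, pair.g_target.id, pair.source_db))
        for existing in self._by_gene_pair.get(
            frozenset((pair.g_source, pair.g_target)), ()
        ):
            if existing.source_db == pair.source_db:
                raise ValueError(
                    f"duplicate ortholog record {pair.g_source.id}–{pair.g_target.id} "
                    f"from {pair.source_db!r}"
                )
        self._pairs.add(pair)
        skey = frozenset((pair.g_source.species, pair.g_target.species))
        self._by_species.setdefault(skey, set()).add(pair)
        self._by_gene.setdefault((pair.g_source, pair.g_target.species), []).append(pair)
        self._by_gene.setdefault((pair.g_target, pair.g_source.species), []).append(pair)
        self._by_gene_pair.setdefault(
            frozenset((pair.g_source, pair.g_target)), []
        ).append(pair)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self):
        return iter(self._pairs)

    @property
    def species_pairs(self) -> set[frozenset[str]]:
        return set(self._by_species)

    def pairs_between(self, sp1: str, sp2: str) -> set[OrthologPair]:
        return set(self._by_species.get(frozenset((sp1, sp2)), ()))

    def orthologs_of(self, gene: Protein, target_species: str) -> list[OrthologPair]:
        """All records mapping *gene* into *target_species*."""
        return list(self._by_gene.get((gene, target_species), ()))

    def records_for(self, g1: Protein, g2: Protein) -> list[OrthologPair]:
        return list(self._by_gene_pair.get(frozenset((g1, g2)), ()))

    def has_relation(self, g1: Protein, g2: Protein) -> bool:
        return bool(self._by_gene_pair.get(frozenset((g1, g2))))


class GoCategory(str, Enum):
    B = "B"  # biological_process
    C = "C"  # cellular_component
    M = "M"  # molecular_function


_NAMESPACE_TO_CATEGORY = {
    "biological_process": GoCategory.B,
    "cellular_component": GoCategory.C,
    "molecular_function": GoCategory.M,
}


class GoDag:
    """A GO-style DAG restricted to ``is_a`` edges, split into the three
    standard categories, each with a single root."""

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        category: Mapping[str, GoCategory],
    ):
        self.parents: dict[str, set[str]] = {t: set(ps) for t, ps in parents.items()}
        self.category: dict[str, GoCategory] = dict(category)
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValueError(f"term {t} has unknown parent {p}")
                if self.category[p] != self.category[t]:
                    raise ValueError(
                        f"is_a edge {t} -> {p} crosses categories "
                        f"({self.category[t].value} -> {self.category[p].value})"
                    )
        self._check_acyclic()
        self.roots: dict[GoCategory, str] = {}
        for t, ps in self.parents.items():
            if not ps:
                cat = self.category[t]
                if cat in self.roots:
                    raise ValueError(f"two roots in category {cat.value}")
                self.roots[cat] = t
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        terms = sorted({n for edge in cycle for n in edge[:2]})
        raise ValueError(f"cycle in is_a hierarchy involving: {', '.join(terms)}")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """The term itself plus all is_a ancestors up to its root."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """The term itself plus all terms that reach it via is_a."""
        children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        out = {term}
        stack = list(children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children[t])
        return frozenset(out)


@dataclass
class AnnotationStore:
    """Per-protein functional annotations.

    go_terms maps a protein to its directly annotated GO term ids; tokens
    holds prepared lowercase description tokens; domains holds InterPro/PFAM
    ids; pathways holds pathway ids; expression holds per-species intensity
    vectors (equal length within a species).
    """

    go_terms: dict[Protein, set[str]] = field(default_factory=dict)
    tokens: dict[Protein, set[str]] = field(default_factory=dict)
    domains: dict[Protein, set[str]] = field(default_factory=dict)
    pathways: dict[Protein, set[str]] = field(default_factory=dict)
    expression: dict[Protein, tuple[float, ...]] = field(default_factory=dict)

    def validate_against(self, dag: GoDag) -> None:
        for p, terms in self.go_terms.items():
            for t in terms:
                if t not in dag:
                    raise ValueError(f"protein {p.id} annotated with unknown term {t}")
        by_species: dict[str, int] = {}
        for p, vec in self.expression.items():
            n = by_species.setdefault(p.species, len(vec))
            if len(vec) != n:
                raise ValueError(
                    f"expression vector length mismatch for species {p.species}"
                )

    def go_terms_in_category(self, p: Protein, dag: GoDag, cat: GoCategory) -> set[str]:
        return {t for t in self.go_terms.get(p, ()) if dag.category[t] is cat}


class PhyloTree:
    """Rooted species tree with optional branch lengths.

    Inner nodes without a label are auto-named ``n1``, ``n2``, ... in
    preorder so paths can be reported deterministically.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        counter = itertools.count(1)
        for node in tree.preorder_node_iter():
            if node.taxon is None and not node.label:
                node.label = f"n{next(counter)}"
        self._graph = nx.Graph()
        for node in tree.preorder_node_iter():
            name = self._node_name(node)
            self._graph.add_node(name, is_leaf=node.is_leaf())
            if node.parent_node is not None:
                length = node.edge.length if node.edge.length is not None else None
                self._graph.add_edge(
                    self._node_name(node.parent_node), name, length=length
                )

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    @property
    def leaves(self) -> set[str]:
        return {n for n, d in self._graph.nodes(data=True) if d["is_leaf"]}

    def is_leaf(self, name: str) -> bool:
        return name in self._graph.nodes and self._graph.nodes[name]["is_leaf"]

    def path(self, a: str, b: str) -> list[str]:
        """Node names on the unique path from *a* to *b*, inclusive."""
        return nx.shortest_path(self._graph, a, b)

    def distance(self, s1: str, s2: str) -> float:
        """Patristic distance between two leaves.

        Uses branch lengths when present on every edge of the path; the
        number of edges otherwise.
        """
        for s in (s1, s2):
            if not self.is_leaf(s):
                raise KeyError(f"{s!r} is not a leaf of the tree")
        if s1 == s2:
            return 0.0
        nodes = self.path(s1, s2)
        lengths = [
            self._graph.edges[u, v]["length"] for u, v in zip(nodes, nodes[1:])
        ]
        if any(l is None for l in lengths):
            return float(len(nodes) - 1)
        return float(sum(lengths))

    def closest_leaf(self, node: str, exclude: frozenset[str] = frozenset()) -> str | None:
        """The leaf reachable from *node* in the fewest edges, ignoring the
        leaves in *exclude*.

        Ties are broken lexicographically on the leaf name so the answer is
        deterministic.  None when every leaf is excluded.
        """
        if self.is_leaf(node) and node not in exclude:
            return node
        depths = nx.single_source_shortest_path_length(self._graph, node)
        leaves = [
            (d, n)
            for n, d in depths.items()
            if self.is_leaf(n) and n not in exclude
        ]
        if not leaves:
            return None
        return min(leaves)[1]

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# Readers / writers


def _as_stream(stream: TextIO | str) -> TextIO:
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


_INTERACTION_HEADER = ["idA", "idB", "itype", "source_db", "pubmed_ids"]


def parse_interaction_table(stream: TextIO | str, species: str) -> InteractionNetwork:
    """Read a tab-separated interaction table into an InteractionNetwork.

    Duplicate rows for the same canonical (pair, itype, source_db) are
    collapsed with their PubMed evidence unioned.
    """
    fh = _as_stream(stream)
    header = fh.readline().rstrip("\n").split("\t")
    if header != _INTERACTION_HEADER:
        raise ParseError(
            f"bad interaction header {header!r}; expected {_INTERACTION_HEADER!r}"
        )
    merged: dict[tuple[str, str, InteractionType, str], set[str]] = {}
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"line {lineno}: expected 5 fields, got {len(fields)}")
        id_a, id_b, itype_tok, db, pubmed = fields
        if id_a == id_b:
            raise ParseError(f"line {lineno}: self-interaction on {id_a!r}")
        try:
            itype = InteractionType.from_token(itype_tok)
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if id_a > id_b:
            id_a, id_b = id_b, id_a
        pmids = {p for p in pubmed.split("|") if p}
        merged.setdefault((id_a, id_b, itype, db), set()).update(pmids)
    net = InteractionNetwork(species)
    for (id_a, id_b, itype, db), pmids in merged.items():
        net.add(
            Interaction(
                Protein(id_a, species),
                Protein(id_b, species),
                itype,
                db,
                frozenset(pmids),
            )
        )
    return net


def write_interaction_table(net: InteractionNetwork, fh: TextIO) -> None:
    fh.write("\t".join(_INTERACTION_HEADER) + "\n")
    for inter in sorted(
        net.interactions, key=lambda e: (e.pair, e.itype.value, e.source_db)
    ):
        fh.write(
            "\t".join(
                [
                    inter.a.id,
                    inter.b.id,
                    inter.itype.value,
                    inter.source_db,
                    "|".join(sorted(inter.pubmed_ids)),
                ]
            )
            + "\n"
        )


_ORTHOLOG_HEADER = [
    "gene_source",
    "sp_source",
    "gene_target",
    "sp_target",
    "db",
    "inpara_s",
    "inpara_t",
    "boot_s",
    "boot_t",
    "seq_identity",
]


def _parse_score(token: str, name: str, lineno: int) -> float | None:
    if token == "NA":
        return None
    try:
        v = float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: {name} is not a number: {token!r}") from None
    if not (0.0 <= v <= 1.0):
        raise ParseError(f"line {lineno}: {name}={v} outside [0, 1]")
    return v


def parse_ortholog_table(stream: TextIO | str) -> OrthologMapping:
    """Read a tab-separated ortholog table (``NA`` marks a missing score)."""
    fh = _as_stream(stream)
    header = fh.readline().rstrip("\n").split("\t")
    if header != _ORTHOLOG_HEADER:
        raise ParseError(
            f"bad ortholog header {header!r}; expected {_ORTHOLOG_HEADER!r}"
        )
    mapping = OrthologMapping()
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 10:
            raise ParseError(f"line {lineno}: expected 10 fields, got {len(fields)}")
        (g_s, sp_s, g_t, sp_t, db, inp_s, inp_t, b_s, b_t, seq_id) = fields
        if sp_s == sp_t:
            raise ParseError(f"line {lineno}: sp_source == sp_target ({sp_s!r})")
        pair = OrthologPair(
            g_source=Protein(g_s, sp_s),
            g_target=Protein(g_t, sp_t),
            source_db=db,
            inparalog_source=_parse_score(inp_s, "inpara_s", lineno),
            inparalog_target=_parse_score(inp_t, "inpara_t", lineno),
            bootstrap_source=_parse_score(b_s, "boot_s", lineno),
            bootstrap_target=_parse_score(b_t, "boot_t", lineno),
            seq_identity=_parse_score(seq_id, "seq_identity", lineno),
        )
        try:
            mapping.add(pair)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return mapping


def write_ortholog_table(mapping: OrthologMapping, fh: TextIO) -> None:
    def fmt(v: float | None) -> str:
        return "NA" if v is None else f"{v:.6g}"

    fh.write("\t".join(_ORTHOLOG_HEADER) + "\n")
    for p in sorted(
        mapping, key=lambda p: (p.g_source.id, p.g_target.id, p.source_db)
    ):
        fh.write(
            "\t".join(
                [
                    p.g_source.id,
                    p.g_source.species,
                    p.g_target.id,
                    p.g_target.species,
                    p.source_db,
                    fmt(p.inparalog_source),
                    fmt(p.inparalog_target),
                    fmt(p.bootstrap_source),
                    fmt(p.bootstrap_target),
                    fmt(p.seq_identity),
                ]
            )
            + "\n"
        )


def parse_obo(stream: TextIO | str) -> GoDag:
    """Read a GO OBO file, keeping only id / namespace / is_a.

    Obsolete terms are dropped (obonet already removes them); cycles raise.
    """
    fh = _as_stream(stream)
    graph = obonet.read_obo(fh, ignore_obsolete=True)
    parents: dict[str, set[str]] = {}
    category: dict[str, GoCategory] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in _NAMESPACE_TO_CATEGORY:
            raise ParseError(f"term {term} has unknown namespace {ns!r}")
        category[term] = _NAMESPACE_TO_CATEGORY[ns]
        parents[term] = set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    try:
        return GoDag(parents, category)
    except ValueError as exc:
        raise ParseError(str(exc)) from None


def parse_newick(stream: TextIO | str) -> PhyloTree:
    """Read a single rooted Newick tree."""
    text = _as_stream(stream).read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"newick parse error: {exc}") from None
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, fh: TextIO) -> None:
    fh.write(tree.newick() + "\n")


def _parse_set(block: str) -> set[str]:
    if block == "NA" or block == "":
        return set()
    return {tok for tok in block.split("|") if tok}


def parse_annotation_table(
    stream: TextIO | str, species: str, store: AnnotationStore | None = None
) -> AnnotationStore:
    """Read per-protein GO / token / domain / pathway annotations.

    Columns: ``protein  go_terms  tokens  domains  pathways`` with
    pipe-separated sets, ``NA`` for an absent block.  Appends into *store*
    when given so multi-species annotation files can be accumulated.
    """
    fh = _as_stream(stream)
    header = fh.readline().rstrip("\n").split("\t")
    if header != ["protein", "go_terms", "tokens", "domains", "pathways"]:
        raise ParseError(f"bad annotation header {header!r}")
    store = store if store is not None else AnnotationStore()
    for lineno, line in enumerate(fh, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(f"line {lineno}: expected 5 fields, got {len(fields)}")
        p = Protein(fields[0], species)
        go, tokens, domains, pathways = map(_parse_set, fields[1:])
        if any(t != t.lower() for t in tokens):
            raise ParseError(f"line {lineno}: tokens must be lowercase")
        if go:
            store.go_terms.setdefault(p, set()).update(go)
        if tokens:
            store.tokens.setdefault(p, set()).update(tokens)
        if domains:
            store.domains.setdefault(p, set()).update(domains)
        if pathways:
            store.pathways.setdefault(p, set()).update(pathways)
    return store


def write_annotation_table(
    store: AnnotationStore, species: str, fh: TextIO
) -> None:
    def fmt(s: set[str]) -> str:
        return "|".join(sorted(s)) if s else "NA"

    proteins = sorted(
        {
            p
            for d in (store.go_terms, store.tokens, store.domains, store.pathways)
            for p in d
            if p.species == species
        }
    )
    fh.write("protein\tgo_terms\ttokens\tdomains\tpathways\n")
    for p in proteins:
        fh.write(
            "\t".join(
                [
                    p.id,
                    fmt(store.go_terms.get(p, set())),
                    fmt(store.tokens.get(p, set())),
                    fmt(store.domains.get(p, set())),
                    fmt(store.pathways.get(p, set())),
                ]
            )
            + "\n"
        )


def parse_expression_table(
    stream: TextIO | str, species: str, store: AnnotationStore | None = None
) -> AnnotationStore:
    """Read per-protein expression vectors: ``protein  v1  v2 ...``."""
    fh = _as_stream(stream)
    store = store if store is not None else AnnotationStore()
    width: int | None = None
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected protein and ≥1 value")
        try:
            vec = tuple(float(v) for v in fields[1:])
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric expression value") from None
        if width is None:
            width = len(vec)
        elif len(vec) != width:
            raise ParseError(f"line {lineno}: expected {width} values, got {len(vec)}")
        store.expression[Protein(fields[0], species)] = vec
    return store


def write_expression_table(store: AnnotationStore, species: str, fh: TextIO) -> None:
    for p in sorted(p for p in store.expression if p.species == species):
        vec = store.expression[p]
        fh.write(p.id + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")
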