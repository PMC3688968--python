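"""Feature computation for transferred interactions.

Every transfer instance involves four proteins: the source interaction
partners (pairing S), the two target proteins (pairing T) and the two
ortholog pairs linking them (pairings O1 and O2).  Twenty feature types are
modeled across these pairings; ortholog features are emitted once per
ortholog pair.  A feature that cannot be computed from the available
annotation is a missing value (None / NaN), never silently zero.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .go_semantics import IcTable, protein_go_similarity
from .iodata import (
    AnnotationStore,
    GoDag,
    InteractionNetwork,
    OrthologMapping,
    OrthologPair,
    PhyloTree,
    Protein,
)
from .transfer import TransferredInteraction

__all__ = [
    "FEATURE_TABLE",
    "FEATURE_SETS",
    "FeatureContext",
    "feature_schema",
    "network_overlap",
    "network_go_similarity",
    "harmonic_sequence_similarity",
    "token_similarity",
    "domain_similarity",
    "expression_correlation",
    "ortholog_score",
    "ortholog_support",
    "pathway_score",
    "phylo_distance",
    "transitive_ortholog",
    "build_transfer_index",
    "build_feature_vector",
    "build_feature_matrix",
    "prepare_tokens",
]

# feature type -> (pairings in which it is modeled, value kind)
FEATURE_TABLE: dict[str, tuple[tuple[str, ...], str]] = {
    "network_overlap": (("S", "T"), "real"),
    "go_network": (("S", "T"), "real"),
    "go_global": (("S", "T", "O"), "real"),
    "go_B": (("S", "T", "O"), "real"),
    "go_C": (("S", "T", "O"), "real"),
    "go_M": (("S", "T", "O"), "real"),
    "source_db": (("S",), "categorical"),
    "edge_support": (("S",), "int"),
    "source_itype": (("S",), "categorical"),
    "total_support": (("T",), "int"),
    "expression_corr": (("T",), "real"),
    "seq_identity": (("O",), "real"),
    "token_similarity": (("O",), "real"),
    "domain_similarity": (("O",), "real"),
    "pathway_score": (("O",), "real"),
    "ortholog_source": (("O",), "categorical"),
    "ortholog_score": (("O",), "real"),
    "ortholog_support": (("O",), "int"),
    "transitive_ortholog": (("O",), "real"),
    "phylo_distance": (("O",), "real"),
}

_BLOCKS = {
    "network": ("network_overlap", "go_network"),
    "go": ("go_global", "go_B", "go_C", "go_M"),
    "general": (
        "source_db",
        "edge_support",
        "source_itype",
        "total_support",
        "expression_corr",
    ),
    "ortholog": (
        "seq_identity",
        "token_similarity",
        "domain_similarity",
        "pathway_score",
        "ortholog_source",
        "ortholog_score",
        "ortholog_support",
        "transitive_ortholog",
        "phylo_distance",
    ),
}

# named feature sets: which feature types each includes
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "full": tuple(FEATURE_TABLE),
    "reduced": tuple(
        f
        for f in FEATURE_TABLE
        if f not in ("network_overlap", "go_network", "expression_corr")
    ),
    "network": _BLOCKS["network"],
    "go": _BLOCKS["go"],
    "general": _BLOCKS["general"],
    "ortholog": _BLOCKS["ortholog"],
}


def feature_schema(set_name: str) -> dict[str, str]:
    """Column name -> value kind for a named feature set.

    Ortholog-pairing features expand into one column per ortholog pair
    (suffixes ``(O1)`` and ``(O2)``).
    """
    if set_name not in FEATURE_SETS:
        raise KeyError(
            f"unknown feature set {set_name!r}; known: {sorted(FEATURE_SETS)}"
        )
    schema: dict[str, str] = {}
    for ftype in FEATURE_SETS[set_name]:
        pairings, kind = FEATURE_TABLE[ftype]
        for p in pairings:
            if p == "O":
                schema[f"{ftype} (O1)"] = kind
                schema[f"{ftype} (O2)"] = kind
            else:
                schema[f"{ftype} ({p})"] = kind
    return schema


# ---------------------------------------------------------------------------
# individual feature operations


def network_overlap(
    net: InteractionNetwork, a: Protein, b: Protein
) -> float | None:
    """Jaccard index of the direct neighborhoods of a and b.

    The two proteins are removed from each other's neighbor sets first, so
    an edge between them does not contribute.  0/0 (both isolated) and a
    protein absent from the network are missing, not zero.
    """
    if a not in net or b not in net:
        return None
    na = net.neighbors(a) - {b.id}
    nb = net.neighbors(b) - {a.id}
    union = na | nb
    if not union:
        return None
    return len(na & nb) / len(union)


def network_go_similarity(
    net: InteractionNetwork,
    a: Protein,
    b: Protein,
    ic: IcTable,
    dag: GoDag,
    ann: AnnotationStore,
    _cache: dict | None = None,
) -> float | None:
    """Mean semantic GO similarity over all neighbor pairs N(a) x N(b).

    Pairs where the similarity is missing are skipped; missing overall if a
    neighborhood is empty or no pair is computable.
    """
    if a not in net or b not in net:
        return None
    na = sorted(net.neighbors(a) - {b.id})
    nb = sorted(net.neighbors(b) - {a.id})
    if not na or not nb:
        return None
    values = []
    for u in na:
        pu = Protein(u, net.species)
        for v in nb:
            pv = Protein(v, net.species)
            if _cache is not None:
                key = (ic.category, u, v) if u <= v else (ic.category, v, u)
                if key in _cache:
                    s = _cache[key]
                else:
                    s = protein_go_similarity(ic, dag, ann, pu, pv)
                    _cache[key] = s
            else:
                s = protein_go_similarity(ic, dag, ann, pu, pv)
            if s is not None:
                values.append(s)
    if not values:
        return None
    return float(np.mean(values))


def harmonic_sequence_similarity(
    id1: float | None, id2: float | None
) -> float | None:
    """Harmonic mean of the two ortholog sequence identities."""
    if id1 is None or id2 is None:
        return None
    if id1 == 0.0 and id2 == 0.0:
        return 0.0
    return 2.0 * id1 * id2 / (id1 + id2)


def _jaccard(s1: set[str], s2: set[str]) -> float | None:
    if not s1 or not s2:
        return None
    return len(s1 & s2) / len(s1 | s2)


def token_similarity(ann: AnnotationStore, p1: Protein, p2: Protein) -> float | None:
    """Jaccard index of the prepared description-token sets."""
    return _jaccard(ann.tokens.get(p1, set()), ann.tokens.get(p2, set()))


def domain_similarity(ann: AnnotationStore, p1: Protein, p2: Protein) -> float | None:
    """Jaccard index of the pooled InterPro/PFAM domain id sets."""
    return _jaccard(ann.domains.get(p1, set()), ann.domains.get(p2, set()))


def pathway_score(ann: AnnotationStore, p1: Protein, p2: Protein) -> float | None:
    """1.0 iff the two proteins share a pathway id; missing if either set
    is empty."""
    s1 = ann.pathways.get(p1, set())
    s2 = ann.pathways.get(p2, set())
    if not s1 or not s2:
        return None
    return 1.0 if s1 & s2 else 0.0


def expression_correlation(
    ann: AnnotationStore, p1: Protein, p2: Protein
) -> float | None:
    """Pearson correlation of the two expression vectors.

    Missing if either vector is absent, shorter than 3 conditions, or
    constant (undefined variance).
    """
    v1 = ann.expression.get(p1)
    v2 = ann.expression.get(p2)
    if v1 is None or v2 is None:
        return None
    if len(v1) < 3 or len(v2) < 3 or len(v1) != len(v2):
        return None
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


def ortholog_score(pair: OrthologPair) -> float | None:
    """Combined InParanoid-style confidence of an ortholog pair:
    (i_s * b_s + i_t * b_t) / 2.  Missing if any component is missing."""
    i_s, i_t = pair.inparalog_source, pair.inparalog_target
    b_s, b_t = pair.bootstrap_source, pair.bootstrap_target
    if None in (i_s, i_t, b_s, b_t):
        return None
    return (i_s * b_s + i_t * b_t) / 2.0


def ortholog_support(mapping: OrthologMapping, g1: Protein, g2: Protein) -> int:
    """Number of distinct ortholog databases listing the gene pair."""
    records = mapping.records_for(g1, g2)
    if not records:
        raise KeyError(f"no ortholog record for {g1.id}–{g2.id}")
    return len({r.source_db for r in records})


def phylo_distance(tree: PhyloTree, s1: str, s2: str) -> float:
    """Patristic distance between two species leaves (edge count when the
    tree carries no branch lengths)."""
    return tree.distance(s1, s2)


def intermediate_species(tree: PhyloTree, src_sp: str, tgt_sp: str) -> list[str]:
    """Species 'between' source and target on the tree.

    For each inner node on the src->tgt path, take its closest leaf other
    than the two endpoint species (fewest edges; lexicographic tie-break),
    deduped preserving order.
    """
    path = tree.path(src_sp, tgt_sp)
    exclude = frozenset((src_sp, tgt_sp))
    out: list[str] = []
    for node in path[1:-1]:
        leaf = tree.closest_leaf(node, exclude=exclude)
        if leaf is None or leaf in out:
            continue
        out.append(leaf)
    return out


def transitive_ortholog(
    tree: PhyloTree,
    mapping: OrthologMapping,
    src_sp: str,
    tgt_sp: str,
    g_src: Protein,
    g_tgt: Protein,
) -> bool:
    """Whether the direct ortholog relation can be re-traced hop by hop
    through the species lying between source and target on the tree.

    A chain g_src -> x1 -> ... -> g_tgt must follow pairwise ortholog
    records through every intermediate species in order; a species with no
    record for its hop breaks the chain (returns False).  With no
    intermediates the direct record alone suffices.
    """
    if src_sp == tgt_sp:
        raise ValueError("source and target species must differ")
    if not mapping.has_relation(g_src, g_tgt):
        raise KeyError(f"no direct ortholog record {g_src.id}–{g_tgt.id}")
    chain_species = intermediate_species(tree, src_sp, tgt_sp)
    if not chain_species:
        return True

    def reachable(current: Protein, remaining: list[str]) -> bool:
        if not remaining:
            return mapping.has_relation(current, g_tgt)
        next_sp = remaining[0]
        for rec in mapping.orthologs_of(current, next_sp):
            if reachable(rec.gene_for(next_sp), remaining[1:]):
                return True
        return False

    return reachable(g_src, chain_species)


def build_transfer_index(
    transfers: Iterable[TransferredInteraction],
) -> dict[tuple[str, str], set[str]]:
    """Index: canonical target pair -> set of source species transferring it."""
    index: dict[tuple[str, str], set[str]] = {}
    for tr in transfers:
        index.setdefault(tr.target_pair, set()).add(tr.source_species)
    return index


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureContext:
    """Everything needed to featurize a batch of transfer instances.

    target_net is the target-species network used for (T) network features;
    it may be None in production mode, in which case all (T) network
    features are missing.  ic_tables must hold the keys "global", "B", "C",
    "M".
    """

    source_nets: Mapping[str, InteractionNetwork]
    mapping: OrthologMapping
    dag: GoDag
    ic_tables: Mapping[str, IcTable]
    ann: AnnotationStore
    tree: PhyloTree
    target_net: InteractionNetwork | None = None
    pair_index: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    _go_cache: dict = field(default_factory=dict, repr=False)
    _trans_cache: dict = field(default_factory=dict, repr=False)

    def protein_sim(self, table_key: str, p1: Protein, p2: Protein) -> float | None:
        key = (
            (table_key, p1.id, p2.id)
            if (p1.species, p1.id) <= (p2.species, p2.id)
            else (table_key, p2.id, p1.id)
        )
        if key in self._go_cache:
            return self._go_cache[key]
        s = protein_go_similarity(self.ic_tables[table_key], self.dag, self.ann, p1, p2)
        self._go_cache[key] = s
        return s


_GO_KEYS = {"go_global": "global", "go_B": "B", "go_C": "C", "go_M": "M"}


def build_feature_vector(
    tr: TransferredInteraction,
    ctx: FeatureContext,
    set_name: str = "full",
) -> dict[str, object]:
    """Compute the named feature set for one transfer instance.

    Returns a flat dict column-name -> value with None marking missing.
    """
    schema = feature_schema(set_name)
    src_net = ctx.source_nets.get(tr.source_species)
    if src_net is None:
        raise KeyError(f"no source network for species {tr.source_species!r}")
    s1, s2 = tr.source.a, tr.source.b
    t1, t2 = tr.t_a, tr.t_b
    pair_proteins = {"S": (s1, s2), "T": (t1, t2)}
    orth_pairs = {"O1": tr.ortho_a, "O2": tr.ortho_b}

    values: dict[str, object] = {}
    for column in schema:
        ftype, pairing = column.rsplit(" (", 1)
        pairing = pairing.rstrip(")")
        values[column] = _compute_cell(ftype, pairing, tr, ctx, src_net,
                                       pair_proteins, orth_pairs)
    return values


def _compute_cell(ftype, pairing, tr, ctx, src_net, pair_proteins, orth_pairs):
    if ftype in ("network_overlap", "go_network"):
        net = src_net if pairing == "S" else ctx.target_net
        if net is None:
            return None
        a, b = pair_proteins[pairing]
        if pairing == "T":
            a, b = tr.t_a, tr.t_b
        if ftype == "network_overlap":
            return network_overlap(net, a, b)
        return network_go_similarity(
            net, a, b, ctx.ic_tables["global"], ctx.dag, ctx.ann,
            _cache=ctx._go_cache,
        )
    if ftype in _GO_KEYS:
        table_key = _GO_KEYS[ftype]
        if pairing in ("S", "T"):
            a, b = pair_proteins[pairing]
        else:
            op = orth_pairs[pairing]
            a, b = op.g_source, op.g_target
        return ctx.protein_sim(table_key, a, b)
    if ftype == "source_db":
        return tr.source.source_db
    if ftype == "edge_support":
        return len(tr.source.pubmed_ids)
    if ftype == "source_itype":
        return tr.source.itype.value
    if ftype == "total_support":
        others = ctx.pair_index.get(tr.target_pair, set()) - {tr.source_species}
        return len(others)
    if ftype == "expression_corr":
        return expression_correlation(ctx.ann, tr.t_a, tr.t_b)
    # ortholog-pair features
    op = orth_pairs[pairing]
    if ftype == "seq_identity":
        return op.seq_identity
    if ftype == "token_similarity":
        return token_similarity(ctx.ann, op.g_source, op.g_target)
    if ftype == "domain_similarity":
        return domain_similarity(ctx.ann, op.g_source, op.g_target)
    if ftype == "pathway_score":
        return pathway_score(ctx.ann, op.g_source, op.g_target)
    if ftype == "ortholog_source":
        return op.source_db
    if ftype == "ortholog_score":
        return ortholog_score(op)
    if ftype == "ortholog_support":
        return ortholog_support(ctx.mapping, op.g_source, op.g_target)
    if ftype == "transitive_ortholog":
        key = (op.g_source, op.g_target)
        if key not in ctx._trans_cache:
            ctx._trans_cache[key] = float(
                transitive_ortholog(
                    ctx.tree,
                    ctx.mapping,
                    op.g_source.species,
                    op.g_target.species,
                    op.g_source,
                    op.g_target,
                )
            )
        return ctx._trans_cache[key]
    if ftype == "phylo_distance":
        return phylo_distance(ctx.tree, op.g_source.species, op.g_target.species)
    raise KeyError(f"unknown feature type {ftype!r}")


def build_feature_matrix(
    transfers: list[TransferredInteraction],
    ctx: FeatureContext,
    set_name: str = "full",
) -> pd.DataFrame:
    """Featurize a batch of transfer instances into a DataFrame.

    The pair index for total-support is (re)built over the batch.  Missing
    values are NaN for numeric columns and None for categorical ones.
    """
    ctx.pair_index = build_transfer_index(transfers)
    schema = feature_schema(set_name)
    rows = [build_feature_vector(tr, ctx, set_name) for tr in transfers]
    df = pd.DataFrame(rows, columns=list(schema))
    for col, kind in schema.items():
        if kind in ("real", "int"):
            df[col] = pd.to_numeric(df[col])
    df.attrs["schema"] = schema
    df.attrs["feature_set"] = set_name
    return df


# ---------------------------------------------------------------------------
# token preparation

_STOP_WORDS = frozenset(
    """a an and are as at be but by for from has have in is it its of on or
    that the this to was were which with protein gene putative probable
    uncharacterized""".split()
)

_SUFFIXES = ("ations", "ation", "ingly", "ings", "ing", "edly", "ed", "ies",
              "es", "e", "s", "ly")


def _stem(token: str) -> str:
    """Light rule-based English suffix stripper (longest matching suffix,
    keeping stems of at least 3 characters)."""
    for suf in _SUFFIXES:
        if token.endswith(suf) and len(token) - len(suf) >= 3:
            return token[: -len(suf)]
    return token


def prepare_tokens(
    descriptions: Mapping[Protein, str], general_threshold: float = 0.10
) -> dict[Protein, set[str]]:
    """Turn free-text protein descriptions into prepared token sets.

    Lowercases, splits on non-alphanumerics, drops stop words and 1-letter
    tokens, stems, and removes tokens occurring in more than
    *general_threshold* of all proteins (too generic to be descriptive).
    """
    raw: dict[Protein, set[str]] = {}
    doc_freq: dict[str, int] = {}
    for p, text in descriptions.items():
        toks = {
            _stem(t)
            for t in re.split(r"[^0-9a-z]+", text.lower())
            if len(t) > 1 and t not in _STOP_WORDS
        }
        raw[p] = toks
        for t in toks:
            doc_freq[t] = doc_freq.get(t, 0) + 1
    n = max(len(raw), 1)
    general = {t for t, c in doc_freq.items() if c / n > general_threshold}
    return {p: toks - general for p, toks in raw.items()}
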