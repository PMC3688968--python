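"""Synthetic multi-species worlds with planted interolog conservation.

A world consists of per-species interaction networks, scored n:m ortholog
mappings, a small three-category GO DAG with annotations, description
tokens, domains, pathways, expression profiles, a species tree, and a
ground truth assigning each transferable target pair a conserved /
not-conserved status.

Conservation is planted per *target family pair* (interolog): whether the
pair appears in the target gold network is decided once, with probability
``conservation_rate``, and shared by every source edge mapping onto it.
Planting per source edge instead would make consistency depend on how many
species transfer a pair — the gold network is shared — so zero-signal
worlds would not be null.  When a pair is conserved, every ortholog
combination reaching it is written into the gold network, so a direct
transfer at zero feature signal has consistency exactly equal to the
conservation rate.

``feature_signal`` controls, per feature block, how strongly the planted
conservation is reflected in the features: family "quality" and module
co-membership shift ortholog scores, GO annotation fidelity, token/domain
retention and expression correlation only in proportion to the respective
block's signal.  At signal 0 every feature is independent of the labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iodata import (
    AnnotationStore,
    GoCategory,
    GoDag,
    Interaction,
    InteractionNetwork,
    InteractionType,
    OrthologMapping,
    OrthologPair,
    PhyloTree,
    Protein,
    parse_newick,
    write_annotation_table,
    write_expression_table,
    write_interaction_table,
    write_newick,
    write_ortholog_table,
)

__all__ = ["WorldConfig", "World", "generate", "world_fixtures", "write_world"]

_BLOCKS = ("network", "go", "ortholog", "expression", "general")


@dataclass
class WorldConfig:
    """Generation parameters for a synthetic world.

    n_species includes the target; feature_signal is either one strength in
    [0, 1] for all blocks or a per-block dict with keys
    network/go/ortholog/expression/general.
    """

    n_species: int = 4
    genes_per_species: int = 150
    tree: str | None = None
    ortholog_coverage: float = 0.75
    cluster_size_probs: dict = field(
        default_factory=lambda: {"1:1": 0.8, "1:2": 0.15, "2:2": 0.05}
    )
    edges_per_species: int = 900
    conservation_rate: float = 0.3
    rewire_rate: float = 0.3
    feature_signal: float | dict = 0.0
    annotation_coverage: float = 0.9
    module_size: int = 8
    within_module_edge_prob: float = 0.7
    multi_db_rate: float = 0.2
    background_edges_per_gene: float = 2.0
    expression_conditions: int = 20
    seed: int = 0

    def signal(self, block: str) -> float:
        if isinstance(self.feature_signal, dict):
            return float(self.feature_signal.get(block, 0.0))
        return float(self.feature_signal)

    def validate(self) -> None:
        fracs = {
            "ortholog_coverage": self.ortholog_coverage,
            "conservation_rate": self.conservation_rate,
            "rewire_rate": self.rewire_rate,
            "multi_db_rate": self.multi_db_rate,
            "annotation_coverage": self.annotation_coverage,
            "within_module_edge_prob": self.within_module_edge_prob,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for b in _BLOCKS:
            if not (0.0 <= self.signal(b) <= 1.0):
                raise ValueError(f"feature_signal[{b}] outside [0, 1]")
        if abs(sum(self.cluster_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("cluster_size_probs must sum to 1")
        if set(self.cluster_size_probs) - {"1:1", "1:2", "2:2"}:
            raise ValueError("cluster sizes limited to 1:1, 1:2, 2:2")
        if self.n_species < 2:
            raise ValueError("need at least a source and a target species")


@dataclass
class World:
    config: WorldConfig
    target_species: str
    source_species: list[str]
    networks: dict[str, InteractionNetwork]
    mapping: OrthologMapping
    dag: GoDag
    ann: AnnotationStore
    tree: PhyloTree
    truth: dict[tuple[str, str], bool]

    @property
    def gold(self) -> InteractionNetwork:
        return self.networks[self.target_species]


def _default_tree(species: list[str], target: str) -> str:
    """Caterpillar tree placing the target next to the first source."""
    sources = [s for s in species if s != target]
    core = f"({sources[0]}:1,{target}:1)"
    for s in sources[1:]:
        core = f"({core}:1,{s}:1)"
    return core + ";"


def _add_family_m_terms(
    parents: dict[str, set[str]],
    category: dict[str, GoCategory],
    n_families: int,
    module_of,
) -> None:
    for k in range(n_families):
        parents[f"M:fam{k}"] = {f"M:mod{module_of(k)}"}
        category[f"M:fam{k}"] = GoCategory.M


def generate(config: WorldConfig) -> World:  # noqa: C901 - one linear recipe
    """Build a complete world from the configuration (reproducible from
    the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_src = config.n_species - 1
    target = "tgt"
    sources = [f"src{i + 1}" for i in range(n_src)]
    species = sources + [target]
    tree = parse_newick(config.tree or _default_tree(species, target))
    missing_leaves = set(species) - tree.leaves
    if missing_leaves:
        raise ValueError(f"tree lacks leaves for species: {sorted(missing_leaves)}")

    G = config.genes_per_species
    module_of = lambda k: k // config.module_size  # noqa: E731
    n_modules = math.ceil(G / config.module_size)

    def gene(sp: str, fam: int, paralog: bool = False) -> Protein:
        suffix = "b" if paralog else ""
        return Protein(f"{sp}g{fam:04d}{suffix}", sp)

    # --- GO DAG -----------------------------------------------------------
    parents: dict[str, set[str]] = {}
    category: dict[str, GoCategory] = {}

    def add_term(term: str, cat: GoCategory, *ps: str) -> None:
        parents[term] = set(ps)
        category[term] = cat

    add_term("B:root", GoCategory.B)
    add_term("C:root", GoCategory.C)
    add_term("M:root", GoCategory.M)
    for g in range(max(1, math.ceil(n_modules / 4))):
        add_term(f"B:grp{g}", GoCategory.B, "B:root")
    for m in range(n_modules):
        add_term(f"B:mod{m}", GoCategory.B, f"B:grp{m // 4}")
        add_term(f"M:mod{m}", GoCategory.M, "M:root")
    for j in range(6):
        add_term(f"C:comp{j}", GoCategory.C, "C:root")
    _add_family_m_terms(parents, category, G, module_of)
    dag = GoDag(parents, category)

    s_go = config.signal("go")
    s_net = config.signal("network")
    s_orth = config.signal("ortholog")
    s_expr = config.signal("expression")
    s_gen = config.signal("general")

    # family quality: how faithfully a family's orthology and annotation
    # reflect its conservation propensity
    quality = rng.uniform(0.0, 1.0, size=G)

    # --- ortholog mapping -------------------------------------------------
    mapping = OrthologMapping()
    cluster_types = sorted(config.cluster_size_probs)
    cluster_p = np.array([config.cluster_size_probs[t] for t in cluster_types])
    paralogs_created: set[Protein] = set()

    def sample_scores(fam: int) -> dict:
        q = quality[fam]
        seq = float(
            np.clip(rng.beta(2.5, 4.5) + s_orth * (q - 0.5) * 0.55, 0.01, 0.99)
        )
        boot = float(np.clip(0.45 + 0.55 * s_orth * q + rng.normal(0, 0.15), 0, 1))
        rec = {
            "seq_identity": seq,
            "bootstrap_source": boot,
            "bootstrap_target": float(np.clip(boot + rng.normal(0, 0.05), 0, 1)),
            "inparalog_source": 1.0,
            "inparalog_target": 1.0,
        }
        if rng.random() < 0.05:
            rec["bootstrap_source"] = None
        if rng.random() < 0.05:
            rec["seq_identity"] = None
        return rec

    for a_idx in range(len(species)):
        for b_idx in range(a_idx + 1, len(species)):
            sp_a, sp_b = species[a_idx], species[b_idx]
            for fam in range(G):
                p_cov = float(
                    np.clip(
                        config.ortholog_coverage
                        + 0.25 * s_orth * (quality[fam] - 0.5),
                        0.02,
                        1.0,
                    )
                )
                if rng.random() >= p_cov:
                    continue
                ctype = cluster_types[rng.choice(len(cluster_types), p=cluster_p)]
                side_a = [gene(sp_a, fam)]
                side_b = [gene(sp_b, fam)]
                if ctype == "1:2":
                    if rng.random() < 0.5:
                        side_a.append(gene(sp_a, fam, paralog=True))
                    else:
                        side_b.append(gene(sp_b, fam, paralog=True))
                elif ctype == "2:2":
                    side_a.append(gene(sp_a, fam, paralog=True))
                    side_b.append(gene(sp_b, fam, paralog=True))
                paralogs_created.update(
                    p for p in side_a + side_b if p.id.endswith("b")
                )
                for ga in side_a:
                    for gb in side_b:
                        rec = sample_scores(fam)
                        if ga.id.endswith("b"):
                            rec["inparalog_source"] = float(rng.uniform(0.3, 1.0))
                        if gb.id.endswith("b"):
                            rec["inparalog_target"] = float(rng.uniform(0.3, 1.0))
                        mapping.add(
                            OrthologPair(g_source=ga, g_target=gb,
                                         source_db="orthdb1", **rec)
                        )
                        p_second = config.multi_db_rate + 0.5 * s_orth * quality[fam]
                        if rng.random() < p_second:
                            rec2 = dict(rec)
                            if rec2["seq_identity"] is not None:
                                rec2["seq_identity"] = float(
                                    np.clip(
                                        rec2["seq_identity"] + rng.normal(0, 0.03),
                                        0.01,
                                        0.99,
                                    )
                                )
                            mapping.add(
                                OrthologPair(g_source=ga, g_target=gb,
                                             source_db="orthdb2", **rec2)
                            )

    # --- source networks --------------------------------------------------
    def sample_family_pair() -> tuple[int, int]:
        if rng.random() < config.within_module_edge_prob:
            m = int(rng.integers(n_modules))
            lo = m * config.module_size
            hi = min(lo + config.module_size, G)
            if hi - lo < 2:
                lo, hi = 0, G
            i, j = rng.choice(np.arange(lo, hi), size=2, replace=False)
        else:
            i, j = rng.choice(G, size=2, replace=False)
        return (int(i), int(j)) if i < j else (int(j), int(i))

    itype_values = [InteractionType.physical, InteractionType.genetic,
                    InteractionType.other]
    itype_p = np.array([0.5, 0.3, 0.2])
    dbs = ["DBa", "DBb", "DBc"]

    conserved_pair: dict[tuple[int, int], bool] = {}

    def is_conserved(i: int, j: int) -> bool:
        key = (i, j)
        if key not in conserved_pair:
            within = module_of(i) == module_of(j)
            adj = 0.45 * s_net * (1.0 if within else -1.0) + 0.5 * s_orth * (
                quality[i] + quality[j] - 1.0
            )
            c = config.conservation_rate
            p = c + (1 - c) * max(adj, 0.0) + c * min(adj, 0.0)
            conserved_pair[key] = bool(rng.random() < p)
        return conserved_pair[key]

    source_edges: dict[str, list[tuple[int, int, InteractionType, str]]] = {}
    networks: dict[str, InteractionNetwork] = {}
    for sp in sources:
        net = InteractionNetwork(sp)
        seen_pairs: set[tuple[int, int]] = set()
        edges = []
        attempts = 0
        while len(edges) < config.edges_per_species and attempts < 50 * config.edges_per_species:
            attempts += 1
            i, j = sample_family_pair()
            if (i, j) in seen_pairs:
                continue
            seen_pairs.add((i, j))
            itype = itype_values[rng.choice(3, p=itype_p)]
            db = dbs[int(rng.integers(3))]
            n_pub = 1 + int(rng.poisson(1.0))
            if is_conserved(i, j) and rng.random() < s_gen:
                n_pub += 1 + int(rng.poisson(2.0))
            pubs = frozenset(f"pm{sp}{i}x{j}n{t}" for t in range(n_pub))
            net.add(
                Interaction(gene(sp, i), gene(sp, j), itype, db, pubs)
            )
            edges.append((i, j, itype, db))
        source_edges[sp] = edges
        networks[sp] = net

    # --- gold target network ----------------------------------------------
    gold = InteractionNetwork(target)
    transferable: dict[tuple[str, str], tuple[int, int]] = {}
    truth: dict[tuple[str, str], bool] = {}
    for sp in sources:
        for i, j, itype, _db in source_edges[sp]:
            targets_i = sorted(
                {
                    r.gene_for(target)
                    for r in mapping.orthologs_of(gene(sp, i), target)
                },
                key=lambda p: p.id,
            )
            targets_j = sorted(
                {
                    r.gene_for(target)
                    for r in mapping.orthologs_of(gene(sp, j), target)
                },
                key=lambda p: p.id,
            )
            for ta in targets_i:
                for tb in targets_j:
                    if ta.id == tb.id:
                        continue
                    pair = (ta.id, tb.id) if ta.id < tb.id else (tb.id, ta.id)
                    transferable.setdefault(pair, (i, j))
                    conserved = is_conserved(i, j)
                    truth[pair] = truth.get(pair, False) or conserved
                    if conserved and not gold.has_pair(ta, tb):
                        keep_type = rng.random() < 0.9
                        gtype = (
                            itype
                            if keep_type
                            else itype_values[int(rng.integers(3))]
                        )
                        gold.add(Interaction(ta, tb, gtype, "gold", frozenset()))

    # every target gene participates in the gold graph so that network
    # features are missing symmetrically across classes
    target_genes = sorted(
        {gene(target, k) for k in range(G)}
        | {p for p in paralogs_created if p.species == target},
        key=lambda p: p.id,
    )
    for p in target_genes:
        gold.add_protein(p)

    # rewired hard negatives: a non-conserved source edge appears in gold
    # with one endpoint swapped to a random other family
    if config.rewire_rate > 0:
        for pair, (i, j) in sorted(transferable.items()):
            if truth[pair] or rng.random() >= config.rewire_rate:
                continue
            k = int(rng.integers(G))
            if k in (i, j):
                continue
            ta, tb = gene(target, i), gene(target, k)
            rp = (ta.id, tb.id) if ta.id < tb.id else (tb.id, ta.id)
            if rp in transferable or ta.id == tb.id:
                continue
            if not gold.has_pair(ta, tb):
                gold.add(
                    Interaction(ta, tb, itype_values[int(rng.integers(3))],
                                "gold", frozenset())
                )

    # background edges keep every target protein connected
    n_background = int(config.background_edges_per_gene * len(target_genes))
    added = 0
    attempts = 0
    while added < n_background and attempts < 50 * n_background:
        attempts += 1
        ia, ib = rng.choice(len(target_genes), size=2, replace=False)
        ta, tb = target_genes[int(ia)], target_genes[int(ib)]
        pair = (ta.id, tb.id) if ta.id < tb.id else (tb.id, ta.id)
        if pair in transferable or gold.has_pair(ta, tb):
            continue
        gold.add(
            Interaction(ta, tb, itype_values[int(rng.integers(3))],
                        "goldbg", frozenset())
        )
        added += 1
    networks[target] = gold

    # --- annotations -------------------------------------------------------
    ann = AnnotationStore()
    all_genes = sorted(
        {gene(sp, k) for sp in species for k in range(G)} | paralogs_created,
        key=lambda p: (p.species, p.id),
    )
    fam_of_gene = {p: int(p.id[len(p.species) + 1 : len(p.species) + 5]) for p in all_genes}

    b_leaves = [f"B:mod{m}" for m in range(n_modules)]
    c_leaves = [f"C:comp{j}" for j in range(6)]
    m_leaves = [f"M:fam{k}" for k in range(G)]

    for p in all_genes:
        fam = fam_of_gene[p]
        q = quality[fam]
        module = module_of(fam)
        fidelity = 0.3 + 0.65 * s_go * q
        terms: set[str] = set()
        if rng.random() < config.annotation_coverage:
            terms.add(
                f"B:mod{module}"
                if rng.random() < fidelity
                else b_leaves[int(rng.integers(n_modules))]
            )
        if rng.random() < config.annotation_coverage:
            terms.add(
                f"C:comp{module % 6}"
                if rng.random() < fidelity
                else c_leaves[int(rng.integers(6))]
            )
        if rng.random() < config.annotation_coverage:
            terms.add(
                f"M:fam{fam}"
                if rng.random() < fidelity
                else m_leaves[int(rng.integers(G))]
            )
        if terms:
            ann.go_terms[p] = terms

        keep = 0.3 + 0.6 * s_orth * q
        if rng.random() < config.annotation_coverage:
            toks = {f"fam{fam}tok{t}" for t in range(3) if rng.random() < keep}
            toks.add(f"noise{int(rng.integers(G * 2))}")
            ann.tokens[p] = toks
            doms = {f"ipr{fam:04d}"} if rng.random() < keep else set()
            if rng.random() < 0.5:
                doms.add(f"pf{module:03d}")
            if doms:
                ann.domains[p] = doms
            if rng.random() < 0.4 + 0.5 * s_orth * q:
                ann.pathways[p] = {f"path{module}"}

    # expression for the target species: module-level latent profiles
    n_cond = config.expression_conditions
    profiles = rng.normal(size=(n_modules, n_cond))
    for p in target_genes:
        if rng.random() >= config.annotation_coverage:
            continue
        fam = fam_of_gene[p]
        w = s_expr * (0.3 + 0.7 * quality[fam])
        noise = rng.normal(size=n_cond)
        vec = w * profiles[module_of(fam)] + math.sqrt(max(1 - w * w, 0.0)) * noise
        ann.expression[p] = tuple(float(v) for v in vec)

    ann.validate_against(dag)
    return World(
        config=config,
        target_species=target,
        source_species=sources,
        networks=networks,
        mapping=mapping,
        dag=dag,
        ann=ann,
        tree=tree,
        truth=truth,
    )


def world_fixtures() -> dict[str, WorldConfig]:
    """Named deterministic world configurations.

    ``tiny`` is hand-checkable (one source species, full ortholog coverage,
    1:1 clusters); ``signal`` plants strong feature signal for classifier
    tests; ``noise`` has zero feature signal for null tests.
    """
    return {
        "tiny": WorldConfig(
            n_species=2,
            genes_per_species=10,
            edges_per_species=8,
            ortholog_coverage=1.0,
            cluster_size_probs={"1:1": 1.0},
            conservation_rate=0.5,
            rewire_rate=0.0,
            feature_signal=0.0,
            module_size=5,
            background_edges_per_gene=1.0,
            seed=42,
        ),
        "signal": WorldConfig(
            n_species=4,
            genes_per_species=150,
            edges_per_species=900,
            ortholog_coverage=0.75,
            cluster_size_probs={"1:1": 0.8, "1:2": 0.15, "2:2": 0.05},
            conservation_rate=0.3,
            rewire_rate=0.3,
            feature_signal={
                "network": 0.9,
                "go": 0.9,
                "ortholog": 0.35,
                "expression": 0.6,
                "general": 0.15,
            },
            seed=7,
        ),
        "noise": WorldConfig(
            n_species=2,
            genes_per_species=400,
            edges_per_species=2500,
            ortholog_coverage=0.9,
            cluster_size_probs={"1:1": 1.0},
            conservation_rate=0.25,
            rewire_rate=0.0,
            feature_signal=0.0,
            module_size=10,
            within_module_edge_prob=0.5,
            multi_db_rate=0.0,
            seed=11,
        ),
    }


def _write_obo(dag: GoDag, fh) -> None:
    ns = {
        GoCategory.B: "biological_process",
        GoCategory.C: "cellular_component",
        GoCategory.M: "molecular_function",
    }
    fh.write("format-version: 1.2\n")
    for term in sorted(dag.terms):
        fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
        fh.write(f"namespace: {ns[dag.category[term]]}\n")
        for p in sorted(dag.parents[term]):
            fh.write(f"is_a: {p} ! {p}\n")


def write_world(world: World, outdir: str | Path) -> None:
    """Write a world as the standard file set (TSV / OBO / Newick)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp, net in world.networks.items():
        with open(outdir / f"interactions_{sp}.tsv", "w") as fh:
            write_interaction_table(net, fh)
    with open(outdir / "orthologs.tsv", "w") as fh:
        write_ortholog_table(world.mapping, fh)
    with open(outdir / "ontology.obo", "w") as fh:
        _write_obo(world.dag, fh)
    with open(outdir / "tree.nwk", "w") as fh:
        write_newick(world.tree, fh)
    species = world.source_species + [world.target_species]
    for sp in species:
        with open(outdir / f"annotations_{sp}.tsv", "w") as fh:
            write_annotation_table(world.ann, sp, fh)
    with open(outdir / f"expression_{world.target_species}.tsv", "w") as fh:
        write_expression_table(world.ann, world.target_species, fh)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("t_a\tt_b\tconserved\n")
        for (a, b), v in sorted(world.truth.items()):
            fh.write(f"{a}\t{b}\t{int(v)}\n")
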