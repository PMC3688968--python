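import numpy as np
import pytest

from interolog import pipeline
from interolog.features import (
    FEATURE_SETS,
    build_feature_matrix,
    domain_similarity,
    expression_correlation,
    feature_schema,
    harmonic_sequence_similarity,
    intermediate_species,
    network_go_similarity,
    network_overlap,
    ortholog_score,
    ortholog_support,
    pathway_score,
    phylo_distance,
    prepare_tokens,
    token_similarity,
    transitive_ortholog,
)
from interolog.go_semantics import build_ic_table
from interolog.iodata import (
    AnnotationStore,
    GoCategory,
    Interaction,
    InteractionNetwork,
    InteractionType,
    OrthologMapping,
    Protein,
    parse_newick,
)

import oracles
from conftest import (
    make_ortholog_pair,
    p,
    random_annotations,
    random_single_category_dag,
)


class TestNetworkOverlap:
    def test_partial_overlap(self, toy_net):
        # N(a)\{b} = {x,y,z}, N(b)\{a} = {y,z,w} -> 2/4
        assert network_overlap(toy_net, p("a"), p("b")) == pytest.approx(0.5)

    def test_identical_neighborhoods(self):
        net = InteractionNetwork("S")
        for u in ("a", "b"):
            for v in ("x", "y"):
                net.add(Interaction(p(u), p(v), InteractionType.physical, "D"))
        assert network_overlap(net, p("a"), p("b")) == 1.0

    def test_both_isolated_is_missing(self):
        net = InteractionNetwork("S")
        net.add(Interaction(p("a"), p("b"), InteractionType.physical, "D"))
        # only the mutual edge exists; after removing each other both empty
        assert network_overlap(net, p("a"), p("b")) is None

    def test_absent_protein_is_missing(self, toy_net):
        assert network_overlap(toy_net, p("nope"), p("a")) is None


class TestNetworkGoSimilarity:
    def test_single_neighbor_each_side_equals_protein_sim(self, toy_dag, toy_ann):
        table = build_ic_table(toy_dag, toy_ann, "global")
        net = InteractionNetwork("S")
        net.add(Interaction(p("a"), p("p1"), InteractionType.physical, "D"))
        net.add(Interaction(p("b"), p("p2"), InteractionType.physical, "D"))
        got = network_go_similarity(net, p("a"), p("b"), table, toy_dag, toy_ann)
        want = oracles.protein_similarity_bruteforce(
            {**toy_dag.parents}, table.counts, table.total,
            toy_ann.go_terms[p("p1")], toy_ann.go_terms[p("p2")],
        )
        assert got == pytest.approx(want)

    def test_empty_neighborhood_is_missing(self, toy_dag, toy_ann):
        net = InteractionNetwork("S")
        net.add(Interaction(p("a"), p("b"), InteractionType.physical, "D"))
        table = build_ic_table(toy_dag, toy_ann, "global")
        assert (
            network_go_similarity(net, p("a"), p("b"), table, toy_dag, toy_ann)
            is None
        )

    def test_randomized_against_neighbor_pair_oracle(self):
        rng = np.random.default_rng(47)
        checked = 0
        while checked < 100:
            dag = random_single_category_dag(rng, int(rng.integers(4, 10)))
            ann = random_annotations(rng, dag, 8)
            table = build_ic_table(dag, ann, GoCategory.B)
            net = InteractionNetwork("S")
            names = [f"q{i}" for i in range(8)] + ["a", "b"]
            for _ in range(12):
                u, v = rng.choice(len(names), 2, replace=False)
                if names[int(u)] != names[int(v)]:
                    net.add(
                        Interaction(
                            p(names[int(u)]), p(names[int(v)]),
                            InteractionType.physical, "D",
                        )
                    )
            if p("a") not in net or p("b") not in net:
                continue
            got = network_go_similarity(net, p("a"), p("b"), table, dag, ann)
            na = sorted(net.neighbors(p("a")) - {"b"})
            nb = sorted(net.neighbors(p("b")) - {"a"})
            want = oracles.mean_neighbor_similarity_bruteforce(
                dag.parents, table.counts, table.total,
                {q.id: t for q, t in ann.go_terms.items()}, na, nb,
            )
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-10)
            checked += 1


class TestPairwiseSimilarities:
    def test_harmonic_mean_closed_form(self):
        assert harmonic_sequence_similarity(0.8, 0.4) == pytest.approx(8 / 15)
        assert harmonic_sequence_similarity(0.7, 0.7) == pytest.approx(0.7)
        assert harmonic_sequence_similarity(0.5, 0.0) == 0.0
        assert harmonic_sequence_similarity(None, 0.5) is None

    def test_token_jaccard(self):
        ann = AnnotationStore()
        ann.tokens = {
            p("a"): {"kinas", "serin"},
            p("b"): {"kinas", "threonin"},
            p("c"): set(),
        }
        assert token_similarity(ann, p("a"), p("b")) == pytest.approx(1 / 3)
        assert token_similarity(ann, p("a"), p("a")) == 1.0
        assert token_similarity(ann, p("a"), p("c")) is None

    def test_domain_jaccard(self):
        ann = AnnotationStore()
        ann.domains = {
            p("a"): {"IPR001", "PF01"},
            p("b"): {"IPR001"},
            p("c"): {"PF99"},
        }
        assert domain_similarity(ann, p("a"), p("b")) == 0.5
        assert domain_similarity(ann, p("b"), p("c")) == 0.0
        assert domain_similarity(ann, p("a"), p("nope")) is None

    def test_pathway_boolean(self):
        ann = AnnotationStore()
        ann.pathways = {p("a"): {"k1"}, p("b"): {"k1", "k2"}, p("c"): {"k3"}}
        assert pathway_score(ann, p("a"), p("b")) == 1.0
        assert pathway_score(ann, p("a"), p("c")) == 0.0
        assert pathway_score(ann, p("a"), p("nope")) is None

    def test_expression_correlation(self):
        ann = AnnotationStore()
        x = (1.0, 2.0, 3.0, 4.0)
        ann.expression = {
            p("a"): x,
            p("b"): tuple(2 * v + 1 for v in x),
            p("c"): tuple(-v for v in x),
            p("d"): (5.0, 5.0, 5.0, 5.0),
        }
        assert expression_correlation(ann, p("a"), p("b")) == pytest.approx(1.0)
        assert expression_correlation(ann, p("a"), p("c")) == pytest.approx(-1.0)
        assert expression_correlation(ann, p("a"), p("d")) is None
        assert expression_correlation(ann, p("a"), p("nope")) is None


class TestOrthologScores:
    def test_score_combination(self):
        assert ortholog_score(make_ortholog_pair("g", "h")) == 1.0
        pair = make_ortholog_pair(
            "g", "h", bootstrap_source=0.5, bootstrap_target=1.0
        )
        assert ortholog_score(pair) == pytest.approx(0.75)
        assert ortholog_score(
            make_ortholog_pair("g", "h", bootstrap_source=None)
        ) is None

    def test_support_counts_databases(self):
        mapping = OrthologMapping(
            [
                make_ortholog_pair("g", "h", db="db1"),
                make_ortholog_pair("g", "h", db="db2"),
                make_ortholog_pair("g", "h", db="db3"),
                make_ortholog_pair("g2", "h2", db="db1"),
            ]
        )
        assert ortholog_support(mapping, Protein("g", "A"), Protein("h", "B")) == 3
        assert ortholog_support(mapping, Protein("g2", "A"), Protein("h2", "B")) == 1
        with pytest.raises(KeyError):
            ortholog_support(mapping, Protein("x", "A"), Protein("y", "B"))


class TestPhyloDistance:
    def test_same_species_zero(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        assert phylo_distance(tree, "A", "A") == 0.0

    def test_sibling_branch_lengths(self):
        tree = parse_newick("((A:1,B:1),C:2);")
        assert phylo_distance(tree, "A", "B") == 2.0

    def test_edge_count_without_lengths(self):
        tree = parse_newick("((A,B),(C,D));")
        assert phylo_distance(tree, "A", "D") == 4.0

    def test_non_leaf_raises(self):
        tree = parse_newick("((A,B)inner,C);")
        with pytest.raises(KeyError):
            phylo_distance(tree, "inner", "C")


class TestTransitiveOrtholog:
    def setup_chain(self, relations):
        mapping = OrthologMapping()
        for src, sp_s, tgt, sp_t in relations:
            mapping.add(make_ortholog_pair(src, tgt, sp_src=sp_s, sp_tgt=sp_t))
        return mapping

    def test_intermediate_species_balanced_tree(self):
        tree = parse_newick("((A,B),(C,D));")
        assert intermediate_species(tree, "A", "D") == ["B", "C"]

    def test_chain_found(self):
        tree = parse_newick("((A,B),(C,D));")
        mapping = self.setup_chain(
            [("a", "A", "b", "B"), ("b", "B", "c", "C"),
             ("c", "C", "d", "D"), ("a", "A", "d", "D")]
        )
        assert transitive_ortholog(
            tree, mapping, "A", "D", Protein("a", "A"), Protein("d", "D")
        )

    def test_chain_reaching_wrong_gene_fails(self):
        tree = parse_newick("((A,B),(C,D));")
        mapping = self.setup_chain(
            [("a", "A", "b", "B"), ("b", "B", "c", "C"),
             ("c", "C", "dx", "D"), ("a", "A", "d", "D")]
        )
        assert not transitive_ortholog(
            tree, mapping, "A", "D", Protein("a", "A"), Protein("d", "D")
        )

    def test_adjacent_species_need_only_direct_record(self):
        tree = parse_newick("(A,B);")
        mapping = self.setup_chain([("a", "A", "b", "B")])
        assert transitive_ortholog(
            tree, mapping, "A", "B", Protein("a", "A"), Protein("b", "B")
        )

    def test_broken_hop_yields_false(self):
        tree = parse_newick("((A,B),(C,D));")
        # no B->C records at all: the hop cannot be skipped
        mapping = self.setup_chain(
            [("a", "A", "b", "B"), ("c", "C", "d", "D"), ("a", "A", "d", "D")]
        )
        assert not transitive_ortholog(
            tree, mapping, "A", "D", Protein("a", "A"), Protein("d", "D")
        )

    def test_randomized_against_chain_enumeration(self):
        rng = np.random.default_rng(59)
        checked = 0
        while checked < 100:
            species = ["A", "B", "C", "D", "E"][: int(rng.integers(3, 6))]
            newick = species[0]
            for s in species[1:]:
                newick = f"({newick},{s})"
            tree = parse_newick(newick + ";")
            genes = {sp: [Protein(f"{sp.lower()}{i}", sp) for i in range(3)]
                     for sp in species}
            mapping = OrthologMapping()
            relations = set()
            for i, sa in enumerate(species):
                for sb in species[i + 1:]:
                    for ga in genes[sa]:
                        for gb in genes[sb]:
                            if rng.random() < 0.3:
                                mapping.add(
                                    make_ortholog_pair(
                                        ga.id, gb.id, sp_src=sa, sp_tgt=sb
                                    )
                                )
                                relations.add(frozenset((ga, gb)))
            src, tgt = species[0], species[-1]
            g_src, g_tgt = genes[src][0], genes[tgt][0]
            if not mapping.has_relation(g_src, g_tgt):
                mapping.add(
                    make_ortholog_pair(g_src.id, g_tgt.id, sp_src=src, sp_tgt=tgt)
                )
                relations.add(frozenset((g_src, g_tgt)))
            got = transitive_ortholog(tree, mapping, src, tgt, g_src, g_tgt)
            chain_species = intermediate_species(tree, src, tgt)
            want = oracles.transitive_chain_bruteforce(
                relations, genes, chain_species, g_src, g_tgt
            )
            assert got == want
            checked += 1


class TestSchema:
    def test_full_set_cell_count(self):
        # 20 feature types across S/T/O pairings, O expanded to O1/O2
        assert len(feature_schema("full")) == 43

    def test_reduced_drops_network_and_expression(self):
        full = set(feature_schema("full"))
        reduced = set(feature_schema("reduced"))
        dropped = full - reduced
        assert dropped == {
            "network_overlap (S)", "network_overlap (T)",
            "go_network (S)", "go_network (T)", "expression_corr (T)",
        }

    def test_category_sets_are_subsets_of_full(self):
        full = set(feature_schema("full"))
        for name in ("network", "go", "general", "ortholog", "reduced"):
            assert set(feature_schema(name)) <= full

    def test_category_sets_partition_full(self):
        union = set()
        for name in ("network", "go", "general", "ortholog"):
            cells = set(feature_schema(name))
            assert not (union & cells)
            union |= cells
        assert union == set(feature_schema("full"))

    def test_unknown_set_raises(self):
        with pytest.raises(KeyError, match="unknown feature set"):
            feature_schema("everything")


class TestFeatureMatrix:
    def test_production_mode_target_features_missing(self, tiny_world):
        ctx = pipeline.build_context(tiny_world)
        ctx.target_net = None
        labeled, _ = pipeline.transfer_world(tiny_world)
        df = build_feature_matrix(labeled, ctx, "full")
        assert df["network_overlap (T)"].isna().all()
        assert df["go_network (T)"].isna().all()
        # the vector is still valid: ortholog features remain computable
        assert df["phylo_distance (O1)"].notna().all()

    def test_total_support_counts_other_species(self, signal_data):
        df = signal_data["df"]
        labeled = signal_data["labeled"]
        counts = {}
        for tr in labeled:
            counts.setdefault(tr.target_pair, set()).add(tr.source_species)
        expected = [len(counts[tr.target_pair]) - 1 for tr in labeled]
        assert df["total_support (T)"].tolist() == expected

    def test_edge_support_is_pubmed_count(self, tiny_world):
        labeled, _ = pipeline.transfer_world(tiny_world)
        ctx = pipeline.build_context(tiny_world)
        df = build_feature_matrix(labeled, ctx, "general")
        expected = [len(tr.source.pubmed_ids) for tr in labeled]
        assert df["edge_support (S)"].tolist() == expected

    def test_similarity_features_symmetric_in_instance(self, toy_dag, toy_ann):
        table = build_ic_table(toy_dag, toy_ann, "global")
        net = InteractionNetwork("S")
        net.add(Interaction(p("a"), p("p1"), InteractionType.physical, "D"))
        net.add(Interaction(p("b"), p("p2"), InteractionType.physical, "D"))
        ab = network_go_similarity(net, p("a"), p("b"), table, toy_dag, toy_ann)
        ba = network_go_similarity(net, p("b"), p("a"), table, toy_dag, toy_ann)
        assert ab == ba
        assert network_overlap(net, p("a"), p("b")) == network_overlap(
            net, p("b"), p("a")
        )


class TestPrepareTokens:
    def test_pipeline_lowercases_stems_and_filters(self):
        descriptions = {
            p("a"): "Serine/threonine-protein KINASE",
            p("b"): "Threonine kinases of the membrane",
        }
        tokens = prepare_tokens(descriptions, general_threshold=1.0)
        assert "kinas" in tokens[p("a")] and "kinas" in tokens[p("b")]
        assert "the" not in tokens[p("b")]
        assert all(t == t.lower() for ts in tokens.values() for t in ts)

    def test_general_words_removed_by_document_frequency(self):
        descriptions = {p(f"x{i}"): "ubiquitous widget" for i in range(10)}
        descriptions[p("y")] = "rare descriptor widget"
        tokens = prepare_tokens(descriptions, general_threshold=0.5)
        assert all("widget" not in ts for ts in tokens.values())
        assert "descriptor" in tokens[p("y")]
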