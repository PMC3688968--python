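from __future__ import annotations

import numpy as np
import pytest

from interolog import pipeline, synthetic
from interolog.iodata import (
    AnnotationStore,
    GoCategory,
    GoDag,
    Interaction,
    InteractionNetwork,
    InteractionType,
    OrthologMapping,
    OrthologPair,
    Protein,
)


def p(pid: str, sp: str = "S") -> Protein:
    return Protein(pid, sp)


@pytest.fixture
def toy_dag() -> GoDag:
    """Small biological-process hierarchy with a diamond under b_mid:

        root <- mid1 <- leaf1
        root <- mid2 <- leaf1  (diamond)
        root <- mid2 <- leaf2
    plus a molecular-function root with one leaf.
    """
    parents = {
        "root": set(),
        "mid1": {"root"},
        "mid2": {"root"},
        "leaf1": {"mid1", "mid2"},
        "leaf2": {"mid2"},
        "mroot": set(),
        "mleaf": {"mroot"},
    }
    category = {
        t: GoCategory.B for t in ("root", "mid1", "mid2", "leaf1", "leaf2")
    }
    category.update({"mroot": GoCategory.M, "mleaf": GoCategory.M})
    return GoDag(parents, category)


@pytest.fixture
def toy_ann(toy_dag) -> AnnotationStore:
    ann = AnnotationStore()
    ann.go_terms = {
        p("p1"): {"leaf1"},
        p("p2"): {"leaf2"},
        p("p3"): {"mid1"},
        p("p4"): {"leaf1", "leaf2"},
        p("p5"): {"root"},
        p("p6"): {"mleaf"},
    }
    ann.validate_against(toy_dag)
    return ann


@pytest.fixture
def toy_net() -> InteractionNetwork:
    net = InteractionNetwork("S")
    edges = [("a", "x"), ("a", "y"), ("a", "z"), ("b", "y"), ("b", "z"),
             ("b", "w"), ("a", "b")]
    for u, v in edges:
        net.add(Interaction(p(u), p(v), InteractionType.physical, "DB"))
    return net


@pytest.fixture(scope="session")
def fixture_configs():
    return synthetic.world_fixtures()


@pytest.fixture(scope="session")
def tiny_world(fixture_configs):
    return synthetic.generate(fixture_configs["tiny"])


@pytest.fixture(scope="session")
def signal_world(fixture_configs):
    return synthetic.generate(fixture_configs["signal"])


@pytest.fixture(scope="session")
def noise_world(fixture_configs):
    return synthetic.generate(fixture_configs["noise"])


@pytest.fixture(scope="session")
def signal_data(signal_world):
    """Featurized signal world: context, labeled instances, labels and the
    full-set feature matrix (computed once per session)."""
    ctx = pipeline.build_context(signal_world)
    df, labels, labeled = pipeline.featurize_world(signal_world, "full", ctx=ctx)
    return {"ctx": ctx, "df": df, "labels": labels, "labeled": labeled}


@pytest.fixture(scope="session")
def signal_cv(signal_world, signal_data):
    """Cross-validated filter performance on the signal world for the three
    headline feature sets, plus the two single-feature baseline filters."""
    from interolog import evaluation, features as feat, rff

    labels = signal_data["labels"]
    labeled = signal_data["labeled"]
    ctx = signal_data["ctx"]
    denom = int(labels.sum())
    out = {}
    for set_name in ("full", "reduced", "general"):
        df = (
            signal_data["df"]
            if set_name == "full"
            else feat.build_feature_matrix(labeled, ctx, set_name)
        )
        cv = rff.cross_validate(df, labels, folds=10, seed=1)
        out[set_name] = {"auprc": cv.auprc, "auroc": cv.auroc}
    full_df = signal_data["df"]
    out["baseline_harmonic_seq"] = evaluation.curve(
        rff.baseline_harmonic_seq_scores(full_df), labels, denom
    ).auprc
    out["baseline_ortholog_score"] = evaluation.curve(
        rff.baseline_ortholog_scores(full_df), labels, denom
    ).auprc
    return out


def random_single_category_dag(rng: np.random.Generator, n_terms: int) -> GoDag:
    """Random rooted DAG in one category: term i gets 1-2 parents among
    earlier terms."""
    parents: dict[str, set[str]] = {"t0": set()}
    category = {"t0": GoCategory.B}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i + 1)))
        ps = rng.choice(i, size=k, replace=False)
        parents[f"t{i}"] = {f"t{int(j)}" for j in ps}
        category[f"t{i}"] = GoCategory.B
    return GoDag(parents, category)


def random_annotations(
    rng: np.random.Generator, dag: GoDag, n_proteins: int
) -> AnnotationStore:
    ann = AnnotationStore()
    terms = sorted(dag.terms)
    for i in range(n_proteins):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(terms), size=k, replace=False)
        ann.go_terms[p(f"q{i}")] = {terms[int(j)] for j in chosen}
    return ann


def make_ortholog_pair(
    src: str, tgt: str, sp_src: str = "A", sp_tgt: str = "B",
    db: str = "db1", **scores
) -> OrthologPair:
    defaults = dict(
        inparalog_source=1.0, inparalog_target=1.0,
        bootstrap_source=1.0, bootstrap_target=1.0, seq_identity=0.5,
    )
    defaults.update(scores)
    return OrthologPair(
        g_source=Protein(src, sp_src), g_target=Protein(tgt, sp_tgt),
        source_db=db, **defaults,
    )
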