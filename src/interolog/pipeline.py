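"""Convenience wiring: run the transfer/featurize pipeline on in-memory
worlds (as produced by the synthetic module or assembled from parsed
inputs)."""

from __future__ import annotations

import numpy as np

from . import features as feat
from . import go_semantics as gosem
from .synthetic import World
from .transfer import Label, Setting, direct_transfer, label_against_gold

__all__ = ["transfer_world", "build_context", "featurize_world"]


def transfer_world(world: World, setting: Setting = Setting.AllI):
    """Direct-transfer every source network of a world onto its target and
    label against the gold network.  Returns (instances, labels)."""
    transfers = []
    for sp in world.source_species:
        transfers.extend(
            direct_transfer(world.networks[sp], world.mapping, world.target_species)
        )
    labeled = label_against_gold(transfers, world.gold, setting)
    labels = np.array([t.label is Label.consistent for t in labeled])
    return labeled, labels


def build_context(world: World) -> feat.FeatureContext:
    ic_tables = {
        "global": gosem.build_ic_table(world.dag, world.ann, "global"),
        "B": gosem.build_ic_table(world.dag, world.ann, gosem.GoCategory.B),
        "C": gosem.build_ic_table(world.dag, world.ann, gosem.GoCategory.C),
        "M": gosem.build_ic_table(world.dag, world.ann, gosem.GoCategory.M),
    }
    return feat.FeatureContext(
        source_nets={s: world.networks[s] for s in world.source_species},
        mapping=world.mapping,
        dag=world.dag,
        ic_tables=ic_tables,
        ann=world.ann,
        tree=world.tree,
        target_net=world.gold,
    )


def featurize_world(
    world: World,
    set_name: str = "full",
    setting: Setting = Setting.AllI,
    ctx: feat.FeatureContext | None = None,
):
    """Transfer + label + featurize a world.

    Returns (feature DataFrame, boolean labels, labeled instances).
    """
    labeled, labels = transfer_world(world, setting)
    ctx = ctx or build_context(world)
    df = feat.build_feature_matrix(labeled, ctx, set_name)
    return df, labels, labeled
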