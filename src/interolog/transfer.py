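"""Direct interolog transfer and gold-standard labeling.

A source interaction (s1, s2) is projected onto a target species through
every combination of ortholog records s1 -> t1 and s2 -> t2, giving one
transfer *instance* per combination.  The same target pair can therefore be
reached several times with different provenance; per-pair aggregation
happens only when a final network is materialised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

from .iodata import (
    Interaction,
    InteractionNetwork,
    InteractionType,
    OrthologMapping,
    OrthologPair,
    Protein,
)

__all__ = [
    "Label",
    "Setting",
    "TransferredInteraction",
    "direct_transfer",
    "label_against_gold",
    "dedupe_network",
    "setting_for_source_type",
]

logger = logging.getLogger(__name__)


class Label(str, Enum):
    consistent = "consistent"
    inconsistent = "inconsistent"
    unlabeled = "unlabeled"


class Setting(str, Enum):
    """Evaluation settings.

    AllI checks only the occurrence of a transferred pair in the gold
    network; PhyI restricts to physical source interactions and additionally
    requires the gold edge to be physical; GenI likewise for genetic.
    """

    AllI = "AllI"
    PhyI = "PhyI"
    GenI = "GenI"


def setting_for_source_type(itype: InteractionType) -> Setting:
    """Which per-setting filter scores an instance in production: physical
    source edges go to the PhyI model, genetic to GenI, everything else
    (unknown/ambiguous types) to the AllI model."""
    if itype is InteractionType.physical:
        return Setting.PhyI
    if itype is InteractionType.genetic:
        return Setting.GenI
    return Setting.AllI


@dataclass(frozen=True)
class TransferredInteraction:
    """One transfer instance with full provenance.

    t_a / t_b are the target-species proteins in canonical order; ortho_a
    and ortho_b are the ortholog records used for source.a and source.b
    respectively (tracked through canonicalization).
    """

    t_a: Protein
    t_b: Protein
    source: Interaction
    ortho_a: OrthologPair
    ortho_b: OrthologPair
    label: Label = Label.unlabeled
    score: float | None = None

    def __post_init__(self) -> None:
        if self.t_a.id == self.t_b.id:
            raise ValueError("transferred self-pair not allowed")
        if self.t_a.id > self.t_b.id:
            ta, tb = self.t_a, self.t_b
            oa, ob = self.ortho_a, self.ortho_b
            object.__setattr__(self, "t_a", tb)
            object.__setattr__(self, "t_b", ta)
            object.__setattr__(self, "ortho_a", ob)
            object.__setattr__(self, "ortho_b", oa)

    @property
    def target_pair(self) -> tuple[str, str]:
        return (self.t_a.id, self.t_b.id)

    @property
    def source_species(self) -> str:
        return self.source.a.species

    @property
    def target_species(self) -> str:
        return self.t_a.species


def direct_transfer(
    source_net: InteractionNetwork,
    mapping: OrthologMapping,
    target_species: str,
) -> list[TransferredInteraction]:
    """Project every source edge onto the target species via orthologs.

    Emits one instance per (source edge, ortholog record for each endpoint)
    combination; combinations that collapse onto a single target protein are
    dropped.  Several ortholog databases listing the same gene pair yield
    one instance per record — downstream ortholog-support features absorb
    the multiplicity.
    """
    if frozenset((source_net.species, target_species)) not in mapping.species_pairs:
        logger.warning(
            "no ortholog mapping between %s and %s; empty transfer",
            source_net.species,
            target_species,
        )
        return []
    out: list[TransferredInteraction] = []
    seen: set[tuple] = set()
    for edge in sorted(
        source_net.interactions, key=lambda e: (e.pair, e.itype.value, e.source_db)
    ):
        orths_a = mapping.orthologs_of(edge.a, target_species)
        orths_b = mapping.orthologs_of(edge.b, target_species)
        for oa in orths_a:
            t1 = oa.gene_for(target_species)
            for ob in orths_b:
                t2 = ob.gene_for(target_species)
                if t1.id == t2.id:
                    continue
                key = (t1.id, t2.id, edge, oa, ob)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    TransferredInteraction(
                        t_a=t1, t_b=t2, source=edge, ortho_a=oa, ortho_b=ob
                    )
                )
    return out


def label_against_gold(
    transfers: list[TransferredInteraction],
    gold: InteractionNetwork,
    setting: Setting,
) -> list[TransferredInteraction]:
    """Label transfer instances against the target gold-standard network.

    AllI keeps every instance and labels it consistent iff the target pair
    occurs in the gold network with any type.  PhyI (GenI) first restricts
    the instance set to physical (genetic) source interactions and requires
    the gold edge type to agree.
    """
    if transfers and gold.species != transfers[0].target_species:
        raise ValueError(
            f"gold network species {gold.species!r} does not match transfers"
        )
    wanted_type = {
        Setting.PhyI: InteractionType.physical,
        Setting.GenI: InteractionType.genetic,
    }.get(setting)
    out = []
    for tr in transfers:
        if wanted_type is not None and tr.source.itype is not wanted_type:
            continue
        if wanted_type is None:
            ok = gold.has_pair(tr.t_a, tr.t_b)
        else:
            ok = wanted_type in gold.types_for_pair(tr.t_a, tr.t_b)
        out.append(
            replace(tr, label=Label.consistent if ok else Label.inconsistent)
        )
    return out


def dedupe_network(
    transfers: list[TransferredInteraction],
) -> tuple[InteractionNetwork, dict[tuple[str, str], list[TransferredInteraction]]]:
    """Collapse transfer instances into one edge per canonical target pair.

    The retained per-pair score is the maximum over instances (best
    evidence); the full provenance list per pair is returned alongside the
    network.
    """
    provenance: dict[tuple[str, str], list[TransferredInteraction]] = {}
    for tr in transfers:
        provenance.setdefault(tr.target_pair, []).append(tr)
    species = transfers[0].target_species if transfers else "empty"
    net = InteractionNetwork(species)
    for pair, instances in provenance.items():
        best = max(
            (tr.score for tr in instances if tr.score is not None), default=None
        )
        first = instances[0]
        net.add(
            Interaction(
                first.t_a,
                first.t_b,
                first.source.itype,
                "transfer",
                frozenset(),
            )
        )
        if best is not None:
            # expose the aggregate score on the provenance index; the edge
            # set itself stays score-free
            provenance[pair] = sorted(
                instances, key=lambda t: -(t.score if t.score is not None else -1.0)
            )
    return net, provenance
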