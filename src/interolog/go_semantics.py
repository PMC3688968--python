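"""Resnik information content and semantic similarity over the GO DAG.

IC(t) = -ln p(t) with p(t) the fraction of annotated proteins carrying t or
any of its descendants.  Term similarity is the IC of the most informative
common ancestor (MICA); protein similarity is the maximum over all pairs of
their annotated terms.  A pooled "global" table places a virtual super-root
above the three category roots, so cross-category term pairs score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .iodata import AnnotationStore, GoCategory, GoDag, Protein

__all__ = ["IcTable", "build_ic_table", "term_similarity", "protein_go_similarity"]

GLOBAL_ROOT = "__global_root__"

Category = GoCategory | Literal["global"]


@dataclass
class IcTable:
    """Annotation counts and information content per term.

    counts(t) is the number of distinct proteins annotated with t or any
    descendant (set semantics: a protein counts once per ancestor even on
    diamond paths).  ic is defined only for terms with counts > 0 and is 0
    at the root.
    """

    category: str
    counts: dict[str, int]
    total: int
    ic: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.ic = {
            t: -math.log(c / self.total) for t, c in self.counts.items() if c > 0
        }

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def write_tsv(self, fh) -> None:
        fh.write("term\tcount\tic\n")
        for t in sorted(self.ic):
            fh.write(f"{t}\t{self.counts[t]}\t{self.ic[t]:.6f}\n")


def build_ic_table(
    dag: GoDag, annotations: AnnotationStore, category: Category
) -> IcTable:
    """Count annotated proteins per term (with upward propagation) and
    derive IC values.

    For a single category only that category's terms and annotations are
    used and the denominator is the count at the category root.  For
    ``"global"`` all three categories are pooled under a virtual super-root;
    the denominator is the total number of annotated proteins.
    """
    if category == "global":
        relevant = dag.terms
    else:
        relevant = {t for t in dag.terms if dag.category[t] is category}
    counts: dict[str, int] = {t: 0 for t in relevant}
    annotated_proteins = 0
    for protein, terms in annotations.go_terms.items():
        reached: set[str] = set()
        for t in terms:
            if t in relevant:
                reached.update(dag.ancestors(t))
        if not reached:
            continue
        annotated_proteins += 1
        for t in reached:
            counts[t] += 1
    if annotated_proteins == 0:
        name = category if isinstance(category, str) else category.value
        raise ValueError(f"no annotations for category {name}")
    if category == "global":
        counts[GLOBAL_ROOT] = annotated_proteins
        name = "global"
    else:
        name = category.value
    return IcTable(category=name, counts=counts, total=annotated_proteins)


def _ancestors_in_table(dag: GoDag, table: IcTable, term: str) -> set[str]:
    anc = {t for t in dag.ancestors(term) if t in table}
    if table.category == "global":
        anc.add(GLOBAL_ROOT)
    return anc


def term_similarity(ic: IcTable, dag: GoDag, t1: str, t2: str) -> float:
    """Resnik similarity of two terms: IC of their most informative common
    ancestor.  0 when the only shared ancestor is the (virtual) root."""
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"unknown term {t}")
        if t not in ic and t != GLOBAL_ROOT:
            raise ValueError(f"term {t} has no annotation count; IC undefined")
    common = _ancestors_in_table(dag, ic, t1) & _ancestors_in_table(dag, ic, t2)
    if not common:
        return 0.0
    return max(ic.ic.get(a, 0.0) for a in common)


def protein_go_similarity(
    ic: IcTable,
    dag: GoDag,
    ann: AnnotationStore,
    p1: Protein,
    p2: Protein,
) -> float | None:
    """Max Resnik similarity over all annotation pairs of the two proteins.

    Returns None (missing) if either protein carries no usable annotation
    for the table's category.
    """
    if ic.category == "global":
        terms1 = {t for t in ann.go_terms.get(p1, ()) if t in ic}
        terms2 = {t for t in ann.go_terms.get(p2, ()) if t in ic}
    else:
        cat = GoCategory(ic.category)
        terms1 = {t for t in ann.go_terms_in_category(p1, dag, cat) if t in ic}
        terms2 = {t for t in ann.go_terms_in_category(p2, dag, cat) if t in ic}
    if not terms1 or not terms2:
        return None
    return max(
        term_similarity(ic, dag, t1, t2) for t1 in terms1 for t2 in terms2
    )
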