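"""Independent brute-force oracles used to check the package's semantic
similarity, transitive-orthology and curve-area computations.

Everything here is written against plain dicts/lists and deliberately
avoids the package's own traversal and aggregation code paths.
"""

from __future__ import annotations

import itertools
import math


def ancestors_bruteforce(parents: dict[str, set[str]], term: str) -> set[str]:
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents[t]:
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def descendants_bruteforce(parents: dict[str, set[str]], term: str) -> set[str]:
    return {
        t for t in parents if term in ancestors_bruteforce(parents, t)
    }


def ic_counts_bruteforce(
    parents: dict[str, set[str]], annotations: dict[object, set[str]]
) -> dict[str, int]:
    """counts(t) = number of proteins annotated with t or any descendant."""
    counts = {}
    for t in parents:
        desc = descendants_bruteforce(parents, t)
        counts[t] = sum(1 for terms in annotations.values() if terms & desc)
    return counts


def term_similarity_bruteforce(
    parents: dict[str, set[str]],
    counts: dict[str, int],
    total: int,
    t1: str,
    t2: str,
) -> float:
    common = ancestors_bruteforce(parents, t1) & ancestors_bruteforce(parents, t2)
    common = {a for a in common if counts.get(a, 0) > 0}
    if not common:
        return 0.0
    return max(-math.log(counts[a] / total) for a in common)


def protein_similarity_bruteforce(
    parents, counts, total, terms1: set[str], terms2: set[str]
) -> float | None:
    terms1 = {t for t in terms1 if counts.get(t, 0) > 0}
    terms2 = {t for t in terms2 if counts.get(t, 0) > 0}
    if not terms1 or not terms2:
        return None
    return max(
        term_similarity_bruteforce(parents, counts, total, a, b)
        for a in terms1
        for b in terms2
    )


def mean_neighbor_similarity_bruteforce(
    parents, counts, total, annotations, neighbors_a, neighbors_b
) -> float | None:
    values = []
    for u in neighbors_a:
        for v in neighbors_b:
            s = protein_similarity_bruteforce(
                parents, counts, total,
                annotations.get(u, set()), annotations.get(v, set()),
            )
            if s is not None:
                values.append(s)
    if not neighbors_a or not neighbors_b or not values:
        return None
    return sum(values) / len(values)


def auroc_bruteforce(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def auprc_numerical(scores, labels, denominator: int, steps: int = 4000) -> float:
    """Davis–Goadrich area by fine numerical integration of the
    TP-interpolated precision over relative recall."""
    ranked = sorted(zip(scores, labels), key=lambda t: -t[0])
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(ranked):
        j = i
        while j < len(ranked) and ranked[j][0] == ranked[i][0]:
            if ranked[j][1]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((float(tp), float(fp)))
        i = j
    area = 0.0
    for (tpa, fpa), (tpb, fpb) in zip(points, points[1:]):
        dtp = tpb - tpa
        if dtp <= 0:
            continue
        slope = (fpb - fpa) / dtp
        for k in range(steps):
            t0 = tpa + dtp * k / steps
            t1 = tpa + dtp * (k + 1) / steps
            tm = (t0 + t1) / 2.0
            prec = tm / (tm + fpa + slope * (tm - tpa))
            area += prec * (t1 - t0) / denominator
    return area


def transitive_chain_bruteforce(
    relations: set[frozenset],
    genes_by_species: dict[str, list],
    chain_species: list[str],
    g_src,
    g_tgt,
) -> bool:
    """Exhaustive enumeration over all gene choices along the chain."""
    if not chain_species:
        return frozenset((g_src, g_tgt)) in relations
    for combo in itertools.product(
        *(genes_by_species[sp] for sp in chain_species)
    ):
        chain = [g_src, *combo, g_tgt]
        if all(
            frozenset((a, b)) in relations for a, b in zip(chain, chain[1:])
        ):
            return True
    return False
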