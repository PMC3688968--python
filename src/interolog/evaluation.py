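"""Precision / relative-recall evaluation, AUPRC, AUROC and
Information-Gain feature ranking.

Relative recall divides retained true positives by the number of consistent
instances under the *unfiltered* direct transfer, so it is 1.0 at threshold
0 by construction; regular recall (against the gold network size) is
reported when a gold size is supplied.  AUPRC uses Davis–Goadrich
non-linear interpolation between achievable precision/recall points, with
relative recall on the x axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CurvePoint",
    "EvaluationCurve",
    "curve",
    "auroc",
    "information_gain",
    "rank_features",
]

MISSING = "__missing__"


class CurvePoint(NamedTuple):
    threshold: float
    precision: float
    relative_recall: float
    recall: float | None
    fpr: float


@dataclass
class EvaluationCurve:
    points: list[CurvePoint]
    auprc: float
    auroc: float

    def write_tsv(self, fh) -> None:
        fh.write("threshold\tprecision\trelative_recall\trecall\tfpr\n")
        for p in self.points:
            rec = "NA" if p.recall is None else f"{p.recall:.6f}"
            fh.write(
                f"{p.threshold:.6f}\t{p.precision:.6f}\t"
                f"{p.relative_recall:.6f}\t{rec}\t{p.fpr:.6f}\n"
            )

    def summary_json(self) -> str:
        return json.dumps({"auprc": self.auprc, "auroc": self.auroc})


def _validate(scores: np.ndarray, labels: np.ndarray) -> None:
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must lie in [0, 1]")


def _threshold_counts(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct thresholds (decreasing) with cumulative TP and FP at >= t."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    last = np.r_[s[1:] != s[:-1], True]  # last index of each distinct score
    return s[last], tp[last], fp[last]


def curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    relative_denominator: int,
    gold_size: int | None = None,
) -> EvaluationCurve:
    """Precision / relative-recall / recall / FPR at every distinct score.

    *relative_denominator* is the number of consistent instances in the
    unfiltered direct transfer.  Thresholds retaining nothing are omitted
    (precision undefined there).
    """
    if relative_denominator <= 0:
        raise ValueError("relative_denominator must be positive")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _validate(scores, labels)
    n_neg = int((~labels).sum())
    thr, tp, fp = _threshold_counts(scores, labels)
    points = [
        CurvePoint(
            threshold=float(t),
            precision=tpi / (tpi + fpi),
            relative_recall=tpi / relative_denominator,
            recall=(tpi / gold_size) if gold_size else None,
            fpr=(fpi / n_neg) if n_neg else 0.0,
        )
        for t, tpi, fpi in zip(thr, tp.tolist(), fp.tolist())
    ]
    return EvaluationCurve(
        points=points,
        auprc=_auprc_davis_goadrich(tp, fp, relative_denominator),
        auroc=auroc(scores, labels),
    )


def _auprc_davis_goadrich(
    tp: np.ndarray, fp: np.ndarray, denominator: int
) -> float:
    """Area under the precision/(relative-)recall curve with Davis–Goadrich
    interpolation.

    Between consecutive achievable points, false positives are interpolated
    linearly in the true positives; precision along such a segment is
    t / ((1+s) t + k) with s the local FP/TP slope and k = FP_a - s TP_a,
    whose integral in t has the closed form t/a - (k/a^2) ln(a t + k).
    The curve starts at (TP, FP) = (0, 0), which extends the first point's
    precision down to recall 0.
    """
    if tp[-1] == 0:
        raise ValueError("AUPRC undefined without positives")
    area = 0.0
    prev_tp, prev_fp = 0, 0
    for tpb, fpb in zip(tp.tolist(), fp.tolist()):
        dtp = tpb - prev_tp
        if dtp > 0:
            s = (fpb - prev_fp) / dtp
            a = 1.0 + s
            k = prev_fp - s * prev_tp
            if abs(k) < 1e-12:
                area += (dtp / a) / denominator
            else:
                antider = lambda t: t / a - (k / a**2) * math.log(a * t + k)
                area += (antider(tpb) - antider(prev_tp)) / denominator
        prev_tp, prev_fp = tpb, fpb
    return float(area)


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve via the rank-sum statistic (ties averaged)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _entropy(pos: int, neg: int) -> float:
    n = pos + neg
    if n == 0:
        return 0.0
    h = 0.0
    for k in (pos, neg):
        if k:
            p = k / n
            h -= p * math.log2(p)
    return h


def _discretize(values: pd.Series, bins: int) -> pd.Series:
    """Equal-frequency binning of a numeric feature; the missing marker
    forms its own value."""
    out = pd.Series(MISSING, index=values.index, dtype=object)
    present = values.dropna()
    if present.empty:
        return out
    if present.nunique() <= bins:
        out.loc[present.index] = present.astype(str)
        return out
    binned = pd.qcut(present, q=bins, duplicates="drop")
    out.loc[present.index] = binned.astype(str)
    return out


def information_gain(
    values: Sequence, labels: Sequence[bool], bins: int = 10
) -> float:
    """Entropy reduction (bits) of the consistent/inconsistent labeling when
    the data are partitioned by the feature's (discretized) values.

    Continuous features are cut into equal-frequency bins over their
    non-missing values; missing is its own partition cell.
    """
    values = pd.Series(list(values))
    labels = np.asarray(labels, dtype=bool)
    if len(values) == 0:
        raise ValueError("information gain of an empty data set")
    if pd.api.types.is_numeric_dtype(values):
        cells = _discretize(values, bins)
    else:
        cells = values.where(values.notna(), MISSING).astype(str)
    n = len(labels)
    h_total = _entropy(int(labels.sum()), int(n - labels.sum()))
    h_cond = 0.0
    for _, idx in cells.groupby(cells).groups.items():
        sub = labels[np.asarray(idx)]
        h_cond += (len(sub) / n) * _entropy(int(sub.sum()), int(len(sub) - sub.sum()))
    return max(0.0, h_total - h_cond)


def rank_features(
    features: pd.DataFrame,
    labels: Sequence[bool],
    bins: int = 10,
    average_ortholog_pairs: bool = False,
) -> pd.DataFrame:
    """Information gain per feature, sorted descending (ties lexicographic).

    With *average_ortholog_pairs* the (O1)/(O2) columns of each ortholog
    feature are averaged and reported once with suffix (O).
    """
    ig = {
        col: information_gain(features[col], labels, bins=bins)
        for col in features.columns
    }
    if average_ortholog_pairs:
        merged: dict[str, float] = {}
        for col, v in ig.items():
            if col.endswith(" (O1)") or col.endswith(" (O2)"):
                base = col[: -len(" (O1)")] + " (O)"
                merged[base] = merged.get(base, 0.0) + v / 2.0
            else:
                merged[col] = v
        ig = merged
    rows = sorted(ig.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(rows, columns=["feature", "ig"])
    out["rank"] = np.arange(1, len(out) + 1)
    return out
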