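"""The Random-Forest-Filter: confidence scoring of transferred interactions.

`RandomForestFilter` is a model object built from a feature matrix and
consistency labels; `fit()` returns a `RffResults` carrying the trained
forest, preprocessing statistics and diagnostics.  The forest's mean leaf
probability for the consistent class is the confidence score in [0, 1].

Missing values are imputed (median for numeric, mode for categorical) and
every feature that had missing values in training gains a binary
missing-indicator column, so "annotation absent" remains visible to the
trees.  Categorical features are one-hot encoded; category tokens unseen at
scoring time map to a reserved ``__other__`` column.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import evaluation
from .transfer import Setting

__all__ = [
    "RandomForestFilter",
    "RffResults",
    "CvResult",
    "cross_validate",
    "grid_search",
    "choose_threshold",
    "baseline_harmonic_seq_scores",
    "baseline_ortholog_scores",
    "DEFAULT_GRID",
]

OTHER_TOKEN = "__other__"

# hyperparameter grid used when none is given: tree counts and the three
# standard per-split feature-subset rules
DEFAULT_GRID = {
    "n_trees": [50, 100, 250, 500],
    "m_features": ["sqrt", "log2p1", "third"],
}


def _resolve_m(m_features: str | int, d: int) -> int:
    """Number of features considered per split, from a rule name or int."""
    if isinstance(m_features, int):
        return max(1, min(m_features, d))
    if m_features == "sqrt":
        return max(1, int(math.sqrt(d)))
    if m_features == "log2p1":
        return max(1, int(math.log2(d)) + 1)
    if m_features == "third":
        return max(1, d // 3)
    raise ValueError(f"unknown m_features rule {m_features!r}")


@dataclass
class _Preprocessor:
    """Imputation + one-hot encoding fitted on the training matrix."""

    schema: dict[str, str]
    medians: dict[str, float] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)
    indicator_cols: list[str] = field(default_factory=list)
    categories: dict[str, list[str]] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)

    def fit(self, df: pd.DataFrame) -> "_Preprocessor":
        for col, kind in self.schema.items():
            series = df[col]
            if kind in ("real", "int"):
                med = float(series.median()) if series.notna().any() else 0.0
                self.medians[col] = med
            else:
                present = series.dropna()
                self.modes[col] = (
                    str(present.mode().iloc[0]) if not present.empty else OTHER_TOKEN
                )
                self.categories[col] = sorted(present.astype(str).unique())
            if series.isna().any():
                self.indicator_cols.append(col)
        self.columns = list(self._transform_frame(df).columns)
        return self

    def _transform_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        pieces: dict[str, np.ndarray] = {}
        for col, kind in self.schema.items():
            series = df[col]
            if col in self.indicator_cols:
                pieces[f"{col} [missing]"] = series.isna().to_numpy(dtype=float)
            if kind in ("real", "int"):
                pieces[col] = series.fillna(self.medians[col]).to_numpy(dtype=float)
            else:
                filled = series.where(series.notna(), self.modes[col]).astype(str)
                known = set(self.categories[col])
                filled = filled.where(filled.isin(known), OTHER_TOKEN)
                for cat in self.categories[col]:
                    pieces[f"{col} = {cat}"] = (filled == cat).to_numpy(dtype=float)
                pieces[f"{col} = {OTHER_TOKEN}"] = (
                    filled == OTHER_TOKEN
                ).to_numpy(dtype=float)
        return pd.DataFrame(pieces, index=df.index)

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if list(df.columns) != list(self.schema):
            raise ValueError(
                "feature matrix schema does not match the fitted model: "
                f"expected columns {list(self.schema)}, got {list(df.columns)}"
            )
        out = self._transform_frame(df)
        return out[self.columns].to_numpy(dtype=float)


class RandomForestFilter:
    """Model object: transfer-instance features + consistency labels.

    Parameters
    ----------
    features : DataFrame as produced by ``features.build_feature_matrix``
        (its ``attrs["schema"]`` records column kinds; a plain frame is
        accepted and treated as all-numeric).
    labels : boolean sequence, True = consistent.
    n_trees, m_features : forest size and per-split feature subsample
        ("sqrt", "log2p1", "third" or an int).
    seed : RNG seed for the forest.
    setting : the experimental setting the model is trained for.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[bool],
        n_trees: int = 100,
        m_features: str | int = "sqrt",
        seed: int = 0,
        setting: Setting = Setting.AllI,
    ):
        self.features = features
        self.labels = np.asarray(labels, dtype=bool)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align")
        self.schema: dict[str, str] = dict(
            features.attrs.get(
                "schema", {c: "real" for c in features.columns}
            )
        )
        self.n_trees = n_trees
        self.m_features = m_features
        self.seed = seed
        self.setting = setting

    @classmethod
    def from_feature_matrix(cls, df: pd.DataFrame, labels, **kwargs):
        return cls(df, labels, **kwargs)

    def fit(self) -> "RffResults":
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training requires both classes")
        if counts.min() < 2:
            raise ValueError("need at least 2 instances of each class")
        prep = _Preprocessor(schema=self.schema).fit(self.features)
        x = prep.transform(self.features)
        m = _resolve_m(self.m_features, x.shape[1])
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=m,
            random_state=self.seed,
            oob_score=True,
            n_jobs=1,
        )
        forest.fit(x, self.labels)
        return RffResults(model=self, preprocessor=prep, forest=forest)


@dataclass
class RffResults:
    """A fitted Random-Forest-Filter."""

    model: RandomForestFilter
    preprocessor: _Preprocessor
    forest: RandomForestClassifier

    @property
    def oob_accuracy(self) -> float:
        return float(self.forest.oob_score_)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Confidence scores in [0, 1] (mean leaf probability of the
        consistent class).  Raises on schema mismatch."""
        x = self.preprocessor.transform(features)
        pos = list(self.forest.classes_).index(True)
        return self.forest.predict_proba(x)[:, pos]

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.forest.feature_importances_, index=self.preprocessor.columns
        ).sort_values(ascending=False)

    def summary(self) -> str:
        m = self.model
        n_pos = int(m.labels.sum())
        lines = [
            "Random-Forest-Filter results",
            "=" * 34,
            f"setting:            {m.setting.value}",
            f"instances:          {len(m.labels)} "
            f"({n_pos} consistent / {len(m.labels) - n_pos} inconsistent)",
            f"feature columns:    {len(m.schema)} "
            f"(encoded: {len(self.preprocessor.columns)})",
            f"trees:              {m.n_trees}",
            f"m per split:        {m.m_features}",
            f"seed:               {m.seed}",
            f"OOB accuracy:       {self.oob_accuracy:.3f}",
            "",
            "top feature importances:",
        ]
        for name, v in self.feature_importances().head(8).items():
            lines.append(f"  {name:<40s} {v:.4f}")
        return "\n".join(lines)

    def save(self, path: str) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str) -> "RffResults":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class CvResult:
    """Out-of-fold scores from a stratified cross-validation."""

    scores: np.ndarray
    labels: np.ndarray
    fold_assignment: np.ndarray
    per_fold: pd.DataFrame

    def curve(self, relative_denominator: int | None = None,
              gold_size: int | None = None) -> evaluation.EvaluationCurve:
        denom = (
            relative_denominator
            if relative_denominator is not None
            else int(self.labels.sum())
        )
        return evaluation.curve(self.scores, self.labels, denom, gold_size)

    @property
    def auprc(self) -> float:
        return self.curve().auprc

    @property
    def auroc(self) -> float:
        return evaluation.auroc(self.scores, self.labels)


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[bool],
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    m_features: str | int = "sqrt",
    setting: Setting = Setting.AllI,
) -> CvResult:
    """Stratified k-fold cross-validation; every instance is scored by the
    model trained on the other folds."""
    labels = np.asarray(labels, dtype=bool)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) < 2:
        raise ValueError("cross-validation requires both classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; "
            "use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full(len(labels), np.nan)
    assignment = np.full(len(labels), -1, dtype=int)
    fold_rows = []
    for k, (train_idx, test_idx) in enumerate(skf.split(features, labels)):
        model = RandomForestFilter(
            features.iloc[train_idx].reset_index(drop=True),
            labels[train_idx],
            n_trees=n_trees,
            m_features=m_features,
            seed=seed + k,
            setting=setting,
        )
        model.features.attrs["schema"] = dict(
            features.attrs.get("schema", {c: "real" for c in features.columns})
        )
        res = model.fit()
        test = features.iloc[test_idx].reset_index(drop=True)
        test.attrs["schema"] = model.schema
        s = res.score(test)
        scores[test_idx] = s
        assignment[test_idx] = k
        y = labels[test_idx]
        row = {"fold": k, "n": len(test_idx), "n_pos": int(y.sum())}
        if 0 < y.sum() < len(y):
            row["auroc"] = evaluation.auroc(s, y)
            row["auprc"] = evaluation.curve(s, y, int(y.sum())).auprc
        fold_rows.append(row)
    assert not np.isnan(scores).any()
    return CvResult(
        scores=scores,
        labels=labels,
        fold_assignment=assignment,
        per_fold=pd.DataFrame(fold_rows),
    )


def grid_search(
    features: pd.DataFrame,
    labels: Sequence[bool],
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    setting: Setting = Setting.AllI,
) -> tuple[int, str | int]:
    """Pick (n_trees, m_features) maximizing mean cross-validated AUPRC.

    Ties break toward fewer trees, then the smaller per-split subsample.
    """
    grid = grid or DEFAULT_GRID
    if not grid.get("n_trees") or not grid.get("m_features"):
        raise ValueError("grid must list n_trees and m_features options")
    d = len(features.columns)
    results = []
    for n_trees in grid["n_trees"]:
        for m in grid["m_features"]:
            cv = cross_validate(
                features, labels, folds=folds, seed=seed,
                n_trees=n_trees, m_features=m, setting=setting,
            )
            results.append((cv.auprc, n_trees, _resolve_m(m, d), m))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    best = results[0]
    return best[1], best[3]


def choose_threshold(
    cv: CvResult,
    precision_target: float | None = None,
    retained_count: int | None = None,
) -> tuple[float, dict]:
    """Pick a score threshold from cross-validated scores.

    Either the smallest threshold whose precision reaches
    *precision_target*, or the threshold retaining *retained_count*
    instances.  Returns (threshold, achieved metrics).
    """
    if (precision_target is None) == (retained_count is None):
        raise ValueError("give exactly one of precision_target, retained_count")
    order = np.argsort(-cv.scores, kind="stable")
    s = cv.scores[order]
    y = cv.labels[order]
    tp = np.cumsum(y)
    retained = np.arange(1, len(y) + 1)
    precision = tp / retained
    denom = int(cv.labels.sum())
    if retained_count is not None:
        if retained_count >= len(y):
            thr = 0.0
            idx = len(y) - 1
        else:
            idx = retained_count - 1
            thr = float(s[idx])
    else:
        last = np.r_[s[1:] != s[:-1], True]
        ok = np.where(last & (precision >= precision_target))[0]
        if len(ok) == 0:
            raise ValueError(
                f"precision target {precision_target} unreachable; "
                f"max achievable {precision[last].max():.4f}"
            )
        idx = int(ok[-1])  # lowest threshold reaching the target
        thr = float(s[idx])
    achieved = {
        "threshold": thr,
        "precision": float(precision[idx]),
        "relative_recall": float(tp[idx] / denom) if denom else float("nan"),
        "retained": int(retained[idx]),
    }
    return thr, achieved


def _pair_mean(df: pd.DataFrame, base: str, fill: float = 0.0) -> np.ndarray:
    a = df[f"{base} (O1)"].to_numpy(dtype=float)
    b = df[f"{base} (O2)"].to_numpy(dtype=float)
    a = np.nan_to_num(a, nan=fill)
    b = np.nan_to_num(b, nan=fill)
    return (a + b) / 2.0


def baseline_harmonic_seq_scores(df: pd.DataFrame) -> np.ndarray:
    """Baseline filter score: harmonic mean of the two ortholog sequence
    identities (missing treated as 0 identity)."""
    a = np.nan_to_num(df["seq_identity (O1)"].to_numpy(dtype=float), nan=0.0)
    b = np.nan_to_num(df["seq_identity (O2)"].to_numpy(dtype=float), nan=0.0)
    denom = a + b
    out = np.zeros_like(a)
    nz = denom > 0
    out[nz] = 2.0 * a[nz] * b[nz] / denom[nz]
    return out


def baseline_ortholog_scores(df: pd.DataFrame) -> np.ndarray:
    """Baseline filter score: mean ortholog (inparalog x bootstrap) score of
    the two ortholog pairs (missing treated as 0)."""
    return _pair_mean(df, "ortholog_score")
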