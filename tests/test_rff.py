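import numpy as np
import pandas as pd
import pytest

from interolog.rff import (
    CvResult,
    RandomForestFilter,
    baseline_harmonic_seq_scores,
    baseline_ortholog_scores,
    choose_threshold,
    cross_validate,
    grid_search,
)


def planted_frame(n=200, noise=0.05, seed=0, categorical=False):
    """Feature matrix where one feature carries the label plus noise."""
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < 0.5
    df = pd.DataFrame(
        {
            "signal": labels.astype(float) + rng.normal(0, noise, n),
            "noise1": rng.random(n),
            "noise2": rng.random(n),
        }
    )
    schema = {"signal": "real", "noise1": "real", "noise2": "real"}
    if categorical:
        df["cat"] = np.where(rng.random(n) < 0.5, "u", "v")
        schema["cat"] = "categorical"
    df.attrs["schema"] = schema
    return df, labels


class TestTraining:
    def test_same_seed_reproduces_scores_exactly(self):
        df, labels = planted_frame()
        s1 = RandomForestFilter(df, labels, seed=3).fit().score(df)
        s2 = RandomForestFilter(df, labels, seed=3).fit().score(df)
        assert np.array_equal(s1, s2)

    def test_separable_fixture_high_oob_accuracy(self):
        df, labels = planted_frame(n=400, noise=0.01)
        res = RandomForestFilter(df, labels, seed=1).fit()
        assert res.oob_accuracy > 0.95

    def test_replicated_positive_scores_high(self):
        df, labels = planted_frame(n=300, noise=0.01, seed=5)
        res = RandomForestFilter(df, labels, seed=1).fit()
        probe = df[labels].iloc[[0]].reset_index(drop=True)
        probe.attrs["schema"] = df.attrs["schema"]
        assert res.score(probe)[0] >= 0.9

    def test_single_class_rejected(self):
        df, _ = planted_frame(n=50)
        with pytest.raises(ValueError, match="both classes"):
            RandomForestFilter(df, np.ones(50, dtype=bool)).fit()

    def test_schema_mismatch_at_scoring_rejected(self):
        df, labels = planted_frame()
        res = RandomForestFilter(df, labels).fit()
        other = df.rename(columns={"signal": "renamed"})
        other.attrs["schema"] = {"renamed": "real", "noise1": "real",
                                 "noise2": "real"}
        with pytest.raises(ValueError, match="schema"):
            res.score(other)

    def test_scores_in_unit_interval_and_order_invariant(self):
        df, labels = planted_frame(categorical=True)
        res = RandomForestFilter(df, labels, seed=2).fit()
        s = res.score(df)
        assert ((0.0 <= s) & (s <= 1.0)).all()
        perm = np.random.default_rng(0).permutation(len(df))
        shuffled = df.iloc[perm].reset_index(drop=True)
        shuffled.attrs["schema"] = df.attrs["schema"]
        assert np.allclose(res.score(shuffled), s[perm])

    def test_missing_values_imputed_with_indicator(self):
        df, labels = planted_frame(n=100)
        df.loc[::7, "noise1"] = np.nan
        df.attrs["schema"] = {c: "real" for c in df.columns}
        res = RandomForestFilter(df, labels).fit()
        assert "noise1 [missing]" in res.preprocessor.columns
        assert res.preprocessor.medians["noise1"] == pytest.approx(
            df["noise1"].median()
        )

    def test_unseen_category_maps_to_other(self):
        df, labels = planted_frame(categorical=True)
        res = RandomForestFilter(df, labels).fit()
        probe = df.iloc[[0]].copy().reset_index(drop=True)
        probe["cat"] = "never-seen"
        probe.attrs["schema"] = df.attrs["schema"]
        s = res.score(probe)  # must not raise; routed to __other__
        assert 0.0 <= s[0] <= 1.0

    def test_summary_mentions_setting_and_trees(self):
        df, labels = planted_frame()
        res = RandomForestFilter(df, labels, n_trees=50).fit()
        text = res.summary()
        assert "AllI" in text and "50" in text


class TestCrossValidation:
    def test_stratified_fold_sizes_and_cover(self):
        df, labels = planted_frame(n=103)
        cv = cross_validate(df, labels, folds=5, seed=0)
        assert (cv.fold_assignment >= 0).all()
        for cls in (True, False):
            sizes = [
                ((cv.fold_assignment == k) & (labels == cls)).sum()
                for k in range(5)
            ]
            assert max(sizes) - min(sizes) <= 1

    def test_scores_reproducible_under_seed(self):
        df, labels = planted_frame()
        a = cross_validate(df, labels, folds=4, seed=9)
        b = cross_validate(df, labels, folds=4, seed=9)
        assert np.array_equal(a.scores, b.scores)

    def test_small_class_suggests_fewer_folds(self):
        df, labels = planted_frame(n=40)
        labels = np.zeros(40, dtype=bool)
        labels[:5] = True
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(df, labels, folds=10)

    def test_planted_signal_recovered(self):
        df, labels = planted_frame(n=300, noise=0.02)
        cv = cross_validate(df, labels, folds=5, seed=1)
        assert cv.auprc > 0.95 and cv.auroc > 0.95


class TestGridSearch:
    def test_single_cell_grid_returns_it(self):
        df, labels = planted_frame(n=80)
        best = grid_search(
            df, labels, grid={"n_trees": [30], "m_features": ["sqrt"]},
            folds=3, seed=0,
        )
        assert best == (30, "sqrt")

    def test_clearly_superior_cell_selected(self):
        df, labels = planted_frame(n=250, noise=0.4, seed=7)
        best = grid_search(
            df, labels, grid={"n_trees": [2, 150], "m_features": ["sqrt"]},
            folds=3, seed=1,
        )
        assert best[0] == 150

    def test_deterministic_under_seed(self):
        df, labels = planted_frame(n=120, noise=0.3)
        grid = {"n_trees": [10, 40], "m_features": ["sqrt", "third"]}
        a = grid_search(df, labels, grid=grid, folds=3, seed=4)
        b = grid_search(df, labels, grid=grid, folds=3, seed=4)
        assert a == b


class TestThreshold:
    def make_cv(self, scores, labels):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        return CvResult(
            scores=scores, labels=labels,
            fold_assignment=np.zeros(len(labels), dtype=int),
            per_fold=pd.DataFrame(),
        )

    def test_perfect_classifier_full_precision(self):
        cv = self.make_cv([0.9, 0.7, 0.2, 0.1], [True, True, False, False])
        thr, achieved = choose_threshold(cv, precision_target=1.0)
        assert thr == 0.7  # smallest score of any positive
        assert achieved["relative_recall"] == 1.0

    def test_retain_all_gives_zero_threshold(self):
        cv = self.make_cv([0.9, 0.1], [True, False])
        thr, achieved = choose_threshold(cv, retained_count=2)
        assert thr == 0.0 and achieved["retained"] == 2

    def test_unreachable_target_reports_maximum(self):
        cv = self.make_cv([0.9, 0.9], [True, False])
        with pytest.raises(ValueError, match="max achievable"):
            choose_threshold(cv, precision_target=0.9)

    def test_threshold_monotone_in_precision_target(self):
        rng = np.random.default_rng(51)
        for _ in range(20):
            n = 60
            scores = rng.random(n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            cv = self.make_cv(scores, labels)
            thresholds = []
            for target in (0.3, 0.5, 0.7, 0.9):
                try:
                    thr, _ = choose_threshold(cv, precision_target=target)
                except ValueError:
                    thr = np.inf
                thresholds.append(thr)
            assert all(a <= b + 1e-12 for a, b in zip(thresholds, thresholds[1:]))


class TestBaselines:
    def test_harmonic_baseline_matches_closed_form(self):
        df = pd.DataFrame(
            {
                "seq_identity (O1)": [0.8, np.nan],
                "seq_identity (O2)": [0.4, 0.5],
            }
        )
        s = baseline_harmonic_seq_scores(df)
        assert s[0] == pytest.approx(8 / 15)
        assert s[1] == 0.0  # missing treated as zero identity

    def test_ortholog_baseline_is_pair_mean(self):
        df = pd.DataFrame(
            {
                "ortholog_score (O1)": [1.0, 0.5],
                "ortholog_score (O2)": [0.5, np.nan],
            }
        )
        s = baseline_ortholog_scores(df)
        assert s[0] == pytest.approx(0.75)
        assert s[1] == pytest.approx(0.25)
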