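"""TAD/background classification: background contract, features, models,
target-shuffling importance."""

import numpy as np
import pandas as pd
import pytest

from triplextad.intervals import intersect_bp
from triplextad.tad_ml import (build_feature_matrix, check_tad_fraction,
                               generate_background, lncrna_importance,
                               train_and_tune)

SMALL_GRID = {"clf__n_estimators": [100], "clf__max_features": ["sqrt"]}


@pytest.fixture(scope="module")
def tads():
    rng = np.random.default_rng(0)
    rows = []
    for c in ("chr1", "chr2"):
        pos = 20_000
        for _ in range(15):
            L = int(rng.integers(8_000, 14_000))
            rows.append((c, pos, pos + L))
            pos += L + int(rng.integers(10_000, 20_000))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


SIZES = {"chr1": 600_000, "chr2": 600_000}


class TestBackground:
    def test_count_lengths_and_zero_overlap(self, tads, rng):
        bg = generate_background(tads, SIZES, rng=rng)
        assert len(bg) == len(tads)
        assert intersect_bp(bg, tads) == 0
        assert sorted((bg["end"] - bg["start"]).tolist()) == \
            sorted((tads["end"] - tads["start"]).tolist())
        # background intervals must not overlap each other either
        for _, sub in bg.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_high_tad_fraction_refused(self):
        tads = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [90_000]})
        with pytest.raises(ValueError, match="refused"):
            generate_background(tads, {"c": 100_000}, rng=0)

    def test_guard_passes_below_threshold(self, tads):
        frac = check_tad_fraction(tads, SIZES)
        assert 0 < frac < 0.75


def make_sites(rng, regions, lnc, n, chroms=SIZES):
    """n 25-bp sites for one lncRNA uniformly inside the given regions."""
    rows = []
    iv = regions.reset_index(drop=True)
    for _ in range(n):
        j = int(rng.integers(len(iv)))
        s = int(rng.integers(iv.loc[j, "start"], iv.loc[j, "end"] - 25))
        rows.append({"lncrna_id": lnc, "chrom": iv.loc[j, "chrom"],
                     "start": s, "end": s + 25})
    return pd.DataFrame(rows)


class TestFeatureMatrix:
    def test_counts_match_brute_force(self, tads, rng):
        bg = generate_background(tads, SIZES, rng=rng)
        sites = pd.concat([make_sites(rng, tads, "L1", 40),
                           make_sites(rng, bg, "L2", 25),
                           make_sites(rng, tads, "L2", 5)], ignore_index=True)
        X, y = build_feature_matrix(tads, bg, sites)
        regions = pd.concat([tads, bg], ignore_index=True)
        for ri, (_, r) in enumerate(regions.iterrows()):
            for lnc in X.columns:
                sub = sites[sites["lncrna_id"] == lnc]
                want = int(((sub["chrom"] == r["chrom"])
                            & (sub["start"] < r["end"])
                            & (sub["end"] > r["start"])).sum())
                assert X.iloc[ri][lnc] == want

    def test_labels_are_n_ones_n_zeros(self, tads, rng):
        bg = generate_background(tads, SIZES, rng=rng)
        sites = make_sites(rng, tads, "L1", 30)
        X, y = build_feature_matrix(tads, bg, sites)
        assert (y == 1).sum() == len(tads) and (y == 0).sum() == len(bg)

    def test_lncrna_without_tad_site_excluded_by_default(self, tads, rng):
        bg = generate_background(tads, SIZES, rng=rng)
        sites = pd.concat([make_sites(rng, tads, "L1", 30),
                           make_sites(rng, bg, "BGonly", 10)], ignore_index=True)
        X, _ = build_feature_matrix(tads, bg, sites)
        assert "BGonly" not in X.columns
        X2, _ = build_feature_matrix(tads, bg, sites, include_all_lncrnas=True)
        assert "BGonly" in X2.columns

    def test_empty_feature_set_raises(self, tads, rng):
        bg = generate_background(tads, SIZES, rng=rng)
        sites = make_sites(rng, bg, "BGonly", 10)
        with pytest.raises(ValueError, match="empty feature set"):
            build_feature_matrix(tads, bg, sites)


class TestTrainAndTune:
    def _separable(self, rng, n=60, m=8):
        X = pd.DataFrame(rng.poisson(1.0, size=(n, m)),
                         columns=[f"L{j}" for j in range(m)],
                         index=[f"R{i}" for i in range(n)])
        y = pd.Series(np.repeat([1, 0], n // 2), index=X.index)
        X.loc[y == 1, "L0"] += 30            # perfectly separating feature
        return X, y

    def test_separable_matrix_high_accuracy(self, rng):
        X, y = self._separable(rng)
        rep = train_and_tune(X, y, "random_forest", seed=0, grid=SMALL_GRID)
        assert rep.metrics["accuracy"] >= 0.95
        assert set(rep.metrics) == {"accuracy", "auc", "sensitivity",
                                    "specificity", "f1"}

    @pytest.mark.parametrize("model,grid", [
        ("logistic_elastic_net", {"clf__C": [1.0], "clf__l1_ratio": [0.0, 0.5]}),
        ("gradient_boosting", {"clf__n_estimators": [100], "clf__max_depth": [2]}),
        ("svm_rbf", {"clf__C": [1.0, 10.0], "clf__gamma": ["scale"]}),
    ])
    def test_other_models_run(self, rng, model, grid):
        X, y = self._separable(rng)
        rep = train_and_tune(X, y, model, seed=0, grid=grid)
        assert rep.metrics["accuracy"] >= 0.9
        assert 0 <= rep.metrics["auc"] <= 1

    def test_no_test_set_leakage(self, rng):
        X, y = self._separable(rng)
        rep = train_and_tune(X, y, "random_forest", seed=1, grid=SMALL_GRID)
        assert len(set(rep.train_index) & set(rep.test_index)) == 0
        assert len(rep.train_index) + len(rep.test_index) == len(X)
        assert rep.n_test == pytest.approx(0.2 * len(X), abs=1)

    def test_too_few_samples_rejected(self, rng):
        X, y = self._separable(rng, n=20)
        with pytest.raises(ValueError, match="≥ 50"):
            train_and_tune(X, y, "random_forest", seed=0)

    def test_permuted_labels_near_chance(self, rng):
        X, y = self._separable(rng, n=80)
        accs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            yp = pd.Series(r.permutation(y.to_numpy()), index=y.index)
            rep = train_and_tune(X, yp, "random_forest", seed=seed, grid=SMALL_GRID)
            accs.append(rep.metrics["accuracy"])
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_reproducible_given_seed(self, rng):
        X, y = self._separable(rng)
        a = train_and_tune(X, y, "random_forest", seed=5, grid=SMALL_GRID)
        b = train_and_tune(X, y, "random_forest", seed=5, grid=SMALL_GRID)
        assert a.metrics == b.metrics
        assert list(a.test_index) == list(b.test_index)


class TestImportance:
    def test_constant_column_scores_exactly_zero(self, rng):
        X = pd.DataFrame({"signal": np.repeat([5, 0], 30),
                          "const": np.ones(60, dtype=int)},
                         index=[f"R{i}" for i in range(60)])
        y = pd.Series(np.repeat([1, 0], 30), index=X.index)
        rep = train_and_tune(X, y, "random_forest", seed=0, grid=SMALL_GRID)
        scores = {s.lncrna_id: s.score for s in lncrna_importance(rep, rng=rng)}
        assert scores["const"] == 0.0
        assert scores["signal"] > 0.0

    def test_ranks_are_dense_and_sorted(self, rng):
        X = pd.DataFrame(rng.poisson(2.0, size=(60, 5)),
                         columns=[f"L{j}" for j in range(5)],
                         index=[f"R{i}" for i in range(60)])
        y = pd.Series(np.repeat([1, 0], 30), index=X.index)
        X.loc[y == 1] += 3
        rep = train_and_tune(X, y, "random_forest", seed=0, grid=SMALL_GRID)
        imp = lncrna_importance(rep, repeats=5, rng=rng)
        assert [s.rank for s in imp] == list(range(1, 6))
        assert all(imp[i].score >= imp[i + 1].score for i in range(len(imp) - 1))

    def test_label_independent_column_concentrates_at_zero(self, rng):
        # importance of noise columns under a fitted model stays near 0
        ok = 0
        n_runs = 10
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            X = pd.DataFrame({"signal": np.repeat([6, 0], 30) + r.poisson(1, 60),
                              "noise": r.poisson(3, 60)},
                             index=[f"R{i}" for i in range(60)])
            y = pd.Series(np.repeat([1, 0], 30), index=X.index)
            rep = train_and_tune(X, y, "random_forest", seed=seed, grid=SMALL_GRID)
            scores = {s.lncrna_id: s.score for s in lncrna_importance(rep, rng=r)}
            ok += abs(scores["noise"]) < 0.05
        assert ok >= int(0.9 * n_runs)
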