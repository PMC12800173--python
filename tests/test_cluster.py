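"""Clustering stack: preprocessing arithmetic, spectral eigen-oracle,
external clinical gating, grid-search selection soundness, mutual
information and reference-based evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import two_blobs
from pdmci.cluster import (
    build_feature_matrix,
    default_grids,
    evaluate_vs_reference,
    external_criteria_check,
    feature_importance,
    gmm_cluster,
    grid_search,
    kmeans_cluster,
    mean_silhouette,
    spectral_cluster,
    spectral_embedding,
    ClusterSolution,
)


class TestFeatureMatrix:
    def _toy(self):
        return pd.DataFrame(
            {
                "z_tmt_a": [-1.0, 0.0, 1.0, 0.5, -0.5],
                "updrs_iii": [10.0, 20, 30, 40, 50],
                "cardiovascular": [0, 1, 0, 1, 0],
            }
        )

    def test_hand_computed_robust_scaling(self):
        fm = build_feature_matrix(self._toy(), ["z_tmt_a", "updrs_iii", "cardiovascular"])
        # median 30, IQR = 40 - 20 = 20
        assert fm.medians["updrs_iii"] == 30 and fm.iqrs["updrs_iii"] == 20
        assert np.allclose(fm.frame["updrs_iii"], [-1.0, -0.5, 0.0, 0.5, 1.0])
        # z and flag columns pass through unscaled
        assert np.allclose(fm.frame["z_tmt_a"], self._toy()["z_tmt_a"])
        assert set(fm.frame["cardiovascular"]) <= {0.0, 1.0}

    def test_scaled_columns_have_zero_median(self, scored_pd):
        scored, _ = scored_pd
        fm = build_feature_matrix(scored)
        for col in fm.medians:
            assert np.median(fm.frame[col]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_rejected(self):
        df = self._toy().assign(updrs_iii=5.0)
        with pytest.raises(ValueError, match="updrs_iii"):
            build_feature_matrix(df, ["z_tmt_a", "updrs_iii"])

    def test_missing_cells_rejected(self):
        df = self._toy()
        df.loc[0, "z_tmt_a"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_feature_matrix(df, ["z_tmt_a", "updrs_iii"])


class TestSpectral:
    def test_eigenpairs_match_dense_oracle_on_small_instances(self):
        rng = np.random.default_rng(0)
        for n in (4, 6, 8):
            X = rng.normal(size=(n, 3))
            vals, vecs, _ = spectral_embedding(X, k=2, bandwidth=1.0)
            # independent construction of L_sym and full dense eigensolve
            W = np.exp(
                -np.array([[np.sum((a - b) ** 2) for b in X] for a in X]) / 2.0
            )
            np.fill_diagonal(W, 0)
            d = W.sum(1)
            L = np.eye(n) - np.diag(d**-0.5) @ W @ np.diag(d**-0.5)
            ref_vals = np.linalg.eigvalsh(L)
            assert np.max(np.abs(vals - ref_vals[:2])) < 1e-8
            assert abs(ref_vals[0]) < 1e-8  # connected graph: lambda_min = 0

    def test_two_blobs_recovered_exactly(self):
        X, y = two_blobs(seed=1)
        labels, _ = spectral_cluster(X, k=2, bandwidth=3.0, seed=0)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_duplicated_points_get_identical_assignments(self):
        X, _ = two_blobs(n_per=10, seed=2)
        labels, _ = spectral_cluster(np.vstack([X, X]), k=2, bandwidth=3.0, seed=0)
        assert np.array_equal(labels[: len(X)], labels[len(X) :])

    def test_isolated_point_suggests_larger_bandwidth(self):
        X = np.vstack([np.zeros((3, 2)), [[1e6, 1e6]]])
        with pytest.raises(ValueError, match="bandwidth"):
            spectral_cluster(X, k=2, bandwidth=0.1)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            spectral_cluster(np.zeros((1, 2)), k=2, bandwidth=1.0)


class TestPartitioners:
    def test_two_blobs_all_methods_ari_one(self):
        X, y = two_blobs(seed=3)
        assert adjusted_rand_score(y, kmeans_cluster(X, 2, seed=0)) == 1.0
        labels, post = gmm_cluster(X, 2, "full", seed=0)
        assert adjusted_rand_score(y, labels) == 1.0
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_single_cluster_inertia_is_total_ss(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=1, n_init=1, random_state=0).fit(X)
        tss = np.sum((X - X.mean(0)) ** 2)
        assert km.inertia_ == pytest.approx(tss)


class TestSilhouette:
    def test_tight_far_pairs_above_point_nine(self):
        X = np.array([[0.0, 0], [0.1, 0], [50, 0], [50.1, 0]])
        assert mean_silhouette(X, np.array([0, 0, 1, 1])) > 0.9

    def test_matches_brute_force_on_five_points(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0]])
        labels = np.array([0, 0, 0, 1, 1])

        def brute(X, labels):
            n = len(X)
            D = np.abs(X - X.T.reshape(1, -1)).reshape(n, n)
            s = []
            for i in range(n):
                own = labels == labels[i]
                a = D[i, own & (np.arange(n) != i)].mean()
                b = min(
                    D[i, labels == c].mean() for c in set(labels) if c != labels[i]
                )
                s.append((b - a) / max(a, b))
            return np.mean(s)

        D = np.abs(X[:, 0][:, None] - X[:, 0][None, :])
        assert mean_silhouette(X, labels) == pytest.approx(brute(X, labels))

    def test_random_labels_on_structureless_data_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 5))
        labels = rng.integers(0, 2, 200)
        assert abs(mean_silhouette(X, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestExternalCriteria:
    def _clinical(self, n=40, flip_age=False, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        df = pd.DataFrame(
            {
                "age": (np.where(labels, 60.0, 70.0) if flip_age
                        else np.where(labels, 70.0, 60.0)) + rng.normal(0, 1, n),
                "disease_duration": np.where(labels, 6.0, 3.0) + rng.normal(0, 0.5, n),
                "hoehn_yahr": np.where(labels, 3.0, 2.0) + rng.normal(0, 0.1, n),
                "moca_total": np.where(labels, 23.0, 27.0) + rng.normal(0, 0.5, n),
            }
        )
        return labels, df

    def test_planted_structure_passes(self):
        labels, df = self._clinical()
        ok, failed, cand = external_criteria_check(labels, df)
        assert ok and not failed and cand == 1

    def test_lower_moca_but_younger_fails_older_rule(self):
        labels, df = self._clinical(flip_age=True)
        ok, failed, cand = external_criteria_check(labels, df)
        assert not ok and "older" in failed and cand == 1

    def test_random_labels_on_structureless_data_fail_most_of_the_time(self):
        # with mutually independent continuous features a random split
        # passes all three >=-rules only by chance (~1/8), since the
        # candidate choice (lower MoCA median) carries no information
        # about the other medians
        rng = np.random.default_rng(6)
        n = 400
        df = pd.DataFrame(
            rng.normal(size=(n, 4)),
            columns=["age", "disease_duration", "hoehn_yahr", "moca_total"],
        )
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        fails = sum(
            not external_criteria_check(rng.permutation(labels), df)[0]
            for _ in range(40)
        )
        # Binomial(40, 7/8) has 99% mass above 29
        assert fails >= 29

    def test_k_not_two_rejected(self):
        labels, df = self._clinical()
        labels = labels.copy()
        labels[0] = 2
        with pytest.raises(ValueError):
            external_criteria_check(labels, df)


class TestGridSearch:
    def test_selected_solutions_pass_external_and_maximise_silhouette(self, scored_pd):
        scored, _ = scored_pd
        fm = build_feature_matrix(scored)
        best, report = grid_search(fm, scored, seed=0)
        for algorithm, sol in best.items():
            if sol is None:
                continue
            assert sol.external_ok
            ok = report[
                (report["algorithm"] == algorithm)
                & (report["external_ok"])
            ]
            assert sol.silhouette == pytest.approx(ok["silhouette"].max())

    def test_single_passing_configuration_is_selected(self, scored_pd):
        scored, _ = scored_pd
        fm = build_feature_matrix(scored)
        grids = {"kmeans": [{"k": 2, "n_init": 10}]}
        best, report = grid_search(fm, scored, grids=grids, seed=0)
        assert best["kmeans"] is not None
        assert len(report) == 1

    def test_exploratory_k_logged_but_not_selected(self, scored_pd):
        scored, _ = scored_pd
        fm = build_feature_matrix(scored)
        grids = {"kmeans": [{"k": k, "n_init": 5} for k in (2, 3, 4)]}
        best, report = grid_search(fm, scored, grids=grids, seed=0)
        assert sorted(report["k"]) == [2, 3, 4]
        assert best["kmeans"].hyperparameters["k"] == 2

    def test_no_surviving_candidate_returns_none(self, scored_pd):
        scored, _ = scored_pd
        fm = build_feature_matrix(scored)
        grids = {"spectral": [{"k": 2, "bandwidth": 1e-9}]}  # isolated points
        best, report = grid_search(fm, scored, grids=grids, seed=0)
        assert best["spectral"] is None
        assert "error" in report.columns


class TestFeatureImportance:
    def _fm(self, X, names):
        from pdmci.cluster import FeatureMatrix

        return FeatureMatrix(X, names, pd.RangeIndex(len(X)), {}, {})

    def test_label_copy_attains_label_entropy(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 400)
        X = np.column_stack([labels.astype(float), rng.normal(size=400)])
        mi = feature_importance(self._fm(X, ["copy", "noise"]), labels)
        p = labels.mean()
        h = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        assert mi["copy"] == pytest.approx(h, rel=1e-6)
        assert mi.index[0] == "copy"

    def test_hand_computed_two_by_two(self):
        # joint counts 40/10/10/40
        x = np.array([0] * 50 + [1] * 50)
        y = np.array([0] * 40 + [1] * 10 + [0] * 10 + [1] * 40)
        mi = feature_importance(self._fm(x[:, None].astype(float), ["f"]), y)["f"]
        oracle = 0.0
        for i in (0, 1):
            for j in (0, 1):
                pij = np.mean((x == i) & (y == j))
                oracle += pij * np.log(pij / (np.mean(x == i) * np.mean(y == j)))
        assert mi == pytest.approx(oracle, rel=1e-9)

    def test_independent_feature_below_permutation_null(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, 500)
        x = rng.normal(size=500)
        fm = self._fm(x[:, None], ["f"])
        observed = feature_importance(fm, labels)["f"]
        null = np.array(
            [feature_importance(fm, rng.permutation(labels))["f"] for _ in range(100)]
        )
        assert observed < np.percentile(null, 95)

    def test_constant_feature_zero(self):
        mi = feature_importance(
            self._fm(np.ones((50, 1)), ["const"]), np.arange(50) % 2
        )
        assert mi["const"] == 0.0


class TestEvaluation:
    def _solution(self, labels, score=None):
        return ClusterSolution(
            algorithm="kmeans",
            hyperparameters={"k": 2},
            labels=np.asarray(labels),
            silhouette=0.5,
            external_ok=True,
            mci_cluster=1,
            label_map={1: "MCI", 0: "NC"},
            soft_score=score,
        )

    def test_perfect_agreement_all_metrics_one(self):
        labels = np.array([0] * 30 + [1] * 30)
        ref = np.array(["NC"] * 30 + ["MCI"] * 30)
        ev = evaluate_vs_reference(self._solution(labels, labels.astype(float)), ref)
        assert ev.sensitivity == ev.precision == ev.accuracy == ev.auc == 1.0

    def test_reported_overlap_arithmetic(self):
        """Confusion TP=39, FN=1, FP=26, TN=49 gives sensitivity 0.975 and
        precision 0.6 — the four-way overlap arithmetic."""
        pred = np.array([1] * 39 + [0] * 1 + [1] * 26 + [0] * 49)
        ref = np.array(["MCI"] * 40 + ["NC"] * 75)
        ev = evaluate_vs_reference(self._solution(pred, pred.astype(float)), ref)
        assert ev.sensitivity == pytest.approx(39 / 40)
        assert ev.precision == pytest.approx(39 / 65)
        assert (ev.tp, ev.fn, ev.fp, ev.tn) == (39, 1, 26, 49)

    def test_random_soft_scores_auc_near_half(self):
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 2, 200)
        ref = np.where(rng.integers(0, 2, 200), "MCI", "NC")
        ev = evaluate_vs_reference(
            self._solution(labels, rng.normal(size=200)), ref
        )
        assert abs(ev.auc - 0.5) < 0.1

    def test_single_class_reference_gives_no_auc(self):
        labels = np.array([0, 1] * 10)
        ref = np.array(["NC"] * 20)
        ev = evaluate_vs_reference(self._solution(labels, labels.astype(float)), ref)
        assert ev.auc is None


def test_default_grids_scale_with_median_distance(scored_pd):
    scored, _ = scored_pd
    fm = build_feature_matrix(scored)
    grids = default_grids(fm.X)
    bws = [g["bandwidth"] for g in grids["spectral"]]
    assert bws == sorted(bws) and bws[0] > 0
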