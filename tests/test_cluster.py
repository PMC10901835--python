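import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from tempro.cluster import (ClusterError, FuzzyCMeans, build_profiles,
                            cluster_counts, core_members, estimate_fuzzifier,
                            fuzzy_cmeans, hcluster_profiles, standardize)
from tempro.simulate import make_archetype_profiles


def make_de_tables(lfc: pd.DataFrame, de_at: dict[str, list[float]]):
    """Per-timepoint DE tables from a feature x timepoint lfc matrix."""
    out = {}
    for tp in lfc.columns:
        direction = pd.Series("ns", index=lfc.index)
        for fid, tps in de_at.items():
            if tp in tps:
                direction[fid] = "up" if lfc.loc[fid, tp] >= 0 else "down"
        out[tp] = pd.DataFrame({"log2fc": lfc[tp], "direction": direction})
    return out


class TestBuildProfiles:
    LFC = pd.DataFrame([[0.5, 1.0, 2.0], [0.1, 0.2, 0.1], [0.0, 0.5, 3.0]],
                       index=["early", "never", "late"], columns=[6.0, 24.0, 168.0])

    def test_never_de_feature_absent(self):
        prof = build_profiles(make_de_tables(self.LFC, {"early": [6.0]}))
        assert "never" not in prof.index

    def test_late_only_feature_keeps_full_grid_with_zero_anchor(self):
        prof = build_profiles(make_de_tables(self.LFC, {"late": [168.0]}))
        assert list(prof.columns) == [0.0, 6.0, 24.0, 168.0]
        assert prof.loc["late", 0.0] == 0.0
        assert prof.loc["late", 6.0] == 0.0  # its lfc at 6 h, not imputed

    def test_no_significant_features_gives_empty_matrix(self):
        prof = build_profiles(make_de_tables(self.LFC, {}))
        assert prof.empty

    def test_planted_responder_count_recovered(self, criterion_dataset):
        from tempro.diffexpr import timecourse_de
        from tempro.preprocess import cpm, tmm_factors
        ds = criterion_dataset
        norm = cpm(ds.mrna, norm_factors=tmm_factors(ds.mrna))
        prof = build_profiles(timecourse_de(norm, ds.metadata, "CD4"))
        assert len(prof) == pytest.approx(200, rel=0.10)


class TestStandardize:
    def test_flat_row_dropped(self):
        prof = pd.DataFrame([[1.0] * 6, [0.0, 1, 2, 3, 4, 5]], index=["flat", "ok"])
        z = standardize(prof)
        assert list(z.index) == ["ok"]

    def test_two_point_row(self):
        z = standardize(pd.DataFrame([[0.0, 2.0]], index=["f"]))
        assert z.loc["f"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.loc["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_postcondition_on_random_rows(self):
        rng = np.random.default_rng(0)
        z = standardize(pd.DataFrame(rng.normal(size=(40, 6))))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ClusterError):
            standardize(pd.DataFrame([[1.0]]))


class TestEstimateFuzzifier:
    def test_regression_fixture_from_direct_formula_evaluation(self):
        N, D = 1000, 6
        expected = 1.0 + (1418 / N + 22.05) * D ** -2 \
            + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
        assert estimate_fuzzifier(N, D) == pytest.approx(expected, rel=1e-12)

    def test_large_n_limit(self):
        N, D = 1e9, 6
        limit = 1.0 + 22.05 / 36 + 0.243 * D ** (-0.0406 * np.log(N) - 0.1134)
        assert estimate_fuzzifier(N, D) == pytest.approx(limit, rel=1e-6)

    def test_always_above_one(self):
        for n in (10, 100, 10_000):
            for d in (2, 6, 20):
                assert estimate_fuzzifier(n, d) > 1.0


class TestFuzzyCMeans:
    def test_single_cluster_degenerates_to_mean_profile(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        model = FuzzyCMeans(n_clusters=1, m=1.5, random_state=0).fit(X)
        assert np.allclose(model.membership_, 1.0)
        assert np.allclose(model.cluster_centers_[0], X.mean(axis=0), atol=1e-8)

    def test_membership_rows_sum_to_one(self):
        X, _, _ = make_archetype_profiles(seed=1)
        model = fuzzy_cmeans(standardize(pd.DataFrame(X)), c=6, seed=0)
        assert np.allclose(model.membership_.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objective_trace_non_increasing(self, seed):
        X, _, _ = make_archetype_profiles(n_per=40, seed=seed)
        model = fuzzy_cmeans(standardize(pd.DataFrame(X)), c=6, seed=seed)
        assert np.all(np.diff(model.objective_trace_) <= 1e-9)

    def test_two_separated_archetypes_recovered_exactly(self):
        rng = np.random.default_rng(5)
        a = np.tile([3.0, 0, 0, 0, 0, 0], (50, 1)) + rng.normal(0, 0.1, (50, 6))
        b = np.tile([0, 0, 0, 0, 0, 3.0], (50, 1)) + rng.normal(0, 0.1, (50, 6))
        z = standardize(pd.DataFrame(np.vstack([a, b])))
        model = fuzzy_cmeans(z, c=2, seed=0)
        assign = core_members(model, z.index)
        truth = np.array([0] * 50 + [1] * 50)[assign["core"]]
        assert adjusted_rand_score(truth, assign.loc[assign["core"], "cluster"]) == 1.0

    def test_planted_six_archetypes_recovered(self):
        X, labels, _ = make_archetype_profiles(n_archetypes=6, n_per=100,
                                               noise_sd=0.3, seed=3)
        z = standardize(pd.DataFrame(X))
        model = fuzzy_cmeans(z, c=6, seed=0)
        assign = core_members(model, z.index)
        core = assign["core"].to_numpy()
        ari = adjusted_rand_score(labels[z.index.to_numpy()[core]],
                                  assign.loc[core, "cluster"])
        assert ari >= 0.9

    def test_small_fuzzifier_approaches_hard_assignment(self):
        X, _, _ = make_archetype_profiles(n_per=30, noise_sd=0.1, seed=2)
        z = standardize(pd.DataFrame(X))
        model = fuzzy_cmeans(z, c=6, m=1.05, seed=0)
        assert np.median(model.membership_.max(axis=1)) > 0.99

    def test_coincident_point_gets_full_membership(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        centers = np.array([[0.0, 0.0], [2.0, 2.0]])
        u = FuzzyCMeans._memberships(X, centers, m=2.0)
        assert u[0, 0] == 1.0 and u[0, 1] == 0.0
        assert np.allclose(u.sum(axis=1), 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ClusterError):
            FuzzyCMeans(n_clusters=5).fit(np.zeros((3, 4)))

    def test_label_permutation_leaves_partition_identical(self):
        X, _, _ = make_archetype_profiles(n_per=30, seed=4)
        z = standardize(pd.DataFrame(X))
        model = fuzzy_cmeans(z, c=6, seed=0)
        perm = np.array([3, 1, 5, 0, 4, 2])
        permuted_assign = np.argsort(perm)[model.labels_]  # relabeled clusters
        before = [frozenset(np.flatnonzero(model.labels_ == k)) for k in range(6)]
        after = [frozenset(np.flatnonzero(permuted_assign == k)) for k in range(6)]
        assert set(before) == set(after)

    def test_sklearn_estimator_contract(self):
        from sklearn.base import clone
        est = FuzzyCMeans(n_clusters=3, m=2.0, random_state=1)
        assert clone(est).get_params()["n_clusters"] == 3
        X, _, _ = make_archetype_profiles(n_archetypes=3, n_per=20, seed=0)
        fitted = est.fit(X)
        assert fitted.predict(X).shape == (60,)
        assert fitted.transform(X).shape == (60, 3)
        assert np.array_equal(fitted.fit_predict(X), fitted.labels_)


class TestCoreMembers:
    def _model(self, u):
        model = FuzzyCMeans(n_clusters=u.shape[1])
        model.membership_ = u
        return model

    def test_clear_core(self):
        out = core_members(self._model(np.array([[0.9, 0.1]])), ["f1"])
        assert out.loc["f1", "core"] and out.loc["f1", "cluster"] == 0

    def test_threshold_boundary_inclusive(self):
        out = core_members(self._model(np.array([[0.45, 0.55]])), ["f1"])
        assert out.loc["f1", "core"] and out.loc["f1", "cluster"] == 1

    def test_exact_tie_is_not_core(self):
        out = core_members(self._model(np.array([[0.5, 0.5]])), ["f1"])
        assert not out.loc["f1", "core"]

    def test_cluster_counts(self):
        u = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.5, 0.5]])
        assign = core_members(self._model(u), list("abcd"))
        counts = cluster_counts(assign, 2)
        assert list(counts) == [2, 1]


class TestHclusterProfiles:
    def test_identical_profiles_merge_at_zero_height(self):
        prof = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4, 3, 2, 1.0]],
                            index=["a", "b", "c"])
        Z, labels, _ = hcluster_profiles(prof, n_clusters=2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_profile_and_negation_at_distance_two(self):
        prof = pd.DataFrame([[1.0, 2, 3, 4], [-1.0, -2, -3, -4]], index=["a", "b"])
        Z, _, _ = hcluster_profiles(prof, n_clusters=2)
        assert Z[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_manual_upgma_trace(self):
        # four profiles whose correlation matrix is hand-computable; the
        # scipy result must match a manual average-linkage trace
        prof = pd.DataFrame([
            [1.0, 2.0, 3.0, 4.0],
            [1.1, 2.0, 3.1, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [0.0, 1.0, 0.0, 1.0],
        ], index=list("abcd"))
        corr = np.corrcoef(prof.to_numpy())
        dist = 1.0 - corr
        Z, _, _ = hcluster_profiles(prof, n_clusters=2)
        # manual trace: a-b merge first (most correlated)
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(dist[0, 1], abs=1e-12)
        # next: d joins {a,b} at the average of its two distances
        avg_d_ab = 0.5 * (dist[3, 0] + dist[3, 1])
        assert Z[1, 2] == pytest.approx(min(avg_d_ab, dist[2, 3],
                                            0.5 * (dist[2, 0] + dist[2, 1])), abs=1e-12)

    def test_constant_profile_dropped(self):
        prof = pd.DataFrame([[1.0, 1, 1, 1], [1, 2, 3, 4.0], [4, 3, 2, 1.0]],
                            index=["flat", "up", "down"])
        _, labels, kept = hcluster_profiles(prof, n_clusters=2)
        assert "flat" not in kept
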