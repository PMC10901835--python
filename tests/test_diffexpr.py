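import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tempro.cluster import build_profiles
from tempro.diffexpr import (DEThresholds, DiffExprError, bky_adjust,
                             bky_reject, call_de, de_contrast, percent_de,
                             row_ttests, subset_contrast, timecourse_de)
from tempro.preprocess import cpm, tmm_factors


class TestRowTtests:
    def test_identical_groups_give_p_one(self):
        a = np.array([[1.0, 2.0, 3.0]])
        p, t, tested = row_ttests(a, a.copy())
        assert tested[0]
        assert p[0] == pytest.approx(1.0)

    def test_paired_zero_differences_degenerate_to_p_one(self):
        a = np.array([[1.0, 2.0, 3.0]])
        p, _, tested = row_ttests(a, a.copy(), paired=True)
        assert tested[0] and p[0] == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        # textbook pooled two-sample t computed independently
        A = np.array([5.1, 5.3, 4.9])
        B = np.array([2.0, 2.2, 1.8])
        sp2 = (A.var(ddof=1) * 2 + B.var(ddof=1) * 2) / 4
        t_hand = (A.mean() - B.mean()) / np.sqrt(sp2 * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), 4)
        p, t, _ = row_ttests(A[None, :], B[None, :])
        assert t[0] == pytest.approx(t_hand, rel=1e-12)
        assert p[0] == pytest.approx(p_hand, rel=1e-12)

    def test_agrees_with_scipy_on_random_rows(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(50, 4))
        b = rng.normal(size=(50, 5))
        p, t, _ = row_ttests(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(t, ref.statistic)
        assert np.allclose(p, ref.pvalue)

    def test_too_few_present_values_is_untested(self):
        a = np.array([[1.0, np.nan, np.nan]])
        b = np.array([[2.0, 3.0, 4.0]])
        p, _, tested = row_ttests(a, b)
        assert not tested[0] and np.isnan(p[0])

    def test_zero_variance_unequal_means_degenerates_to_zero(self):
        a = np.array([[2.0, 2.0, 2.0]])
        b = np.array([[5.0, 5.0, 5.0]])
        p, t, tested = row_ttests(a, b)
        assert tested[0] and p[0] == 0.0 and np.isinf(t[0])


def bky_oracle(p: np.ndarray, q: float) -> np.ndarray:
    """Manual two-stage trace: explicit step-up loops, no shared code."""
    m = len(p)
    order = np.argsort(p)
    q1 = q / (1 + q)

    def bh_count(level):
        k = 0
        for i in range(m):
            if p[order[i]] <= (i + 1) * level / m:
                k = i + 1
        return k

    r1 = bh_count(q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    r2 = bh_count(q1 * m / (m - r1))
    out = np.zeros(m, dtype=bool)
    out[order[:r2]] = True
    return out


class TestBkyAdjust:
    FIXTURE = np.array([0.001, 0.004, 0.019, 0.095, 0.201, 0.280,
                        0.550, 0.740, 0.900, 1.000])

    def test_fixture_matches_hand_executed_two_stage_trace(self):
        # stage 1 at 0.05/1.05 rejects 2; stage 2 level 0.0476*10/8 keeps 2
        expected = bky_oracle(self.FIXTURE, 0.05)
        _, rejected = bky_adjust(self.FIXTURE, 0.05)
        assert np.array_equal(rejected, expected)
        assert np.array_equal(rejected,
                              [True, True, False, False, False, False,
                               False, False, False, False])

    def test_all_ones_reject_nothing(self):
        q_adj, rej = bky_adjust(np.ones(8), 0.05)
        assert not rej.any()
        assert np.allclose(q_adj, 1.0)

    def test_single_zero_p_rejected_at_any_level(self):
        q_adj, rej = bky_adjust(np.array([0.0]), 1e-9)
        assert rej[0] and q_adj[0] == 0.0

    @pytest.mark.parametrize("q", [0.01, 0.05, 0.2])
    def test_matches_statsmodels_tsbky_rejections(self, q):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = np.concatenate([rng.uniform(0, 1, 150), rng.beta(0.1, 1, 50)])
            assert np.array_equal(bky_reject(p, q),
                                  multipletests(p, alpha=q, method="fdr_tsbky")[0])

    def test_q_adj_thresholding_reproduces_rejection_sets(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 1, 200), rng.beta(0.2, 1, 60)])
        q_adj, _ = bky_adjust(p, 0.05)
        for q in (0.003, 0.01, 0.049, 0.05, 0.11, 0.5):
            assert np.array_equal(q_adj <= q, bky_reject(p, q)), q

    def test_superset_of_plain_bh_and_monotone(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 1, 300), rng.beta(0.1, 1, 100)])
        q = 0.05
        bh = multipletests(p, alpha=q / (1 + q), method="fdr_bh")[0]
        bky = bky_reject(p, q)
        assert np.all(bky[bh])  # BKY rejects everything plain BH rejects
        q_adj, _ = bky_adjust(p, q)
        order = np.argsort(p)
        assert np.all(np.diff(q_adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(DiffExprError):
            bky_adjust(np.array([0.5, 1.5]))
        with pytest.raises(DiffExprError):
            bky_adjust(np.array([np.nan]))

    def test_fdr_control_and_power_vs_bh(self):
        # 900 uniform nulls + 100 Beta(0.1, 1) alternatives per replicate
        rng = np.random.default_rng(2024)
        reps = 200
        fdp, power, bh_power = [], [], []
        for _ in range(reps):
            p = np.concatenate([rng.uniform(0, 1, 900), rng.beta(0.1, 1, 100)])
            is_null = np.arange(1000) < 900
            rej = bky_reject(p, 0.05)
            n_rej = rej.sum()
            fdp.append((rej & is_null).sum() / max(n_rej, 1))
            power.append((rej & ~is_null).sum() / 100)
            bh = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            bh_power.append((bh & ~is_null).sum() / 100)
        mc_se = np.std(fdp, ddof=1) / np.sqrt(reps)
        assert np.mean(fdp) <= 0.05 + 3 * mc_se
        assert np.mean(power) >= np.mean(bh_power)


class TestCallDe:
    def test_mrna_boundary_is_strict(self):
        lfc = pd.Series([1.5], index=["g1"])
        q = pd.Series([0.001], index=["g1"])
        assert call_de(lfc, q, "mrna")["g1"] == "ns"
        assert call_de(lfc + 0.01, q, "mrna")["g1"] == "up"

    def test_protein_boundary_is_inclusive(self):
        lfc = pd.Series([1.0, -1.0], index=["p1", "p2"])
        q = pd.Series([0.05, 0.05], index=["p1", "p2"])
        out = call_de(lfc, q, "protein")
        assert out["p1"] == "up" and out["p2"] == "down"

    def test_threshold_conjunction(self):
        lfc = pd.Series([2.0], index=["g1"])
        q = pd.Series([0.02], index=["g1"])
        assert call_de(lfc, q, "mrna")["g1"] == "ns"  # fails alpha 0.01

    def test_unknown_kind_rejected(self):
        with pytest.raises(DiffExprError):
            call_de(pd.Series([1.0]), pd.Series([0.01]), "metabolite")

    def test_direction_flips_under_group_swap(self, criterion_dataset):
        ds = criterion_dataset
        norm = cpm(ds.mrna, norm_factors=tmm_factors(ds.mrna))
        meta = ds.metadata
        g6 = meta[(meta["subset"] == "CD4") & (meta["timepoint_h"] == 6)]["sample_id"].tolist()
        g0 = meta[(meta["subset"] == "CD4") & (meta["timepoint_h"] == 0)]["sample_id"].tolist()
        fwd = de_contrast(norm, meta, g6, g0, "fwd")
        rev = de_contrast(norm, meta, g0, g6, "rev")
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert (rev["direction"] == fwd["direction"].map(flip)).all()


class TestPercentDe:
    def test_arithmetic(self):
        assert percent_de(0, 100) == 0.0
        assert percent_de(25, 250) == 10.0

    def test_zero_quantified_rejected(self):
        with pytest.raises(DiffExprError):
            percent_de(0, 0)

    def test_union_percentage_is_weighted_mean_of_subsets(self):
        n1, k1, n2, k2 = 120, 30, 80, 10
        combined = percent_de(k1 + k2, n1 + n2)
        weighted = (percent_de(k1, n1) * n1 + percent_de(k2, n2) * n2) / (n1 + n2)
        assert combined == pytest.approx(weighted)


class TestRecovery:
    def test_planted_responders_recovered(self, criterion_dataset):
        # 200 strong responders among 2000 genes: union DE percentage near
        # the planted 10% and recall >= 0.9 at default thresholds
        ds = criterion_dataset
        norm = cpm(ds.mrna, norm_factors=tmm_factors(ds.mrna))
        tabs = timecourse_de(norm, ds.metadata, "CD4")
        de_any = set(build_profiles(tabs).index)
        responders = set(ds.truth.responder_genes)
        percent = 100 * len(de_any) / ds.mrna.shape[0]
        recall = len(de_any & responders) / len(responders)
        assert percent == pytest.approx(10.0, abs=2.0)
        assert recall >= 0.9

    def test_subset_contrast_sign_convention_and_recall(self, criterion_dataset):
        # the planted subset effect is constant in time, so detection is
        # scored over the union of per-timepoint contrasts (the between-subset
        # DE universe is counted across the whole course)
        ds = criterion_dataset
        norm = cpm(ds.mrna, norm_factors=tmm_factors(ds.mrna))
        truth = ds.truth.params["subset_effect_log2"]
        planted = truth[truth != 0]
        nulls = truth[truth == 0].index
        hit = pd.Series(False, index=planted.index)
        false_any = pd.Series(False, index=nulls)
        for tp in sorted(set(ds.metadata["timepoint_h"])):
            tab = subset_contrast(norm, ds.metadata, tp)
            # positive planted effect = higher in CD4 = "up" under the convention
            expected = np.where(planted > 0, "up", "down")
            hit |= tab.loc[planted.index, "direction"].to_numpy() == expected
            false_any |= (tab.loc[nulls, "direction"] != "ns").to_numpy()
        assert hit.mean() >= 0.9
        assert false_any.mean() < 0.02

    def test_identical_subsets_yield_no_de(self, small_dataset):
        ds = small_dataset
        meta = ds.metadata.copy()
        cd4 = meta[meta["subset"] == "CD4"]["sample_id"].tolist()
        # duplicate CD4 values into the CD8 columns -> no between-subset signal
        values = ds.mrna.values.copy()
        cd8 = meta[meta["subset"] == "CD8"]["sample_id"].tolist()
        values[cd8] = values[cd4].to_numpy()
        from tempro.io import ExpressionMatrix
        norm = cpm(ExpressionMatrix(values, "mrna"))
        tab = subset_contrast(norm, meta, 6.0)
        assert (tab["direction"] == "ns").all()
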