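"""Gene filtering, robust correlation, PC-contribution stratification,
Kaplan-Meier and log-rank, each checked against hand or brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from circaloh import CohortConfig, generate_cohort
from circaloh.covsurv import (NoSignificantPairs, assign_groups, bicor,
                              correlation_matrix, covariance_scores,
                              covsurv_pipeline, differential_means_test,
                              filter_expressed_genes, kaplan_meier,
                              logrank_test, select_significant_pairs,
                              split_by_sample_code, CorrelationMatrix)


class TestFilterAndSplit:
    def test_filter_boundary_is_strict(self):
        expr = pd.DataFrame({f"s{i}": [1.0 if i < 5 else 0.0, 1.0 if i < 6 else 0.0]
                             for i in range(10)}, index=["half", "six"])
        kept = filter_expressed_genes(expr)
        assert list(kept.index) == ["six"]  # exactly 50% removed, 60% kept

    def test_all_zero_matrix_warns_empty(self):
        expr = pd.DataFrame(np.zeros((3, 4)), index=list("abc"),
                            columns=[f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning):
            assert filter_expressed_genes(expr).empty

    def test_sample_code_convention(self):
        clin = pd.DataFrame({"sample_id": ["TCGA-AA-0001-01", "TCGA-AA-0001-11",
                                           "TCGA-AA-0002-06", "TCGA-AA-0003-20",
                                           "weird"]})
        tumor, normal = split_by_sample_code(clin)
        assert tumor == ["TCGA-AA-0001-01", "TCGA-AA-0002-06"]
        assert normal == ["TCGA-AA-0001-11"]

    def test_partition_conserves_samples(self):
        bundle = generate_cohort(CohortConfig(n_patients=15, n_normal=5,
                                              n_background_genes=5, seed=1))
        tumor, normal = split_by_sample_code(bundle.clinical)
        assert len(tumor) + len(normal) == len(bundle.clinical)


class TestDifferential:
    def test_overwhelming_shift_flagged(self, rng):
        x = rng.normal(0, 1, size=(1, 100))
        expr = pd.DataFrame(np.concatenate([x, x + 5.0], axis=1),
                            index=["g"],
                            columns=[f"t{i}" for i in range(100)]
                            + [f"n{i}" for i in range(100)])
        res = differential_means_test(expr, [f"t{i}" for i in range(100)],
                                      [f"n{i}" for i in range(100)])
        assert res.loc["g", "significant"]

    def test_constant_gene_p_one(self):
        expr = pd.DataFrame([[1.0] * 8], index=["g"],
                            columns=[f"s{i}" for i in range(8)])
        res = differential_means_test(expr, [f"s{i}" for i in range(4)],
                                      [f"s{i}" for i in range(4, 8)])
        assert res.loc["g", "p"] == 1.0

    def test_null_flag_rate_near_nominal(self, rng):
        n_genes = 10000
        expr = pd.DataFrame(rng.normal(size=(n_genes, 60)),
                            columns=[f"s{i}" for i in range(60)])
        res = differential_means_test(expr, [f"s{i}" for i in range(30)],
                                      [f"s{i}" for i in range(30, 60)])
        rate = res["significant"].mean()
        se = np.sqrt(0.001 * 0.999 / n_genes)
        assert rate < 0.001 + 4 * se


def _bicor_direct(x, y):
    """Straight transliteration of the biweight midcorrelation formula."""
    out = []
    for v in (x, y):
        v = np.asarray(v, float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        a = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
        out.append(a * (v - med))
    gx, gy = out
    return (gx * gy).sum() / np.sqrt((gx ** 2).sum() * (gy ** 2).sum())


class TestBicor:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(size=50)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_direct_formula_oracle_five_points(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 5.0, 4.0, 10.0]
        assert bicor(x, y) == pytest.approx(_bicor_direct(x, y), abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian(self, rng):
        for _ in range(5):
            z = rng.normal(size=200)
            x = z + rng.normal(size=200)
            y = z + rng.normal(size=200)
            assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.02

    def test_robust_to_one_gross_outlier(self, rng):
        z = rng.normal(size=100)
        x = z + 0.5 * rng.normal(size=100)
        y = z + 0.5 * rng.normal(size=100)
        b0, p0 = bicor(x, y), np.corrcoef(x, y)[0, 1]
        x2 = x.copy()
        x2[0] = 50.0  # gross outlier
        b1, p1 = bicor(x2, y), np.corrcoef(x2, y)[0, 1]
        assert abs(b1 - b0) < 0.1
        assert abs(p1 - p0) > 0.3

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 2.0])  # MAD = 0
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bicor([1, 2, 3, 4, 5], [1, 2, 3, 4])

    @given(st.integers(min_value=0, max_value=2 ** 32 - 1),
           st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    def test_bounds_symmetry_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        b = bicor(x, y)
        assert -1 <= b <= 1
        assert bicor(y, x) == pytest.approx(b)
        assert bicor(scale * x + shift, y) == pytest.approx(b, abs=1e-9)


class TestCorrelationMatrix:
    def test_square_case_structure(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 30)), index=list("abc"),
                            columns=[f"s{i}" for i in range(30)])
        cm = correlation_matrix(expr, list("abc"), list("abc"))
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.allclose(cm.r, cm.r.T)

    def test_planted_covariance_detected_null_not(self):
        strong = generate_cohort(CohortConfig(n_patients=400, n_normal=57,
                                              covariance_strength=0.9, seed=5))
        t_ids, _ = split_by_sample_code(strong.clinical)
        cm = correlation_matrix(strong.expression, strong.gene_sets["clock"],
                                strong.gene_sets["wnt"], t_ids)
        assert (cm.p.to_numpy() < 0.001).mean() > 0.5
        null = generate_cohort(CohortConfig(n_patients=400, n_normal=57,
                                            covariance_strength=0.0, seed=6))
        t_ids, _ = split_by_sample_code(null.clinical)
        cm0 = correlation_matrix(null.expression, null.gene_sets["clock"],
                                 null.gene_sets["wnt"], t_ids)
        assert (cm0.p.to_numpy() < 0.001).mean() < 0.02

    def test_zero_r_gives_p_one(self):
        from circaloh.covsurv import _corr_pvalue
        assert _corr_pvalue(0.0, 100) == 1.0

    def test_too_few_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"],
                            columns=list("wxyz"))
        with pytest.raises(ValueError):
            correlation_matrix(expr, ["a"], ["b"])


class TestSelectPairs:
    def _cm(self, p_vals):
        r = pd.DataFrame(0.5, index=["g1"], columns=["g5", "g6"])
        p = pd.DataFrame([p_vals], index=["g1"], columns=["g5", "g6"])
        return CorrelationMatrix(r, p, 100)

    def test_all_null_halts(self):
        with pytest.raises(NoSignificantPairs):
            select_significant_pairs(self._cm([1.0, 1.0]))

    def test_union_set_logic(self):
        pairs, union = select_significant_pairs(self._cm([1e-6, 0.5]))
        assert [(p[0], p[1]) for p in pairs] == [("g1", "g5")]
        assert union == ["g1", "g5"]

    def test_planted_pairs_recovered(self):
        hits = 0
        for seed in range(10):
            b = generate_cohort(CohortConfig(n_patients=400, n_normal=57,
                                             n_background_genes=20,
                                             covariance_strength=0.9, seed=seed))
            t_ids, _ = split_by_sample_code(b.clinical)
            cm = correlation_matrix(b.expression, b.gene_sets["clock"][:3],
                                    b.gene_sets["wnt"][:2], t_ids)
            pairs, _ = select_significant_pairs(cm)
            hits += len(pairs) >= 5  # 5 of the 6 planted correlated pairs
        assert hits >= 9


class TestCovarianceScores:
    def test_contributions_sum_to_100(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 20)),
                            index=list("abcd"),
                            columns=[f"s{i}" for i in range(20)])
        scores = covariance_scores(expr, list(expr.columns), list("abcd"))
        assert scores["pc_contribution"].sum() == pytest.approx(100.0, abs=1e-9)
        assert set(scores["decile"]) <= set(range(1, 11))

    def test_hand_eigen_oracle_3x2(self):
        # 3 individuals x 2 genes; oracle: eigen-decomposition of the 2x2
        # covariance of the standardised matrix, scores by projection
        expr = pd.DataFrame([[1.0, 2.0, 6.0], [2.0, 1.0, 4.0]],
                            index=["g1", "g2"], columns=["a", "b", "c"])
        z = expr.T.to_numpy(dtype=float)
        z = (z - z.mean(0)) / z.std(0, ddof=1)
        cov = z.T @ z / 2
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        proj = z @ lead
        expected = 100 * proj ** 2 / (proj ** 2).sum()
        scores = covariance_scores(expr, ["a", "b", "c"], ["g1", "g2"])
        assert np.allclose(np.sort(scores["pc_contribution"]), np.sort(expected),
                           atol=1e-9)

    def test_duplicate_individual_equal_contributions(self, rng):
        base = rng.normal(size=(3, 10))
        base[:, 1] = base[:, 0]  # duplicate individual
        expr = pd.DataFrame(base, index=list("abc"),
                            columns=[f"s{i}" for i in range(10)])
        scores = covariance_scores(expr, list(expr.columns), list("abc"))
        assert scores.loc["s0", "pc_contribution"] == \
               pytest.approx(scores.loc["s1", "pc_contribution"])

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc"),
                            columns=[f"s{i}" for i in range(10)])
        expr.loc["b"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            scores = covariance_scores(expr, list(expr.columns), list("abc"))
        assert scores["pc_contribution"].sum() == pytest.approx(100.0)


class TestAssignGroups:
    def _scores(self, contribs, ids=None):
        ids = ids or [f"s{i}" for i in range(len(contribs))]
        return pd.DataFrame({"pc_contribution": contribs}, index=ids)

    def test_even_split(self):
        g = assign_groups(self._scores([1.0, 2.0, 3.0, 4.0]))
        assert (g == "high").sum() == 2 and (g == "low").sum() == 2
        assert g["s3"] == "high" and g["s0"] == "low"

    def test_odd_n_extra_goes_low(self):
        g = assign_groups(self._scores([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (g == "low").sum() == 3

    def test_ties_stable_by_id(self):
        g1 = assign_groups(self._scores([1.0] * 4))
        g2 = assign_groups(self._scores([1.0] * 4))
        assert g1.equals(g2)
        assert abs((g1 == "high").sum() - (g1 == "low").sum()) <= 1

    def test_strong_separation_recovers_planted_level(self):
        bundle = generate_cohort(CohortConfig(n_patients=300, n_normal=57,
                                              covariance_strength=1.0,
                                              noise_sd=0.5, seed=2))
        res = covsurv_pipeline(bundle)
        truth = bundle.truth["covariance_level"]
        agree = (res.groups.map({"high": 1, "low": 0})
                 .reindex(truth.index) == truth).mean()
        assert agree >= 0.8


class TestKaplanMeier:
    def _clin(self, times, events, ids=None):
        ids = ids or [f"s{i}-01" for i in range(len(times))]
        return pd.DataFrame({"sample_id": ids, "patient_id": ids,
                             "type": "tumor", "time_days": times,
                             "event": events})

    def test_hand_product_limit_oracle(self):
        # times 1 (event), 2 (censored), 3 (event):
        # S(1) = (1 - 1/3) = 2/3; S(3) = 2/3 * (1 - 1/1) = 0
        clin = self._clin([1.0, 2.0, 3.0], [1, 0, 1])
        groups = pd.Series("all", index=clin["sample_id"])
        curves = kaplan_meier(clin, groups)["all"]
        s = dict(zip(curves["time"], curves["survival"]))
        assert s[1.0] == pytest.approx(2 / 3)
        assert s[3.0] == pytest.approx(0.0)

    def test_no_events_flat_curve(self):
        clin = self._clin([5.0, 6.0, 7.0], [0, 0, 0])
        groups = pd.Series("all", index=clin["sample_id"])
        with pytest.warns(UserWarning):
            curves = kaplan_meier(clin, groups)["all"]
        assert (curves["survival"] == 1.0).all()

    def test_all_events_matches_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 2.0, 5.0]
        clin = self._clin(times, [1] * 5)
        groups = pd.Series("all", index=clin["sample_id"])
        curves = kaplan_meier(clin, groups)["all"]
        for k, t in enumerate(sorted(times), start=1):
            row = curves[curves["time"] == t]
            assert row["survival"].iloc[0] == pytest.approx((5 - k) / 5)

    def test_survival_monotone_nonincreasing(self, rng):
        clin = self._clin(rng.exponential(100, 50).tolist(),
                          rng.integers(0, 2, 50).tolist())
        groups = pd.Series("all", index=clin["sample_id"])
        curves = kaplan_meier(clin, groups)["all"]
        assert (np.diff(curves["survival"]) <= 1e-12).all()

    def test_negative_times_rejected(self):
        clin = self._clin([1.0, -2.0], [1, 1])
        with pytest.raises(ValueError):
            kaplan_meier(clin, pd.Series("all", index=clin["sample_id"]))


class TestLogrank:
    def _clin(self, times, events, groups):
        ids = [f"s{i}-01" for i in range(len(times))]
        clin = pd.DataFrame({"sample_id": ids, "patient_id": ids,
                             "type": "tumor", "time_days": times,
                             "event": events})
        return clin, pd.Series(groups, index=ids)

    def test_identical_groups_null(self):
        clin, g = self._clin([1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0],
                             ["a"] * 3 + ["b"] * 3)
        res = logrank_test(clin, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_hypergeometric_oracle_2v2(self):
        # group A events at 1, 3; group B events at 2, 4 (all events).
        # Hand sums: O_A = 2, E_A = 1/2 + 1/3 + 1/2 = 4/3,
        # V = 1/4 + 2/9 + 1/4 = 13/18; chi2 = (2/3)^2 / (13/18) = 8/13
        clin, g = self._clin([1.0, 3.0, 2.0, 4.0], [1, 1, 1, 1],
                             ["a", "a", "b", "b"])
        res = logrank_test(clin, g)
        chi2 = (2 - 4 / 3) ** 2 / (13 / 18)
        assert res.statistic == pytest.approx(chi2, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-10)

    def test_empty_group_rejected(self):
        clin, g = self._clin([1, 2, 3], [1, 1, 1], ["a", "a", "a"])
        with pytest.raises(ValueError):
            logrank_test(clin, g)


class TestPipeline:
    def test_end_to_end_returns_consistent_result(self):
        bundle = generate_cohort(CohortConfig(n_patients=120, n_normal=30,
                                              covariance_strength=0.9, seed=8))
        res = covsurv_pipeline(bundle)
        n_tumor = (bundle.clinical["type"] == "tumor").sum()
        assert len(res.groups) == n_tumor
        assert set(res.groups) == {"high", "low"}
        assert res.scores["pc_contribution"].sum() == pytest.approx(100.0)
        assert 0 < res.logrank.p_value <= 1
        assert len(res.differential) == len(bundle.gene_sets["clock"])

    def test_zero_covariance_halts_on_no_pairs(self):
        bundle = generate_cohort(CohortConfig(n_patients=60, n_normal=10,
                                              n_background_genes=20,
                                              covariance_strength=0.0, seed=4))
        with pytest.raises(NoSignificantPairs):
            covsurv_pipeline(bundle)
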