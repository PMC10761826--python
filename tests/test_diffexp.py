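import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pnstrat import (
    CountMatrix,
    DataError,
    DEThresholds,
    bh_adjust,
    composite_call,
    fold_change,
    nb_wald_per_gene,
    size_factors,
    t_test_per_gene,
)

from conftest import make_expr


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t."""
    from scipy import stats

    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_matches_textbook_formula(self, two_groups):
        a, b = [1.0, 2.0, 3.0, 1.5, 2.5], [4.0, 5.0, 6.0, 4.5, 5.5]
        mat = make_expr(np.array(a + b)[None, :], scale="log2")
        out = t_test_per_gene(mat, two_groups)
        t, p = pooled_t_oracle(a, b)
        assert out["statistic"].iloc[0] == pytest.approx(t, abs=1e-10)
        assert out["p_t"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_random_fixtures_match_oracle(self, two_groups):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 10))
        mat = make_expr(values, scale="log2")
        out = t_test_per_gene(mat, two_groups)
        for i in range(20):
            t, p = pooled_t_oracle(values[i, :5], values[i, 5:])
            assert out["statistic"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert out["p_t"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_label_swap_negates_statistic(self, two_groups):
        rng = np.random.default_rng(1)
        mat = make_expr(rng.normal(size=(5, 10)), scale="log2")
        out1 = t_test_per_gene(mat, two_groups)
        swapped = two_groups.map({"A": "B", "B": "A"})
        out2 = t_test_per_gene(mat, swapped)
        np.testing.assert_allclose(out1["statistic"], -out2["statistic"], atol=1e-10)
        np.testing.assert_allclose(out1["p_t"], out2["p_t"], atol=1e-12)

    def test_equal_constant_groups_p_one(self, two_groups):
        mat = make_expr(np.full((1, 10), 3.0), scale="log2")
        out = t_test_per_gene(mat, two_groups)
        assert out["statistic"].iloc[0] == 0.0
        assert out["p_t"].iloc[0] == 1.0

    def test_group_of_one_rejected(self):
        grouping = pd.Series(["A"] + ["B"] * 4, index=[f"s{j}" for j in range(5)])
        with pytest.raises(DataError):
            t_test_per_gene(make_expr(np.zeros((2, 5)), scale="log2"), grouping)


def median_of_ratios_oracle(df: pd.DataFrame) -> np.ndarray:
    """Independent re-derivation of the size-factor formula."""
    usable = df[(df > 0).all(axis=1)]
    geo = np.exp(np.log(usable).mean(axis=1))
    return np.array([np.median(usable[c] / geo) for c in df.columns])


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"s1": [3, 7, 11], "s2": [3, 7, 11], "s3": [3, 7, 11]})
        np.testing.assert_allclose(size_factors(df).to_numpy(), 1.0)

    def test_three_gene_fixture_matches_oracle_and_doubling_ratio(self):
        df = pd.DataFrame({"s1": [10, 20, 40], "s2": [12, 18, 36], "s3": [20, 40, 80]})
        sf = size_factors(df)
        np.testing.assert_allclose(sf.to_numpy(), median_of_ratios_oracle(df), atol=1e-12)
        # s3 is exactly double s1: the ratio of their factors is exactly 2
        assert sf["s3"] / sf["s1"] == pytest.approx(2.0, abs=1e-12)

    def test_genes_with_zeros_excluded_from_median(self):
        df = pd.DataFrame({"s1": [0, 8, 8], "s2": [5, 8, 8], "s3": [9, 8, 8]})
        # only the all-positive genes (rows 2, 3) feed the median
        np.testing.assert_allclose(size_factors(df).to_numpy(),
                                   median_of_ratios_oracle(df), atol=1e-12)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(DataError):
            size_factors(df)


class TestNbWald:
    def grouping(self, n=40):
        return pd.Series(["A"] * (n // 2) + ["B"] * (n // 2),
                         index=[f"s{j}" for j in range(n)])

    def test_all_zero_gene_p_one_fc_missing(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(5, 40))
        counts[2] = 0
        mat = make_expr(counts, scale="counts")
        out, _ = nb_wald_per_gene(mat, self.grouping())
        assert out["p_nb"].iloc[2] == 1.0
        assert np.isnan(out["log2fc_nb"].iloc[2])

    def test_type_one_error_calibrated_on_null_poisson(self):
        """Near-Poisson null data: rejection rate at 0.05 close to nominal."""
        rng = np.random.default_rng(123)
        mu = np.exp2(rng.normal(6, 1.5, 2000))
        counts = rng.poisson(mu[:, None], size=(2000, 40))
        mat = make_expr(counts, scale="counts")
        out, _ = nb_wald_per_gene(mat, self.grouping())
        rate = (out["p_nb"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_detects_planted_fold_change(self):
        # only 50 of 200 genes shift, so normalisation cannot absorb the effect
        rng = np.random.default_rng(7)
        mu = np.full((200, 1), 200.0)
        mu_b = mu.copy()
        mu_b[:50] *= 2.0
        a = rng.poisson(mu, size=(200, 20))
        b = rng.poisson(mu_b, size=(200, 20))
        mat = make_expr(np.hstack([a, b]), scale="counts")
        out, _ = nb_wald_per_gene(mat, self.grouping())
        assert (out["p_nb"].iloc[:50] < 0.01).mean() > 0.95
        assert np.median(out["log2fc_nb"].iloc[:50]) == pytest.approx(-1.0, abs=0.15)

    def test_dispersion_floor_applied(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, size=(50, 40))
        out, _ = nb_wald_per_gene(make_expr(counts, scale="counts"), self.grouping())
        assert (out["dispersion"] >= 1e-8).all()


class TestBhAdjust:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_geq_p_and_monotone(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.1, 1.5])


class TestFoldChange:
    def test_equal_means_fc_one(self, two_groups):
        mat = make_expr(np.full((1, 10), 4.0))
        assert fold_change(mat, two_groups).iloc[0] == pytest.approx(1.0)

    def test_half(self, two_groups):
        values = np.array([[4.0] * 5 + [8.0] * 5])
        assert fold_change(make_expr(values), two_groups).iloc[0] == pytest.approx(0.5)

    def test_reciprocity(self, two_groups):
        rng = np.random.default_rng(2)
        mat = make_expr(rng.uniform(1, 50, size=(10, 10)))
        fc_ab = fold_change(mat, two_groups)
        fc_ba = fold_change(mat, two_groups.map({"A": "B", "B": "A"}))
        np.testing.assert_allclose(fc_ab * fc_ba, 1.0, atol=1e-12)


class TestCompositeCall:
    def frame(self, p_t, p_nb, fc, t_sign=None, nb_sign=None):
        n = len(p_t)
        t_sign = t_sign if t_sign is not None else np.where(np.array(fc) < 1, -1.0, 1.0)
        nb_sign = nb_sign if nb_sign is not None else t_sign
        genes = [f"g{i}" for i in range(n)]
        t_res = pd.DataFrame({"statistic": t_sign, "p_t": p_t,
                              "mean_A": np.zeros(n), "mean_B": np.zeros(n)}, index=genes)
        nb_res = pd.DataFrame({"statistic": nb_sign, "p_nb": p_nb}, index=genes)
        return t_res, nb_res, pd.Series(fc, index=genes)

    def test_all_gates_pass_lower(self):
        t_res, nb_res, fc = self.frame([0.01], [0.01], [0.5])
        out = composite_call(t_res, nb_res, fc)
        assert out["call"].iloc[0] == "lower"
        assert out["q_t"].iloc[0] >= out["p_t"].iloc[0]

    def test_fc_boundary_is_strict(self):
        t_res, nb_res, fc = self.frame([0.001], [0.001], [0.8])
        assert composite_call(t_res, nb_res, fc)["call"].iloc[0] == "unchanged"
        t_res, nb_res, fc = self.frame([0.001], [0.001], [1.25])
        assert composite_call(t_res, nb_res, fc)["call"].iloc[0] == "unchanged"

    def test_one_failing_gate_blocks_call(self):
        # q_nb fails: many significant t p-values but one large nb p inflates its q
        t_res, nb_res, fc = self.frame([0.01, 0.01], [0.01, 0.9], [0.5, 0.5])
        out = composite_call(t_res, nb_res, fc)
        assert out["call"].iloc[1] == "unchanged"

    def test_direction_disagreement_forced_unchanged(self):
        t_res, nb_res, fc = self.frame([0.01], [0.01], [0.5],
                                       t_sign=[1.0], nb_sign=[1.0])
        assert composite_call(t_res, nb_res, fc)["call"].iloc[0] == "unchanged"

    def test_higher_call(self):
        t_res, nb_res, fc = self.frame([0.01], [0.01], [2.0])
        assert composite_call(t_res, nb_res, fc)["call"].iloc[0] == "higher"

    def test_misaligned_universes_rejected(self):
        t_res, nb_res, fc = self.frame([0.01], [0.01], [0.5])
        with pytest.raises(DataError):
            composite_call(t_res, nb_res, fc.rename({"g0": "h0"}))

    def test_q_thresholds_enforced(self):
        # uniform-looking p-values: raw p < 0.05 for the head of the list
        # but BH q = 0.12 everywhere, so no gene passes the q < 0.1 gate
        p = [0.012 * (i + 1) for i in range(10)]
        t_res, nb_res, fc = self.frame(p, p, [0.5] * 10)
        out = composite_call(t_res, nb_res, fc)
        assert (np.array(p[:4]) < 0.05).all()
        assert (out["q_t"] > 0.1).all()
        assert (out["call"] == "unchanged").all()


def test_sensitivity_and_fdr_on_planted_cohort(small_cohort):
    """Composite caller recovers planted DE with controlled false discovery."""
    from pnstrat import adjust_for_purity, log_transform, run_de

    sim = small_cohort
    logexpr = log_transform(sim["linear"])
    residuals = adjust_for_purity(logexpr, sim["purity"])
    table = run_de(sim["counts"], sim["linear"], residuals,
                   sim["truth"].group_of_sample)
    called = set(table.index[table["call"] != "unchanged"])
    planted = set(sim["truth"].de_log2fc.index)
    sens = len(called & planted) / len(planted)
    fdr = len(called - planted) / max(len(called), 1)
    assert sens >= 0.7
    assert fdr <= 0.15
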