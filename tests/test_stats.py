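"""Statistical engines against independent oracles and limit cases."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from avmod.errors import DegenerateDesignError
from avmod.stats import (
    mixed_model_fit, one_sample_t, spearman_rho, tukey_kramer, two_way_anova,
)


def random_design(rng, balanced=False):
    if balanced:
        counts = {c: 6 for c in [(0, 0), (0, 1), (1, 0), (1, 1)]}
    else:
        counts = {c: int(rng.integers(3, 9))
                  for c in [(0, 0), (0, 1), (1, 0), (1, 1)]}
    y, a, v = [], [], []
    for (aa, vv), n in counts.items():
        y.extend(rng.normal(aa * 0.5 + vv * 1.0 + aa * vv * 0.7, 1.0, n))
        a.extend([aa] * n)
        v.extend([vv] * n)
    return np.array(y), np.array(a, bool), np.array(v, bool)


def anova_oracle_rss(y, a, v):
    """Brute-force Type-III oracle: explicit normal-equations solves."""
    ae, ve = np.where(a, 1.0, -1.0), np.where(v, 1.0, -1.0)
    cols = {"auditory": ae, "visual": ve, "interaction": ae * ve}

    def rss(names):
        X = np.column_stack([np.ones(y.size)] + [cols[n] for n in names])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    full = rss(["auditory", "visual", "interaction"])
    dfd = y.size - 4
    out = {}
    for term in cols:
        reduced = rss([t for t in cols if t != term])
        F = (reduced - full) / (full / dfd)
        out[term] = (F, float(sps.f.sf(F, 1, dfd)))
    return out


class TestTwoWayAnova:
    def test_matches_rss_oracle_random_instances(self, rng):
        for rep in range(50):
            y, a, v = random_design(rng, balanced=(rep % 2 == 0))
            res = two_way_anova(y, a, v)
            oracle = anova_oracle_rss(y, a, v)
            assert res.F_aud == pytest.approx(oracle["auditory"][0], abs=1e-8)
            assert res.F_vis == pytest.approx(oracle["visual"][0], abs=1e-8)
            assert res.F_int == pytest.approx(oracle["interaction"][0], abs=1e-8)
            assert res.p_int == pytest.approx(oracle["interaction"][1], abs=1e-10)

    def test_matches_statsmodels_type3(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        for _ in range(10):
            y, a, v = random_design(rng)
            df = pd.DataFrame({"y": y, "a": a.astype(int), "v": v.astype(int)})
            fit = smf.ols("y ~ C(a, Sum) * C(v, Sum)", data=df).fit()
            table = sm.stats.anova_lm(fit, typ=3)
            res = two_way_anova(y, a, v)
            assert res.F_aud == pytest.approx(table.loc["C(a, Sum)", "F"],
                                              rel=1e-8)
            assert res.F_vis == pytest.approx(table.loc["C(v, Sum)", "F"],
                                              rel=1e-8)
            assert res.F_int == pytest.approx(
                table.loc["C(a, Sum):C(v, Sum)", "F"], rel=1e-8)

    def test_identical_observations_give_zero_F(self):
        y = np.full(12, 3.0)
        a = np.repeat([0, 0, 1, 1], 3).astype(bool)
        v = np.tile([0, 1, 0, 1], 3).astype(bool)
        res = two_way_anova(y, a, v)
        assert res.F_aud == res.F_vis == res.F_int == 0.0
        assert res.p_aud == res.p_vis == res.p_int == 1.0

    def test_exact_effect_zero_noise_gives_infinite_F(self):
        a = np.repeat([0, 0, 1, 1], 3).astype(bool)
        v = np.tile([0, 1, 0, 1], 3).astype(bool)
        y = np.where(v, 2.0, 0.0)
        res = two_way_anova(y, a, v)
        assert np.isinf(res.F_vis) and res.p_vis == 0.0
        assert res.F_aud == 0.0 and res.p_aud == 1.0

    def test_empty_cell_rejected(self):
        y = np.arange(9.0)
        a = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0], bool)
        v = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1], bool)
        with pytest.raises(DegenerateDesignError):
            two_way_anova(y, a, v)

    @given(scale=st.floats(min_value=0.01, max_value=100),
           shift=st.floats(min_value=-50, max_value=50))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        y, a, v = random_design(rng)
        base = two_way_anova(y, a, v)
        moved = two_way_anova(y * scale + shift, a, v)
        assert moved.F_aud == pytest.approx(base.F_aud, rel=1e-6, abs=1e-9)
        assert moved.F_int == pytest.approx(base.F_int, rel=1e-6, abs=1e-9)

    def test_sums_of_squares_add_up_on_balanced_design(self, rng):
        y, a, v = random_design(rng, balanced=True)
        ss = two_way_anova(y, a, v).ss_table
        total = ss["auditory"] + ss["visual"] + ss["interaction"] + ss["residual"]
        assert total == pytest.approx(ss["total"], rel=1e-8)


class TestOneSampleT:
    def test_matches_direct_formula(self, rng):
        for _ in range(100):
            x = rng.normal(size=int(rng.integers(3, 40)))
            mu0 = float(rng.normal())
            res = one_sample_t(x, mu0)
            t = (x.mean() - mu0) / (x.std(ddof=1) / np.sqrt(x.size))
            assert res.t == pytest.approx(t, abs=1e-12)
            assert res.df == x.size - 1

    def test_symmetric_sample_gives_t_zero(self):
        res = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert res.t == 0.0 and res.p == 1.0

    def test_df_convention(self, rng):
        res = one_sample_t(rng.normal(size=119), 0.0)
        assert res.df == 118

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDesignError):
            one_sample_t([2.0, 2.0, 2.0], 0.0)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x ** 3).rho == pytest.approx(1.0)
        assert spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_ties_match_scipy_and_naive_ranks(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.integers(0, 5, n) + rng.normal(0, 0.1, n)
            try:
                res = spearman_rho(x, y)
            except DegenerateDesignError:
                assert len(set(x)) == 1 or len(set(y)) == 1
                continue
            ref = sps.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-10)

            # exhaustive O(n^2) mid-rank oracle
            def naive_ranks(a):
                return np.array([
                    np.sum(a < ai) + 1 + (np.sum(a == ai) - 1) / 2.0
                    for ai in a])
            rx, ry = naive_ranks(x), naive_ranks(y)
            rho = np.corrcoef(rx, ry)[0, 1]
            assert res.rho == pytest.approx(rho, abs=1e-10)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDesignError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestTukeyKramer:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        res = tukey_kramer([("x", x), ("y", y)])[0]
        t_ref = sps.ttest_ind(x, y)
        assert res.q == pytest.approx(np.sqrt(2) * abs(t_ref.statistic), rel=1e-10)
        assert res.p_adj == pytest.approx(t_ref.pvalue, rel=1e-6)

    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        for res in tukey_kramer([("a", g), ("b", g), ("c", g)]):
            assert res.p_adj > 0.999
            assert res.mean_diff == 0.0

    def test_matches_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(1.0, 1, 9),
                               rng.normal(0.5, 1, 7)])
        labels = np.array(["a"] * 6 + ["b"] * 9 + ["c"] * 7)
        ref = pairwise_tukeyhsd(vals, labels)
        ours = tukey_kramer([(g, vals[labels == g]) for g in ("a", "b", "c")])
        for row, mine in zip(ref.summary().data[1:], ours):
            assert mine.p_adj == pytest.approx(float(row[3]), abs=1e-4)

    def test_small_group_rejected(self):
        with pytest.raises(DegenerateDesignError):
            tukey_kramer([("a", [1.0]), ("b", [1.0, 2.0])])

    def test_symmetry_in_pair_order(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 6)
        r1 = tukey_kramer([("a", a), ("b", b)])[0]
        r2 = tukey_kramer([("b", b), ("a", a)])[0]
        assert r1.p_adj == pytest.approx(r2.p_adj)
        assert r1.mean_diff == pytest.approx(-r2.mean_diff)


def simulate_lmm(rng, n_per_patch=20, beta=None, sd_neuron=1.5, sd_resid=1.0):
    beta = beta or {"intercept": 5.0, "aud": 0.5, "vis": 6.0,
                    "patch": -1.0, "patch_aud": 1.5}
    rows = []
    for p, patch in enumerate(["AF", "AM"]):
        for i in range(n_per_patch):
            nid = f"{patch}{i}"
            u = rng.normal(0, sd_neuron)
            for aud, vis in [(1, 1), (0, 1), (1, 0), (0, 0)]:
                mu = (beta["intercept"] + beta["aud"] * aud + beta["vis"] * vis
                      + beta["patch"] * p + beta["patch_aud"] * p * aud)
                rows.append((nid, patch, aud, vis,
                             mu + u + rng.normal(0, sd_resid)))
    return pd.DataFrame(rows, columns=["neuron_id", "patch", "aud", "vis",
                                       "rate"])


class TestMixedModel:
    def test_zero_variance_limit_equals_ols(self, rng):
        rows = simulate_lmm(rng, sd_neuron=0.0)
        res = mixed_model_fit(rows, var_ratio=0.0)
        X = np.column_stack([
            np.ones(len(rows)), rows["aud"], rows["vis"],
            (rows["patch"] == "AM").astype(float),
            (rows["patch"] == "AM").astype(float) * rows["aud"]])
        beta_ols = np.linalg.lstsq(X, rows["rate"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.beta, beta_ols, atol=1e-8)
        assert res.var_neuron == 0.0

    def test_balanced_design_matches_gls_oracle(self, rng):
        rows = simulate_lmm(rng)
        res = mixed_model_fit(rows)
        # closed-form GLS with the fitted compound-symmetric covariance
        theta = res.var_neuron / res.var_resid
        X = np.column_stack([
            np.ones(len(rows)), rows["aud"], rows["vis"],
            (rows["patch"] == "AM").astype(float),
            (rows["patch"] == "AM").astype(float) * rows["aud"]])
        y = rows["rate"].to_numpy()
        neurons = rows["neuron_id"].to_numpy()
        V = np.eye(len(rows)) + theta * (neurons[:, None] == neurons[None, :])
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(res.beta, beta_gls, atol=1e-8)

    def test_matches_statsmodels_ml(self, rng):
        import statsmodels.formula.api as smf
        rows = simulate_lmm(rng)
        rows["patch_aud"] = (rows["patch"] == "AM").astype(int) * rows["aud"]
        rows["patch_i"] = (rows["patch"] == "AM").astype(int)
        ref = smf.mixedlm("rate ~ aud + vis + patch_i + patch_aud", rows,
                          groups=rows["neuron_id"]).fit(reml=False)
        res = mixed_model_fit(rows)
        np.testing.assert_allclose(
            res.beta,
            [ref.params[k] for k in ["Intercept", "aud", "vis", "patch_i",
                                     "patch_aud"]],
            rtol=1e-4, atol=1e-6)
        assert res.var_neuron == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=0.01)

    def test_singular_design_names_columns(self, rng):
        rows = simulate_lmm(rng)
        # make the auditory flag coincide with the patch indicator
        rows["aud"] = (rows["patch"] == "AM").astype(int)
        with pytest.raises(DegenerateDesignError, match="collinear"):
            mixed_model_fit(rows)

    def test_wald_df_is_residual(self, rng):
        rows = simulate_lmm(rng, n_per_patch=10)
        res = mixed_model_fit(rows)
        assert res.df == len(rows) - 5
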