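"""Differential expression stack: weights, consensus correlation, GLS vs a
matrix-algebra oracle, moderation recovery, FDR/q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipscpipe.diffexpr import (
    ModerationState,
    consensus_correlation,
    ebayes_moderate,
    estimate_prior,
    fdr_adjust,
    fit_de,
    precision_weights,
)


def _cs_cohort(rng, G=1000, m=30, k=2, rho=0.3, effect=None):
    n = m * k
    donors = np.repeat(np.arange(m), k)
    dx = (donors < m // 2).astype(float)
    X = np.column_stack([np.ones(n), dx])
    u = rng.normal(0, np.sqrt(rho / (1 - rho)), (G, m)) if rho > 0 else np.zeros((G, m))
    Y = u[:, donors] + rng.normal(0, 1, (G, n))
    if effect is not None:
        Y += np.outer(effect, dx)
    expr = pd.DataFrame(Y, index=[f"g{i}" for i in range(G)],
                        columns=[f"s{i}" for i in range(n)])
    return expr, X, donors


class TestPrecisionWeights:
    def test_nb_counts_weights_increase_with_expression(self, rng):
        G, n = 1500, 30
        mu = np.exp(rng.uniform(np.log(2), np.log(5000), G))
        lam = rng.gamma(1 / 0.05, mu[:, None] * 0.05, (G, n))
        counts = pd.DataFrame(rng.poisson(lam), index=[f"g{i}" for i in range(G)])
        w = precision_weights(counts, np.ones((n, 1)))
        order = np.argsort(mu)
        assert w.to_numpy()[order[:200]].mean() < w.to_numpy()[order[-200:]].mean()
        assert np.isfinite(w.to_numpy()).all() and (w.to_numpy() > 0).all()

    def test_homoskedastic_counts_near_constant_weights(self, rng):
        counts = pd.DataFrame(rng.poisson(5000, (300, 25)),
                              index=[f"g{i}" for i in range(300)])
        w = precision_weights(counts, np.ones((25, 1)))
        cv = w.to_numpy().std() / w.to_numpy().mean()
        assert cv < 0.2

    def test_too_few_genes_refused(self, rng):
        counts = pd.DataFrame(rng.poisson(100, (5, 10)))
        with pytest.raises(ValueError):
            precision_weights(counts, np.ones((10, 1)))


class TestConsensusCorrelation:
    def test_recovers_simulated_donor_icc(self, rng):
        expr, X, donors = _cs_cohort(rng, G=2000, m=40, k=2, rho=0.4)
        rho_hat = consensus_correlation(expr, X, donors)
        assert abs(rho_hat - 0.4) < 0.08

    def test_shuffled_blocks_near_zero(self, rng):
        expr, X, donors = _cs_cohort(rng, G=800, m=30, k=2, rho=0.4)
        shuffled = rng.permutation(donors)
        assert abs(consensus_correlation(expr, X, shuffled)) < 0.05

    def test_no_replicates_returns_zero_with_warning(self, rng):
        expr, X, _ = _cs_cohort(rng, G=50, m=20, k=1, rho=0.0)
        with pytest.warns(UserWarning):
            assert consensus_correlation(expr, X, np.arange(20)) == 0.0


class TestFitDe:
    def test_rho_zero_equals_ols(self, rng):
        expr, X, donors = _cs_cohort(rng, G=100, m=10, k=3, rho=0.0)
        gls = fit_de(expr, X, 1, block=donors, rho=0.0)
        Y = expr.to_numpy()
        beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]
        np.testing.assert_allclose(gls["log2FC"], beta[1], atol=1e-10)

    def test_single_gene_matches_matrix_algebra_oracle(self):
        # 4 samples, 2 donors x 2 lines, explicit covariance inverse
        rho = 0.35
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1.0]])
        y = np.array([0.3, -0.1, 1.2, 0.9])
        block = [0, 0, 1, 1]
        R = np.array([[1, rho, 0, 0], [rho, 1, 0, 0],
                      [0, 0, 1, rho], [0, 0, rho, 1.0]])
        Ri = np.linalg.inv(R)
        beta_or = np.linalg.solve(X.T @ Ri @ X, X.T @ Ri @ y)
        cov_or = np.linalg.inv(X.T @ Ri @ X)
        resid = y - X @ beta_or
        s2_or = (resid @ Ri @ resid) / (4 - 2)
        expr = pd.DataFrame([y] * 12, index=[f"g{i}" for i in range(12)],
                            columns=list("abcd"))
        res = fit_de(expr, X, 1, block=block, rho=rho)
        assert res["log2FC"].iloc[0] == pytest.approx(beta_or[1], abs=1e-10)
        assert res["sigma2"].iloc[0] == pytest.approx(s2_or, abs=1e-10)
        assert res["u"].iloc[0] == pytest.approx(np.sqrt(cov_or[1, 1]), abs=1e-10)

    def test_weights_unit_match_unweighted(self, rng):
        expr, X, donors = _cs_cohort(rng, G=40, m=8, k=2, rho=0.2)
        w = pd.DataFrame(np.ones(expr.shape), index=expr.index,
                         columns=expr.columns)
        a = fit_de(expr, X, 1, block=donors, rho=0.2)
        b = fit_de(expr, X, 1, block=donors, rho=0.2, weights=w)
        np.testing.assert_allclose(a["log2FC"], b["log2FC"], atol=1e-10)
        np.testing.assert_allclose(a["se"], b["se"], atol=1e-10)

    def test_se_equals_fc_over_t(self, rng):
        expr, X, donors = _cs_cohort(rng, G=300, m=15, k=2, rho=0.3)
        res = ebayes_moderate(fit_de(expr, X, 1, block=donors, rho=0.3))
        nz = res["t"] != 0
        np.testing.assert_allclose(res.loc[nz, "se"],
                                   (res.loc[nz, "log2FC"] / res.loc[nz, "t"]).abs(),
                                   rtol=1e-10)


class TestModeration:
    def test_equal_variances_collapse_to_pooled(self, rng):
        expr, X, donors = _cs_cohort(rng, G=50, m=10, k=2, rho=0.0)
        res = fit_de(expr, X, 1)
        res["sigma2"] = 0.7
        out = ebayes_moderate(res)
        st = out.attrs["moderation"]
        assert np.isinf(st.d0)
        np.testing.assert_allclose(out["sigma2_posterior"], st.s0_2, rtol=1e-6)

    def test_posterior_between_gene_and_prior(self, rng):
        expr, X, donors = _cs_cohort(rng, G=500, m=12, k=2, rho=0.0)
        out = ebayes_moderate(fit_de(expr, X, 1))
        st = out.attrs["moderation"]
        lo = np.minimum(out["sigma2"], st.s0_2) - 1e-12
        hi = np.maximum(out["sigma2"], st.s0_2) + 1e-12
        assert ((out["sigma2_posterior"] >= lo) & (out["sigma2_posterior"] <= hi)).all()

    def test_prior_parameters_recovered(self):
        rng = np.random.default_rng(7)
        d0, s02, df, G = 4.0, 2.0, 10, 5000
        d0s, s02s = [], []
        for _ in range(25):
            true_var = d0 * s02 / stats.chi2.rvs(d0, size=G, random_state=rng)
            s2 = true_var * stats.chi2.rvs(df, size=G, random_state=rng) / df
            st = estimate_prior(s2, np.full(G, df))
            d0s.append(st.d0)
            s02s.append(st.s0_2)
        assert abs(np.median(d0s) - d0) < 1.5
        assert abs(np.median(s02s) - s02) < 0.4


class TestFdr:
    def test_bh_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        ours = fdr_adjust(p, "BH")["adjusted"]
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_pi0_calibrated_null_and_mixture(self, rng):
        p_null = rng.uniform(size=5000)
        assert fdr_adjust(p_null, "qvalue")["pi0"] == pytest.approx(1.0, abs=0.05)
        p_mix = np.concatenate([
            rng.uniform(size=4000),
            stats.beta.rvs(0.05, 1, size=1000, random_state=rng),
        ])
        assert fdr_adjust(p_mix, "qvalue")["pi0"] == pytest.approx(0.8, abs=0.05)

    def test_qvalues_scale_of_bh_and_monotone(self, rng):
        p = rng.uniform(size=1000) ** 2
        bh = fdr_adjust(p, "BH")["adjusted"]
        out = fdr_adjust(p, "qvalue")
        q, pi0 = out["adjusted"], out["pi0"]
        assert (q <= bh + 1e-12).all()
        assert (q >= pi0 * bh - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (np.diff(bh[order]) >= -1e-12).all()

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, np.nan], "BH")


class TestPipelineBehavior:
    def test_one_sample_per_donor_block_is_noop(self, rng):
        expr, X, _ = _cs_cohort(rng, G=200, m=24, k=1, rho=0.0)
        a = fit_de(expr, X, 1)
        with pytest.warns(UserWarning):
            rho = consensus_correlation(expr, X, np.arange(24))
        b = fit_de(expr, X, 1, block=np.arange(24), rho=rho)
        np.testing.assert_allclose(a["t"], b["t"], atol=1e-10)

    def test_power_increases_with_effect_size(self, rng):
        hits = []
        for lfc in (0.3, 0.8):
            effect = np.zeros(800)
            effect[:200] = lfc
            expr, X, donors = _cs_cohort(rng, G=800, m=30, k=2, rho=0.3,
                                         effect=effect)
            res = ebayes_moderate(fit_de(expr, X, 1, block=donors, rho=0.3))
            q = fdr_adjust(res["p_value"], "BH")["adjusted"]
            hits.append(int((q[:200] < 0.1).sum()))
        assert hits[1] > hits[0]
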