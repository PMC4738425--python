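"""Animal-model REML: closed-form oracles, boundary LRT arithmetic,
parameter recovery, EPVs and the cross-population variance test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wildqg.relmat import RelatednessMatrix, blend_G_with_pedigree, build_G, build_crosspop_G
from wildqg.reml import (ModelSpec, RandomTerm, RemlError,
                         compare_crosspop_variances, compute_EPV, fit_reml,
                         lrt_variance, mixture_pvalue)
from wildqg.synthpop import SimConfig, simulate_traits


def _records(y, individual=None, **cols):
    n = len(y)
    df = pd.DataFrame({"individual_id": individual or [f"i{k}" for k in range(n)],
                       "trait": "t", "value": y})
    for k, v in cols.items():
        df[k] = v
    return df


class TestClosedForms:
    def test_balanced_oneway_matches_anova_reml(self):
        """Balanced one-way layout: REML equals the ANOVA estimators
        sigma_b^2 = (MSB - MSW)/k, sigma_w^2 = MSW."""
        rng = np.random.default_rng(1)
        s, k = 12, 5
        groups = np.repeat([f"g{j}" for j in range(s)], k)
        y = (np.repeat(rng.normal(0, 1.2, s), k)
             + rng.normal(0, 0.8, s * k) + 3.0)
        df = _records(y, group=groups)
        fit = fit_reml(ModelSpec("t", df, random=[RandomTerm("group")]))
        ybar = y.reshape(s, k).mean(axis=1)
        msb = k * np.var(ybar, ddof=1)
        msw = y.reshape(s, k).var(axis=1, ddof=1).mean()
        assert fit.varcomps["group"] == pytest.approx(max((msb - msw) / k, 0),
                                                      rel=1e-3, abs=1e-5)
        assert fit.varcomps["residual"] == pytest.approx(msw, rel=1e-3)

    def test_two_observation_toy_closed_form(self):
        """n=2, intercept only, residual only: REML variance is the
        unbiased sample variance and logL matches the closed form."""
        y = np.array([1.0, 3.0])
        df = _records(y)
        fit = fit_reml(ModelSpec("t", df, random=[]))
        s2 = np.var(y, ddof=1)
        assert fit.varcomps["residual"] == pytest.approx(s2, rel=1e-6)
        n, p = 2, 1
        # log|V| + log|X'V^-1 X| + y'Py = (n-1) log s2 + log n + (n-p)
        expected = -0.5 * ((n - 1) * np.log(s2) + np.log(n) + (n - p))
        assert fit.loglik == pytest.approx(expected, abs=1e-4)

    def test_loglik_invariant_to_fixed_reparameterization(self):
        rng = np.random.default_rng(2)
        n = 80
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.0 + 0.5 * x1 - 0.2 * x2 + rng.normal(size=n)
        df = _records(y, x1=x1, x2=x2)
        df2 = df.copy()
        df2["x1"], df2["x2"] = df["x2"], df["x1"]
        f1 = fit_reml(ModelSpec("t", df, fixed=["x1", "x2"], random=[]))
        f2 = fit_reml(ModelSpec("t", df2, fixed=["x1", "x2"], random=[]))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_aliased_fixed_term_named(self):
        y = np.arange(10.0)
        df = _records(y, a=np.ones(10), b=np.ones(10))
        with pytest.raises(RemlError, match="aliased"):
            fit_reml(ModelSpec("t", df, fixed=["a", "b"], random=[]))


class TestLrt:
    @pytest.mark.parametrize("lrt,expected", [
        (2.706, 0.05), (0.0, 1.0), (7.460, 0.00316), (-1.0, 1.0)])
    def test_mixture_null_pvalues(self, lrt, expected):
        assert mixture_pvalue(lrt) == pytest.approx(expected, rel=5e-3)

    def test_null_genetic_variance_hits_boundary(self, nl_A):
        rng = np.random.default_rng(3)
        ids = nl_A.ids[:120]
        zero = 0
        ests = []
        for seed in range(8):
            y = rng.normal(size=len(ids))
            df = _records(y, individual=list(ids))
            fit = fit_reml(ModelSpec("t", df, random=[
                RandomTerm("individual_id", nl_A.submatrix(ids))]))
            ests.append(fit.h2)
            if fit.h2 < 0.02:
                zero += 1
        # boundary null: the estimate hits 0 in about half the replicates
        assert zero >= 3
        assert np.mean(ests) < 0.15


class TestRecovery:
    def test_h2_recovery_with_A(self, pedigree, panel, nl_ids, nl_A):
        cfg = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                        n_chromosomes=6, h2=0.4, n_causal=120, seed=21)
        ests = []
        for rep in range(12):
            cfg.seed = 300 + rep
            tr = simulate_traits(pedigree, panel, cfg)
            rec = tr.records[tr.records["population"] == "NL"]
            fit = fit_reml(ModelSpec("trait", rec, random=[
                RandomTerm("individual_id", nl_A)]))
            ests.append(fit.h2)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(0.4, abs=2 * se + 0.02)


class TestEPV:
    def test_no_effects_epv_is_zscore(self):
        rng = np.random.default_rng(4)
        y = rng.normal(3.0, 2.0, size=60)
        df = _records(y)
        epv = compute_EPV(ModelSpec("t", df, random=[]))
        z = (y - y.mean()) / np.std(y, ddof=1)
        np.testing.assert_allclose(np.sort(epv.to_numpy()), np.sort(z),
                                   atol=1e-10)

    def test_constant_phenotype_rejected(self):
        df = _records(np.ones(20))
        with pytest.raises(RemlError, match="zero variance"):
            compute_EPV(ModelSpec("t", df, random=[]))

    def test_year_effect_removed_from_epv(self):
        """A strong year effect shrinks between-year EPV variance relative
        to raw means."""
        rng = np.random.default_rng(5)
        n_year, per = 8, 50
        year = np.repeat([f"y{j}" for j in range(n_year)], per)
        year_eff = np.repeat(rng.normal(0, np.sqrt(0.3 / 0.7), n_year), per)
        y = year_eff + rng.normal(size=n_year * per)
        df = _records(y, year=year)
        epv = compute_EPV(ModelSpec("t", df, random=[RandomTerm("year")]))
        raw = pd.Series(y, index=df["individual_id"])
        raw_z = (raw - raw.mean()) / raw.std(ddof=1)
        year_of = dict(zip(df["individual_id"], year))
        by_year_raw = raw_z.groupby(year_of).mean().var(ddof=1)
        by_year_epv = epv.groupby(year_of).mean().var(ddof=1)
        assert by_year_epv < 0.5 * by_year_raw

    def test_relatedness_term_rejected(self, nl_A):
        df = _records(np.arange(10.0), individual=list(nl_A.ids[:10]))
        with pytest.raises(RemlError, match="relatedness"):
            compute_EPV(ModelSpec("t", df, random=[
                RandomTerm("individual_id", nl_A.submatrix(nl_A.ids[:10]))]))


@pytest.fixture(scope="module")
def crosspop_setup(panel):
    return build_crosspop_G(panel, blend=False)


class TestCrosspop:

    def test_two_copies_of_one_population_give_null_lrt(self, nl_A):
        """Mirrored relatedness blocks + identical phenotypes force the two
        population variances to the same optimum: LRT ~ 0."""
        rng = np.random.default_rng(6)
        ids = nl_A.ids[:100]
        K = nl_A.align(ids)
        big = np.block([[K, K], [K, K]])
        ids2 = [f"{i}_copy" for i in ids]
        Gx = RelatednessMatrix(big, list(ids) + ids2, "G_crosspop")
        w, Q = np.linalg.eigh(K)
        g = Q @ (np.sqrt(np.clip(w, 0, None)) * rng.normal(size=len(ids)))
        y = 0.6 * g + rng.normal(size=len(ids))
        df = pd.concat([
            _records(y, individual=list(ids), population="NL"),
            _records(y, individual=ids2, population="UK")], ignore_index=True)
        out = compare_crosspop_variances("t", df, Gx)
        assert out["lrt"] == pytest.approx(0.0, abs=0.2)
        assert out["p"] > 0.5

    def test_unequal_variances_detected(self, pedigree, panel, crosspop_setup):
        """V_A ratio 4:1 between populations is detected in most replicates."""
        cfg = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                        n_chromosomes=6, h2=0.6, n_causal=120, seed=30)
        cfg2 = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                         n_chromosomes=6, h2=0.15, n_causal=120, seed=30)
        hits = 0
        for rep in range(4):
            cfg.seed = 400 + rep
            cfg2.seed = 400 + rep
            tr_hi = simulate_traits(pedigree, panel, cfg)
            tr_lo = simulate_traits(pedigree, panel, cfg2)
            rec = pd.concat([
                tr_hi.records[tr_hi.records["population"] == "NL"],
                tr_lo.records[tr_lo.records["population"] == "UK"]],
                ignore_index=True)
            out = compare_crosspop_variances("trait", rec, crosspop_setup)
            if out["p"] < 0.05:
                hits += 1
        assert hits >= 3


def test_grad_norm_small_at_convergence(nl_A, traits):
    rec = traits.records[traits.records["population"] == "NL"]
    fit = fit_reml(ModelSpec("trait", rec, random=[
        RandomTerm("individual_id", nl_A)]))
    assert fit.converged
    assert fit.grad_norm < 1e-2  # soft tolerance, logged on the fit
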