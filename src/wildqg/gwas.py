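"""Kinship-corrected genome-wide association on expected phenotypic values.

The null polygenic model EPV ~ N(X b, s2_g K + s2_e I) is fitted once; each
SNP is then tested with the score statistic

    T = (g' V^-1 r)^2 / (g' V^-1 g),   r = y - X b_hat,

with g the centred dosage vector, referred to chi-square(1).  Multiple
testing uses an effective-number-of-tests reduction of the Bonferroni
threshold based on local linkage disequilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relmat import RelatednessMatrix
from .reml import _fit_two_component

_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)


@dataclass
class GwasResult:
    table: pd.DataFrame  # snp, chrom, cM, beta, score, p
    lambda_gc: float
    k_eff: float | None = None
    thresholds: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _null_covariance(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    fit = _fit_two_component(y, X, K)
    s2g = fit.varcomps["genetic"]
    s2e = fit.varcomps["residual"]
    V = s2g * K + s2e * np.eye(len(y))
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    resid = y - X @ beta
    return fit, Vinv, resid


def score_test_scan(epv: pd.Series, panel, kinship: RelatednessMatrix,
                    covariates: np.ndarray | None = None) -> GwasResult:
    """Single-SNP score tests of the EPV against every polymorphic SNP."""
    ids = [i for i in epv.index if i in set(kinship.ids)]
    y = epv.loc[ids].to_numpy(dtype=float)
    K = kinship.align(ids)
    X = np.ones((len(y), 1))
    if covariates is not None:
        X = np.column_stack([X, covariates])
    fit, Vinv, resid = _null_covariance(y, X, K)
    rows_idx = panel.rows(ids)
    D = panel.dosages[rows_idx]
    p_hat = np.nanmean(D, axis=0) / 2.0
    Vr = Vinv @ resid
    rows, skipped = [], []
    G = np.where(np.isnan(D), 0.0, D - 2.0 * p_hat)  # mean-centred, missing->0
    num = G.T @ Vr
    VG = Vinv @ G
    den = np.einsum("ij,ij->j", G, VG)
    snps = panel.snp_map
    for j in range(panel.n_snps):
        if p_hat[j] <= 0 or p_hat[j] >= 1 or den[j] <= 0:
            skipped.append(str(snps.iloc[j]["snp"]))
            continue
        T = num[j] ** 2 / den[j]
        beta = num[j] / den[j]
        rows.append((snps.iloc[j]["snp"], snps.iloc[j]["chrom"],
                     float(snps.iloc[j]["cM"]), float(beta), float(T),
                     float(stats.chi2.sf(T, 1))))
    table = pd.DataFrame(rows, columns=["snp", "chrom", "cM", "beta", "score", "p"])
    lam = float(np.median(table["score"]) / _CHI2_MEDIAN_1DF) if len(table) else np.nan
    return GwasResult(table=table, lambda_gc=lam, skipped=skipped,
                      thresholds={"nominal": 0.05})


def naive_scan(epv: pd.Series, panel) -> GwasResult:
    """Kinship-free single-SNP regression — the uncorrected comparator."""
    ids = list(epv.index)
    y = epv.loc[ids].to_numpy(dtype=float)
    rows_idx = panel.rows(ids)
    D = panel.dosages[rows_idx]
    p_hat = np.nanmean(D, axis=0) / 2.0
    G = np.where(np.isnan(D), 0.0, D - 2.0 * p_hat)
    r = y - y.mean()
    num = G.T @ r
    den = np.einsum("ij,ij->j", G, G) * np.var(y)
    rows = []
    snps = panel.snp_map
    for j in range(panel.n_snps):
        if p_hat[j] <= 0 or p_hat[j] >= 1 or den[j] <= 0:
            continue
        T = num[j] ** 2 / den[j] * len(y) / max(len(y) - 2, 1)
        rows.append((snps.iloc[j]["snp"], snps.iloc[j]["chrom"],
                     float(snps.iloc[j]["cM"]), float(num[j] / den[j]),
                     float(T), float(stats.chi2.sf(T, 1))))
    table = pd.DataFrame(rows, columns=["snp", "chrom", "cM", "beta", "score", "p"])
    lam = float(np.median(table["score"]) / _CHI2_MEDIAN_1DF) if len(table) else np.nan
    return GwasResult(table=table, lambda_gc=lam)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def effective_tests(panel, window: int = 50) -> float:
    """Effective number of independent tests from local LD.

    K_eff = sum over SNPs of sqrt(1 - max r^2 with preceding SNPs in a
    sliding window on the same chromosome); the first SNP of each chromosome
    contributes 1.  Never exceeds the SNP count.
    """
    if panel.n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    d = panel.dosages
    k_eff = 0.0
    for _, grp in panel.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for a, j in enumerate(idx):
            if a == 0:
                k_eff += 1.0
                continue
            lo = max(0, a - window)
            best = 0.0
            xj = d[:, j]
            for i in idx[lo:a]:
                xi = d[:, i]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < 3 or np.var(xi[ok]) == 0 or np.var(xj[ok]) == 0:
                    continue
                r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                best = max(best, r * r)
            k_eff += np.sqrt(max(1.0 - best, 0.0))
    return float(min(k_eff, panel.n_snps))


def effective_tests_eigen(panel) -> float:
    """Eigenvalue-based effective-test count (cross-check oracle):
    K_eff = sum_i min(1, lambda_i) over eigenvalues of the SNP correlation
    matrix, counting each perfectly correlated block once."""
    d = panel.dosages
    ok = np.all(~np.isnan(d), axis=0)
    x = d[:, ok]
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    c = np.corrcoef(x, rowvar=False)
    w = np.linalg.eigvalsh(c)
    return float(np.sum(np.minimum(np.clip(w, 0, None), 1.0)))


def bonferroni_threshold(alpha: float, k_eff: float) -> float:
    if k_eff < 1:
        raise ValueError("k_eff must be >= 1")
    return alpha / k_eff


# ---------------------------------------------------------------------------
# merged-population scan and cross-population comparisons
# ---------------------------------------------------------------------------

def merged_population_scan(epvs: dict[str, pd.Series], panel,
                           kinship: RelatednessMatrix,
                           n_pcs: int = 10) -> GwasResult:
    """One scan over both populations merged.

    EPVs (already standardized within population) are concatenated; the null
    model adds a population indicator and the top kinship eigenvectors as
    fixed covariates.
    """
    ids, y, pop = [], [], []
    for pname, s in sorted(epvs.items()):
        ids.extend(list(s.index))
        y.extend(list(s.to_numpy()))
        pop.extend([pname] * len(s))
    y = np.asarray(y, dtype=float)
    K = kinship.align(ids)
    w, Q = np.linalg.eigh(K)
    order = np.argsort(w)[::-1]
    nontrivial = [k for k in order if w[k] > 1e-8]
    use = nontrivial[:n_pcs]
    pcs = Q[:, use]
    pop_ind = (np.asarray(pop) == sorted(set(pop))[0]).astype(float)
    covs = np.column_stack([pop_ind, pcs])
    sub = pd.Series(y, index=ids)
    res = score_test_scan(sub, panel, kinship.submatrix(ids), covariates=covs)
    res.thresholds["n_pcs_used"] = len(use)
    return res


def effect_size_correlation(result_a: GwasResult, result_b: GwasResult,
                            n_perm: int = 10_000, seed: int = 0
                            ) -> dict:
    """Pearson correlation of absolute SNP effect sizes between populations,
    permutation p-value (one-sided upper, plus-one rule)."""
    a = result_a.table.set_index("snp")["beta"].abs()
    b = result_b.table.set_index("snp")["beta"].abs()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared SNPs")
    x = a.loc[shared].to_numpy()
    yv = b.loc[shared].to_numpy()
    r_obs = float(np.corrcoef(x, yv)[0, 1])
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(yc)
        if (xc @ perm) / denom >= r_obs - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"r": r_obs, "p": float(p), "n_snps": int(len(shared)),
            "n_perm": n_perm}
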