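"""Cross-population and cross-method agreement tests.

Covers: chromosome-block permutation correlation between two QTL scans,
interpolation of scan LOD scores at SNP map positions, chi-square/Fisher
overlap tests between nominally significant GWAS, QTL and chromosome-
partitioning results, a shared-significant-chromosome binomial test, and the
between-population correlation of posterior SNP counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qtl import LOD_SCALE, ScanResult
from .reml import mixture_pvalue


@dataclass
class ConcordanceReport:
    test: str
    statistic: float
    p: float
    null: str
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scan-versus-scan correlation with chromosome-block permutation
# ---------------------------------------------------------------------------

def _paired_stats(scan_a: pd.DataFrame, scan_b: pd.DataFrame,
                  chrom_order_b: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pair per-position statistics chromosome-slot by chromosome-slot,
    in map order, truncating the longer block."""
    xa, xb = [], []
    chroms_a = list(dict.fromkeys(scan_a["chrom"]))
    for slot, ca in enumerate(chroms_a):
        cb = chrom_order_b[slot % len(chrom_order_b)]
        va = scan_a.loc[scan_a["chrom"] == ca, "lod"].to_numpy()
        vb = scan_b.loc[scan_b["chrom"] == cb, "lod"].to_numpy()
        m = min(len(va), len(vb))
        xa.append(va[:m])
        xb.append(vb[:m])
    return np.concatenate(xa), np.concatenate(xb)


def scan_correlation_permutation(scan_a, scan_b, n_perm: int = 1000,
                                 seed: int = 0) -> ConcordanceReport:
    """Correlation between two genome scans with a whole-chromosome
    permutation null: chromosome blocks of scan B are shuffled across the
    chromosome slots of scan A, preserving within-chromosome autocorrelation.
    """
    ta = scan_a.table if isinstance(scan_a, ScanResult) else scan_a
    tb = scan_b.table if isinstance(scan_b, ScanResult) else scan_b
    chroms_b = list(dict.fromkeys(tb["chrom"]))
    if len(chroms_b) < 2:
        raise ValueError("need at least 2 chromosomes to permute")
    xa, xb = _paired_stats(ta, tb, chroms_b)
    r_obs = float(np.corrcoef(xa, xb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    null_rs = []
    for _ in range(n_perm):
        perm = list(rng.permutation(chroms_b))
        pa, pb = _paired_stats(ta, tb, perm)
        r = np.corrcoef(pa, pb)[0, 1]
        null_rs.append(r)
        if r >= r_obs - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ConcordanceReport(
        test="scan_correlation_permutation", statistic=r_obs, p=float(p),
        null=f"chromosome-block permutation, {n_perm} draws",
        details={"null_r": np.asarray(null_rs), "n_perm": n_perm})


# ---------------------------------------------------------------------------
# LOD interpolation at SNP positions
# ---------------------------------------------------------------------------

def interpolate_lod_at_snps(scan, panel) -> pd.DataFrame:
    """Linear interpolation of grid LOD scores at each SNP's cM position;
    p-values from the mixture null of the implied LRT.  SNPs beyond the grid
    take the nearest endpoint value and are flagged."""
    tab = scan.table if isinstance(scan, ScanResult) else scan
    rows = []
    for _, snp in panel.snp_map.iterrows():
        grp = tab[tab["chrom"] == snp["chrom"]]
        if grp.empty:
            continue
        pos = grp["cM"].to_numpy()
        lod = grp["lod"].to_numpy()
        x = float(snp["cM"])
        flagged = x < pos.min() - 1e-9 or x > pos.max() + 1e-9
        val = float(np.interp(x, pos, lod))
        rows.append((snp["snp"], snp["chrom"], x, val,
                     mixture_pvalue(val * LOD_SCALE), flagged))
    return pd.DataFrame(rows, columns=["snp", "chrom", "cM", "lod", "p",
                                       "extrapolated"])


# ---------------------------------------------------------------------------
# overlap tests
# ---------------------------------------------------------------------------

def gwas_qtl_overlap(gwas_p: pd.Series, qtl_p: pd.Series,
                     alpha: float = 0.05) -> ConcordanceReport:
    """2x2 chi-square test of independence between nominal significance in
    the GWAS and in the interpolated QTL scan; switches to Fisher's exact
    test when an expected cell drops below 5."""
    shared = gwas_p.index.intersection(qtl_p.index)
    a = (gwas_p.loc[shared] < alpha).to_numpy()
    b = (qtl_p.loc[shared] < alpha).to_numpy()
    table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                      [np.sum(~a & b), np.sum(~a & ~b)]], dtype=float)
    margins_ok = table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0
    if not margins_ok:
        return ConcordanceReport(
            test="gwas_qtl_overlap", statistic=np.nan, p=np.nan,
            null="degenerate margin; test skipped",
            details={"table": table})
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 5:
        odds, p = stats.fisher_exact(table.astype(int))
        return ConcordanceReport(
            test="gwas_qtl_overlap", statistic=float(odds), p=float(p),
            null="Fisher exact (small expected cell)",
            details={"table": table, "mode": "fisher"})
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ConcordanceReport(
        test="gwas_qtl_overlap", statistic=float(chi2), p=float(p),
        null="chi-square independence", details={"table": table,
                                                 "mode": "chi2"})


def partition_qtl_fisher(partition_flags: pd.Series,
                         qtl_flags: pd.Series) -> ConcordanceReport:
    """Fisher's exact test (two-tailed) of overlap between chromosome sets
    significant in the partitioning analysis and those carrying a nominally
    significant QTL peak."""
    shared = partition_flags.index.intersection(qtl_flags.index)
    a = partition_flags.loc[shared].astype(bool).to_numpy()
    b = qtl_flags.loc[shared].astype(bool).to_numpy()
    table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                      [np.sum(~a & b), np.sum(~a & ~b)]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ConcordanceReport(test="partition_qtl_fisher", statistic=float(odds),
                             p=float(p), null="hypergeometric (Fisher exact)",
                             details={"table": table})


def shared_chromosome_binomial(n_a: int, n_b: int, n_sets: int,
                               n_shared: int, mode: str = "binomial"
                               ) -> ConcordanceReport:
    """P(>= n_shared chromosome sets significant in both populations).

    ``binomial`` mode: X ~ Binomial(n_sets, (n_a/n_sets)(n_b/n_sets));
    ``hypergeometric`` mode: exact overlap distribution for fixed margins.
    """
    if n_a > n_sets or n_b > n_sets:
        raise ValueError("counts exceed number of sets")
    if mode == "binomial":
        q = (n_a / n_sets) * (n_b / n_sets)
        p = float(stats.binom.sf(n_shared - 1, n_sets, q))
        null = f"Binomial({n_sets}, {q:.4f})"
    elif mode == "hypergeometric":
        p = float(stats.hypergeom.sf(n_shared - 1, n_sets, n_a, n_b))
        null = f"Hypergeometric(N={n_sets}, K={n_a}, n={n_b})"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ConcordanceReport(test="shared_chromosome_binomial",
                             statistic=float(n_shared), p=p, null=null,
                             details={"n_a": n_a, "n_b": n_b,
                                      "n_sets": n_sets, "mode": mode})


def nsnp_correlation(medians_a, medians_b, sided: str = "one"
                     ) -> ConcordanceReport:
    """Pearson correlation between per-trait posterior median SNP counts in
    two populations, t-test on n-2 df (one- or two-sided)."""
    x = np.asarray(medians_a, dtype=float)
    y = np.asarray(medians_b, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired traits")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in median vector")
    r, p_two = stats.pearsonr(x, y)
    if sided == "one":
        p = p_two / 2.0 if r > 0 else 1.0 - p_two / 2.0
    elif sided == "two":
        p = p_two
    else:
        raise ValueError("sided must be 'one' or 'two'")
    return ConcordanceReport(test="nsnp_correlation", statistic=float(r),
                             p=float(p), null=f"t({len(x) - 2}df), {sided}-sided",
                             details={"r": float(r), "p_two_sided": float(p_two),
                                      "n_traits": int(len(x))})
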