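"""Variance-components QTL linkage mapping.

Two-step procedure: (1) expected pairwise identity-by-descent (IBD) matrices
are estimated on a cM grid from pedigree + marker data by Monte-Carlo sampling
of segregation indicators conditioned on the flanking markers; (2) at each
grid position a polygenic + QTL mixed model is tested against the polygenic
model with a boundary (50:50 mixture) likelihood-ratio test, reported as a
LOD score (LRT / 2 ln 10).

Genome-wide thresholds follow the dense-map expected-exceedance argument: a
LOD threshold t is chosen so that the expected number of chance exceedance
regions per scan, mu(t) = [C + 2 rho G (2 ln 10) t] * alpha(t), hits a target
(1 for "suggestive", 0.05 for "significant"), where C is the chromosome
count, G the map length in morgans and alpha(t) the pointwise mixture-null
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .reml import RandomTerm, ModelSpec, build_design, fit_components, mixture_pvalue, RemlError, _term_component
from .relmat import RelatednessMatrix
from .synthpop import GenotypePanel, Pedigree, _haldane_r

LOD_SCALE = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSpec:
    n_chromosomes: int
    map_length_morgans: float
    rho: float = 1.0
    suggestive_target: float = 1.0
    significant_target: float = 0.05

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.map_length_morgans <= 0 or self.rho <= 0:
            raise ValueError("invalid threshold specification")


def _exceedance_rate(t: float, spec: ThresholdSpec) -> float:
    alpha = 0.5 * stats.chi2.sf(LOD_SCALE * t, 1)
    return (spec.n_chromosomes
            + 2.0 * spec.rho * spec.map_length_morgans * LOD_SCALE * t) * alpha


def lod_thresholds(spec: ThresholdSpec) -> dict[str, float]:
    """Nominal / suggestive / significant LOD thresholds, 3-decimal display.

    Nominal solves 0.5 P(chi2_1 >= q) = 0.05; the genome-wide levels solve
    mu(t) = target by bisection.
    """
    q = stats.chi2.isf(0.1, 1)  # 0.5 * sf(q) = 0.05
    nominal = q / LOD_SCALE
    out = {"nominal": round(float(nominal), 3)}
    for name, target in (("suggestive", spec.suggestive_target),
                         ("significant", spec.significant_target)):
        f = lambda t: _exceedance_rate(t, spec) - target  # noqa: E731
        if f(1e-9) < 0 or f(100.0) > 0:
            raise ValueError(f"no root in (0, 100) for target {target}")
        out[name] = round(float(optimize.brentq(f, 1e-9, 100.0, xtol=1e-10)), 3)
    return out


# ---------------------------------------------------------------------------
# IBD machinery: segregation-indicator sampling conditioned on markers
# ---------------------------------------------------------------------------

@dataclass
class IbdGrid:
    positions: pd.DataFrame  # columns chrom, cM
    matrices: list[np.ndarray]  # per position, relationship-scale in [0, 2]
    ids: list[str]
    diagnostics: dict = field(default_factory=dict)

    def matrix_at(self, k: int) -> RelatednessMatrix:
        return RelatednessMatrix(self.matrices[k], list(self.ids), "IBD",
                                 {"chrom": self.positions.iloc[k]["chrom"],
                                  "cM": float(self.positions.iloc[k]["cM"])})


class _PedigreeIndex:
    """Meiosis bookkeeping: founders carry gene labels (2f, 2f+1); each
    non-founder has one meiosis per known parent."""

    def __init__(self, pedigree: Pedigree):
        self.order = pedigree.topological_order()
        self.row = {i: k for k, i in enumerate(self.order)}
        self.parents = {i: pedigree.parents_of(i) for i in self.order}
        self.founder_gene = {}
        self.meioses = []  # (child_row, slot, parent_row)
        n_f = 0
        for i in self.order:
            s, d = self.parents[i]
            k = self.row[i]
            for slot, p in enumerate((s, d)):
                if p is None:
                    self.founder_gene[(k, slot)] = n_f
                    n_f += 1
                else:
                    self.meioses.append((k, slot, self.row[p]))
        self.n_founder_genes = n_f
        self.n_meioses = len(self.meioses)

    def drop_labels(self, seg: np.ndarray) -> np.ndarray:
        """Propagate founder-gene labels; seg is (n_particles, n_meioses)."""
        P = seg.shape[0]
        n = len(self.order)
        lab = np.zeros((P, n, 2), dtype=np.int32)
        for (k, slot), g in self.founder_gene.items():
            lab[:, k, slot] = g
        for m, (k, slot, prow) in enumerate(self.meioses):
            pick = seg[:, m]
            lab[:, k, slot] = lab[np.arange(P), prow, pick]
        return lab


def _categorical_rows(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one column index per row of a non-negative weight matrix."""
    totals = weights.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    cdf = np.cumsum(weights / safe, axis=1)
    u = rng.random((weights.shape[0], 1))
    return (u > cdf[:, :-1]).sum(axis=1)


class _FlankSampler:
    """Sequential importance sampler for phased descent at two flanking
    markers.

    Individuals are processed parents-first.  A founder's phased alleles are
    sampled from its observed dosages (phase uniform, missing alleles from
    the population frequency).  A non-founder's two meioses are sampled
    jointly from their exact local conditional given the parents' phased
    haplotypes: each of the 16 segregation combinations is weighted by its
    Haldane prior times the indicator that the implied dosages match the
    child's observed genotypes.  The particle weight accumulates the local
    predictive probabilities, so expectations under the weighted particles
    are unbiased for the flanking-marker-conditioned posterior.

    State per particle: allele values ``alle[(P, n, slot, marker)]``,
    founder-gene labels ``lab[(P, n, slot, marker)]`` and sampled segregation
    indicators ``seg[(P, n_meioses, marker)]``.
    """

    def __init__(self, pidx: "_PedigreeIndex", dosages: np.ndarray,
                 freqs: np.ndarray, n_particles: int,
                 rng: np.random.Generator):
        self.pidx = pidx
        self.P = n_particles
        self.rng = rng
        self.dos = dosages  # (n, 2) at the two flanking markers; nan = missing
        self.freqs = freqs  # per-marker counted-allele frequency (length 2)

    def run(self, r_lr: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pidx, P, rng = self.pidx, self.P, self.rng
        n = len(pidx.order)
        alle = np.zeros((P, n, 2, 2), dtype=np.int8)
        lab = np.zeros((P, n, 2, 2), dtype=np.int32)
        seg = np.zeros((P, pidx.n_meioses, 2), dtype=np.int8)
        logw = np.zeros(P)
        # segregation prior over (sL, sR): stay 1-r, switch r
        prior = np.array([[0.5 * (1 - r_lr), 0.5 * r_lr],
                          [0.5 * r_lr, 0.5 * (1 - r_lr)]])
        meiosis_of = {}
        for m, (k, slot, prow) in enumerate(pidx.meioses):
            meiosis_of[(k, slot)] = (m, prow)
        for i in pidx.order:
            k = pidx.row[i]
            founder_slots = [s for s in (0, 1) if (k, s) in pidx.founder_gene]
            for s in founder_slots:
                lab[:, k, s, :] = pidx.founder_gene[(k, s)]
            if len(founder_slots) == 2:
                self._sample_founder(k, alle, logw)
                continue
            # meiosis slots (possibly one founder-side slot for half-known)
            if founder_slots:
                s = founder_slots[0]
                for mk in range(2):
                    alle[:, k, s, mk] = rng.random(P) < self.freqs[mk]
            slots = [s for s in (0, 1) if (k, s) in meiosis_of]
            # enumerate joint segregation choices of this child's meioses
            n_c = 4 ** len(slots)
            w = np.ones((P, n_c))
            state = []
            for c in range(n_c):
                cc = c
                allele_sum = np.zeros((P, 2), dtype=np.int8)
                pr = np.ones(P)
                picks = []
                for s in slots:
                    m, prow = meiosis_of[(k, s)]
                    sl, sr = (cc % 4) // 2, cc % 2
                    cc //= 4
                    pr = pr * prior[sl, sr]
                    allele_sum[:, 0] += alle[:, prow, sl, 0]
                    allele_sum[:, 1] += alle[:, prow, sr, 1]
                    picks.append((m, sl, sr))
                if founder_slots:
                    s = founder_slots[0]
                    allele_sum[:, 0] += alle[:, k, s, 0]
                    allele_sum[:, 1] += alle[:, k, s, 1]
                for mk in range(2):
                    g = self.dos[k, mk]
                    if not np.isnan(g):
                        pr = pr * (allele_sum[:, mk] == int(g))
                w[:, c] = pr
                state.append(picks)
            total = w.sum(axis=1)
            logw += np.where(total > 0, np.log(np.maximum(total, 1e-300)), -np.inf)
            choice = _categorical_rows(w, rng)
            for s_i, s in enumerate(slots):
                m, prow = meiosis_of[(k, s)]
                sl_arr = np.array([state[c][s_i][1] for c in range(n_c)],
                                  dtype=np.int8)[choice]
                sr_arr = np.array([state[c][s_i][2] for c in range(n_c)],
                                  dtype=np.int8)[choice]
                seg[:, m, 0] = sl_arr
                seg[:, m, 1] = sr_arr
                rowsP = np.arange(P)
                alle[:, k, s, 0] = alle[rowsP, prow, sl_arr, 0]
                alle[:, k, s, 1] = alle[rowsP, prow, sr_arr, 1]
                lab[:, k, s, 0] = lab[rowsP, prow, sl_arr, 0]
                lab[:, k, s, 1] = lab[rowsP, prow, sr_arr, 1]
        logw -= logw.max() if np.isfinite(logw.max()) else 0.0
        wts = np.exp(logw)
        s = wts.sum()
        wts = wts / s if s > 0 else np.full(P, 1.0 / P)
        return seg, lab, wts

    def _sample_founder(self, k: int, alle: np.ndarray, logw: np.ndarray):
        """Phased founder alleles from observed dosages; phase uniform."""
        P, rng = self.P, self.rng
        for mk in range(2):
            g = self.dos[k, mk]
            if np.isnan(g):
                alle[:, k, 0, mk] = rng.random(P) < self.freqs[mk]
                alle[:, k, 1, mk] = rng.random(P) < self.freqs[mk]
            elif g == 1:
                first = (rng.random(P) < 0.5).astype(np.int8)
                alle[:, k, 0, mk] = first
                alle[:, k, 1, mk] = 1 - first
            else:
                alle[:, k, :, mk] = 1 if g == 2 else 0


def _sharing_accumulate(labels: np.ndarray, weights: np.ndarray,
                        out: np.ndarray) -> None:
    """Add weighted relationship-scale sharing (0.5 * matching label count)."""
    P = labels.shape[0]
    chunk = max(1, int(2e7 // (labels.shape[1] ** 2)))
    for s in range(0, P, chunk):
        lab = labels[s:s + chunk]
        w = weights[s:s + chunk, None, None]
        acc = np.zeros((lab.shape[0], lab.shape[1], lab.shape[1]), dtype=np.float32)
        for a in range(2):
            for b in range(2):
                acc += (lab[:, :, None, a] == lab[:, None, :, b])
        out += np.einsum("pij->ij", 0.5 * acc * w)


def estimate_ibd_grid(pedigree: Pedigree, panel: GenotypePanel,
                      grid_step_cM: float = 5.0, n_samples: int = 500,
                      seed: int = 0, chromosomes: list[str] | None = None,
                      founder_freq_pop: str | None = None) -> IbdGrid:
    """Expected pairwise IBD matrices on a cM grid.

    For each inter-marker interval, segregation indicators at the two flanking
    markers are importance-sampled (prior proposal, genotype-likelihood
    weights); indicators at each interior grid position are then drawn from
    the exact bridge distribution given the flanks.  Grid positions at a
    marker condition on that marker directly.  Far from any marker the
    weights become uninformative and the expectation reverts to the pedigree
    value.
    """
    rng = np.random.default_rng(seed)
    pidx = _PedigreeIndex(pedigree)
    ids = pidx.order
    rows = np.array([panel._row[i] for i in ids])
    dos = panel.dosages[rows]
    if founder_freq_pop is not None and panel.founder_freqs is not None:
        freqs_all = panel.founder_freqs[founder_freq_pop]
    else:
        with np.errstate(invalid="ignore"):
            counts = np.sum(~np.isnan(panel.dosages), axis=0)
            sums = np.nansum(panel.dosages, axis=0)
            freqs_all = np.where(counts > 0, sums / np.maximum(2 * counts, 1), 0.5)
    n = len(ids)
    n_m = pidx.n_meioses
    positions = []
    matrices = []
    ess_log = []
    chrom_list = chromosomes or list(panel.snp_map["chrom"].unique())
    for chrom in chrom_list:
        sub = panel.snp_map[panel.snp_map["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no markers on chromosome {chrom}")
        cm = sub["cM"].to_numpy()
        last = float(cm.max())
        grid = list(np.arange(0.0, last + 1e-9, grid_step_cM))
        if grid[-1] < last - 1e-9:
            grid.append(last)
        marker_idx = sub.index.to_numpy()
        if n_m == 0:
            founder_m = np.diag(np.ones(n))
            for x in grid:
                positions.append((chrom, float(x)))
                matrices.append(founder_m.copy())
            continue
        # group grid positions by flanking-marker interval; one sampler run
        # per interval, bridge sampling per position
        by_interval: dict[tuple[int, int], list[float]] = {}
        for x in grid:
            left = np.where(cm <= x + 1e-9)[0]
            right = np.where(cm >= x - 1e-9)[0]
            li = int(left[-1]) if len(left) else int(right[0])
            ri = int(right[0]) if len(right) else int(left[-1])
            if abs(cm[li] - x) < 1e-9:  # ties at a marker resolve to it
                ri = li
            by_interval.setdefault((li, ri), []).append(float(x))
        for (li, ri), xs in by_interval.items():
            cols = (marker_idx[li], marker_idx[ri])
            d2 = np.column_stack([dos[:, cols[0]], dos[:, cols[1]]])
            f2 = np.array([freqs_all[cols[0]], freqs_all[cols[1]]])
            r_lr = float(_haldane_r(abs(cm[ri] - cm[li])))
            sampler = _FlankSampler(pidx, d2, f2, n_samples, rng)
            seg, lab, wts = sampler.run(r_lr)
            ess_log.append(float(1.0 / np.sum(wts ** 2)))
            for x in xs:
                r_lx = float(_haldane_r(abs(x - cm[li])))
                r_xr = float(_haldane_r(abs(cm[ri] - x)))
                # bridge: P(s_x | s_L, s_R) under Haldane transitions
                sL = seg[:, :, 0]
                sR = seg[:, :, 1]
                p_move1 = np.where(sL == 0, r_lx, 1 - r_lx)  # P(s_x = 1 | sL)
                p_stay1 = np.where(sR == 1, 1 - r_xr, r_xr)  # P(sR | s_x = 1)
                p_move0 = np.where(sL == 0, 1 - r_lx, r_lx)
                p_stay0 = np.where(sR == 1, r_xr, 1 - r_xr)
                num1 = p_move1 * p_stay1
                num0 = p_move0 * p_stay0
                p1 = num1 / np.maximum(num1 + num0, 1e-300)
                seg_x = (rng.random(sL.shape) < p1).astype(np.int8)
                labels_x = pidx.drop_labels(seg_x)
                out = np.zeros((n, n), dtype=np.float64)
                _sharing_accumulate(labels_x, wts, out)
                out = 0.5 * (out + out.T)
                positions.append((chrom, float(x)))
                matrices.append(out)
    order = np.lexsort((pd.DataFrame(positions)[1],
                        pd.factorize(pd.DataFrame(positions)[0])[0]))
    positions = [positions[k] for k in order]
    matrices = [matrices[k] for k in order]
    pos = pd.DataFrame(positions, columns=["chrom", "cM"])
    return IbdGrid(positions=pos, matrices=matrices, ids=list(ids),
                   diagnostics={"mean_ess": float(np.mean(ess_log)) if ess_log else np.nan,
                                "n_samples": n_samples})


def prune_by_ld(panel: GenotypePanel, r2_cap: float = 0.95,
                window: int = 50) -> np.ndarray:
    """Indices of markers kept after dropping the later member of any pair
    with r^2 above the cap (within a sliding window, per chromosome)."""
    keep = np.ones(panel.n_snps, dtype=bool)
    d = panel.dosages
    for _, grp in panel.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for a, j in enumerate(idx):
            if not keep[j]:
                continue
            lo = max(0, a - window)
            for i in idx[lo:a]:
                if not keep[i]:
                    continue
                xi, xj = d[:, i], d[:, j]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < 3 or np.var(xi[ok]) == 0 or np.var(xj[ok]) == 0:
                    continue
                r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                if r * r > r2_cap:
                    keep[j] = False
                    break
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    table: pd.DataFrame  # chrom, cM, lrt, lod, p, qtl_var_prop
    thresholds: dict[str, float]
    null_loglik: float

    def peaks_above(self, level: str) -> pd.DataFrame:
        t = self.thresholds[level]
        return self.table[self.table["lod"] >= t]

    def n_exceedance_clusters(self, level: str) -> int:
        """Count runs of consecutive grid positions above the threshold."""
        t = self.thresholds[level]
        count = 0
        for _, grp in self.table.groupby("chrom", sort=False):
            above = (grp["lod"] >= t).to_numpy()
            count += int(np.sum(above[1:] & ~above[:-1]) + (above[0] if len(above) else 0))
        return count


def qtl_scan(trait: str, data, ibd: IbdGrid, polygenic: RelatednessMatrix,
             fixed: list[str] = (), random: list[RandomTerm] = (),
             thresholds: dict[str, float] | None = None,
             max_iter: int = 100) -> ScanResult:
    """Polygenic vs polygenic + QTL likelihood-ratio scan over the IBD grid."""
    spec = ModelSpec(trait=trait, data=data, fixed=list(fixed), random=[])
    df = spec.records()
    df = df[df["individual_id"].isin(ibd.ids)].reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    X, _ = build_design(df, list(fixed))
    Cpoly, _, _ = _term_component(df, RandomTerm("individual_id", polygenic))
    extra = [(_term_component(df, t)[0], t.label()) for t in random]
    comps0 = [Cpoly] + [c for c, _ in extra] + [np.eye(len(y))]
    names0 = ["polygenic"] + [nm for _, nm in extra] + ["residual"]
    null = fit_components(y, X, comps0, names=names0, max_iter=max_iter)
    if thresholds is None:
        lengths = ibd.positions.groupby("chrom")["cM"].max()
        spec_t = ThresholdSpec(n_chromosomes=len(lengths),
                               map_length_morgans=float(lengths.sum()) / 100.0)
        thresholds = lod_thresholds(spec_t)
    theta0 = null.extras["theta"]
    rows = []
    idx_map = {i: k for k, i in enumerate(ibd.ids)}
    obs_rows = np.array([idx_map[i] for i in df["individual_id"].astype(str)])
    for k in range(len(ibd.positions)):
        Kq = ibd.matrices[k][np.ix_(obs_rows, obs_rows)]
        start = np.concatenate([[max(theta0[0] * 0.7, 1e-6)],
                                [theta0[0] * 0.3], theta0[1:]])
        try:
            full = fit_components(
                y, X, [Cpoly, Kq] + [c for c, _ in extra] + [np.eye(len(y))],
                names=["polygenic", "qtl"] + [nm for _, nm in extra] + ["residual"],
                start=start, max_iter=max_iter)
        except RemlError:
            rows.append((ibd.positions.iloc[k]["chrom"],
                         float(ibd.positions.iloc[k]["cM"]),
                         np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        lrt = max(0.0, 2.0 * (full.loglik - null.loglik))
        theta = full.extras["theta"]
        va = theta[0] + theta[1]
        prop_va = float(theta[1] / va) if va > 0 else 0.0
        prop_phe = float(theta[1] / theta.sum()) if theta.sum() > 0 else 0.0
        rows.append((ibd.positions.iloc[k]["chrom"],
                     float(ibd.positions.iloc[k]["cM"]),
                     float(lrt), float(lrt / LOD_SCALE), mixture_pvalue(lrt),
                     prop_va, prop_phe))
    table = pd.DataFrame(rows, columns=["chrom", "cM", "lrt", "lod", "p",
                                        "qtl_var_prop", "qtl_phe_prop"])
    return ScanResult(table=table, thresholds=thresholds,
                      null_loglik=null.loglik)


def multi_qtl_fit(trait: str, data, ibd: IbdGrid, position_indices: list[int],
                  polygenic: RelatednessMatrix, fixed: list[str] = (),
                  max_iter: int = 150) -> dict:
    """Joint model with one random QTL term per position plus the polygenic
    term; returns each QTL's share of the total genetic variance."""
    spec = ModelSpec(trait=trait, data=data, fixed=list(fixed), random=[])
    df = spec.records()
    df = df[df["individual_id"].isin(ibd.ids)].reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    X, _ = build_design(df, list(fixed))
    idx_map = {i: k for k, i in enumerate(ibd.ids)}
    obs_rows = np.array([idx_map[i] for i in df["individual_id"].astype(str)])
    mats = []
    for k in position_indices:
        Kq = ibd.matrices[k][np.ix_(obs_rows, obs_rows)]
        for prev_i, prev in zip(position_indices, mats):
            denom = np.linalg.norm(prev) * np.linalg.norm(Kq)
            if denom > 0 and np.sum(prev * Kq) / denom > 1.0 - 1e-10:
                raise ValueError(
                    f"collinear IBD structures at positions {prev_i} and {k}")
        mats.append(Kq)
    Cpoly, _, _ = _term_component(df, RandomTerm("individual_id", polygenic))
    names = [f"qtl_{k}" for k in position_indices] + ["polygenic", "residual"]
    fit = fit_components(y, X, mats + [Cpoly, np.eye(len(y))], names=names,
                         max_iter=max_iter)
    theta = fit.extras["theta"]
    vg = float(np.sum(theta[:-1]))
    shares = {names[i]: float(theta[i] / vg) if vg > 0 else 0.0
              for i in range(len(position_indices))}
    return {"fit": fit, "genetic_shares": shares,
            "total_h2": vg / float(np.sum(theta)) if np.sum(theta) > 0 else 0.0}


def plot_scan(scan: ScanResult, path, title: str | None = None) -> None:
    """Genome-scan figure: LOD by cumulative map position, chromosomes
    alternating shade, dashed guide lines at the nominal / suggestive /
    significant thresholds."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0.0
    ticks, labels = [], []
    for ci, (chrom, grp) in enumerate(scan.table.groupby("chrom", sort=False)):
        x = grp["cM"].to_numpy() + offset
        ax.plot(x, grp["lod"], color="C0" if ci % 2 == 0 else "C1", lw=1.2)
        ticks.append(offset + grp["cM"].max() / 2)
        labels.append(str(chrom))
        offset += grp["cM"].max() + 5.0
    for name, style in (("nominal", ":"), ("suggestive", "--"),
                        ("significant", "-.")):
        if name in scan.thresholds:
            ax.axhline(scan.thresholds[name], ls=style, color="tab:blue",
                       lw=0.8, label=f"{name} ({scan.thresholds[name]:.3f})")
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("map position")
    ax.set_ylabel("LOD")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# power / bias simulation
# ---------------------------------------------------------------------------

def simulate_qtl_trait(pedigree: Pedigree, ibd: IbdGrid, position_index: int,
                       qtl_var: float, polygenic: RelatednessMatrix,
                       h2_background: float, rng: np.random.Generator
                       ) -> pd.DataFrame:
    """Phenotype = QTL effect (from the IBD matrix at one position) +
    polygenic value + residual, on a unit-variance scale."""
    ids = ibd.ids
    n = len(ids)
    Kq = ibd.matrices[position_index]
    A = polygenic.align(ids)

    def _mvn(C, var):
        if var <= 0:
            return np.zeros(n)
        w, Q = np.linalg.eigh(C)
        w = np.clip(w, 0, None)
        z = Q @ (np.sqrt(w) * rng.normal(size=n))
        sd = z.std()
        return z * np.sqrt(var) / sd if sd > 0 else z

    q = _mvn(Kq, qtl_var)
    g = _mvn(A, h2_background)
    e = rng.normal(size=n)
    resid_var = max(1.0 - qtl_var - h2_background, 1e-6)
    e = e * np.sqrt(resid_var) / e.std()
    y = q + g + e
    return pd.DataFrame({"individual_id": ids, "trait": "sim", "value": y})


def power_simulation(pedigree: Pedigree, ibd: IbdGrid,
                     polygenic: RelatednessMatrix,
                     effect_sizes: tuple[float, ...] = (0.0, 0.05, 0.10, 0.20, 0.40),
                     n_reps: int = 10, h2_background: float = 0.3,
                     thresholds: dict[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Detection power and effect-size bias across simulated QTL magnitudes.

    For each effect size, a QTL is placed at a random grid position, a trait
    is simulated and the genome is scanned; detection is scored at the
    nominal/suggestive/significant thresholds and the estimated QTL variance
    share at the peak is compared with the simulated share (Beavis bias).
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        lengths = ibd.positions.groupby("chrom")["cM"].max()
        thresholds = lod_thresholds(ThresholdSpec(
            n_chromosomes=len(lengths),
            map_length_morgans=float(lengths.sum()) / 100.0))
    rows = []
    for q in effect_sizes:
        det = {k: 0 for k in thresholds}
        est_sig = []
        for rep in range(n_reps):
            pos = int(rng.integers(0, len(ibd.positions)))
            data = simulate_qtl_trait(pedigree, ibd, pos, q, polygenic,
                                      h2_background, rng)
            scan = qtl_scan("sim", data, ibd, polygenic, thresholds=thresholds)
            tab = scan.table.dropna(subset=["lod"])
            if tab.empty:
                continue
            peak = tab.loc[tab["lod"].idxmax()]
            for level, t in thresholds.items():
                if peak["lod"] >= t:
                    det[level] += 1
            if peak["lod"] >= thresholds["significant"]:
                est_sig.append(float(peak["qtl_phe_prop"]))
        row = {"effect_size": q, "n_reps": n_reps}
        for level in thresholds:
            row[f"power_{level}"] = det[level] / n_reps
        row["mean_est_share_significant"] = (float(np.mean(est_sig))
                                             if est_sig else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
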