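"""Partitioning additive genetic variance across chromosomes.

For each chromosome set, two animal models are compared: one with a GRM built
from all markers *except* the focal set, and one adding a second GRM built
from the focal set only.  The focal variance proportion and a boundary
(50:50 mixture) LRT are recorded, and the proportions are regressed on
chromosome size (Mbp) and on gene count.  A positive size regression is the
polygenic signature; a single significant focal set with a flat regression is
the oligogenic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .relmat import RelatednessMatrix, build_G, blend_G_with_pedigree
from .reml import ModelSpec, RandomTerm, fit_components, build_design, mixture_pvalue, RemlError, _term_component


@dataclass
class ChromosomeSet:
    name: str
    chroms: list[str]
    marker_idx: np.ndarray
    size_mbp: float
    gene_count: float


@dataclass
class PartitionResult:
    table: pd.DataFrame  # per set: proportion, se, lrt, p
    regressions: pd.DataFrame  # predictor, slope, slope_x1e4, r2, p
    failures: list[str] = field(default_factory=list)


def define_chromosome_sets(panel, min_snps: int = 50) -> list[ChromosomeSet]:
    """Chromosomes with >= min_snps markers stand alone; the remainder are
    pooled into one microchromosome set."""
    meta = panel.chrom_meta.set_index("chrom")
    sets: list[ChromosomeSet] = []
    pooled_chroms: list[str] = []
    for chrom, grp in panel.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) >= min_snps:
            sets.append(ChromosomeSet(str(chrom), [str(chrom)], idx,
                                      float(meta.loc[chrom, "size_mbp"]),
                                      float(meta.loc[chrom, "gene_count"])))
        else:
            pooled_chroms.append(str(chrom))
    if pooled_chroms:
        idx = panel.snp_map.index[panel.snp_map["chrom"].isin(pooled_chroms)].to_numpy()
        size = float(meta.loc[pooled_chroms, "size_mbp"].sum())
        genes = float(meta.loc[pooled_chroms, "gene_count"].sum())
        sets.append(ChromosomeSet("pooled_micro", pooled_chroms, idx, size, genes))
    return sets


def partition_variance(trait: str, data, panel, pedigree, subset: list[str],
                       sets: list[ChromosomeSet] | None = None,
                       fixed: list[str] = (), random: list[RandomTerm] = (),
                       anchor_A: RelatednessMatrix | None = None,
                       freq_source=None, blend_weight=None,
                       min_snps: int = 50,
                       grms: dict | None = None) -> PartitionResult:
    """Fit genome-minus-focal and genome-minus-focal + focal models per set.

    ``grms`` may carry precomputed {set name: (G_rest, G_focal)} matrices so
    replicate traits on the same panel skip GRM construction.
    """
    if sets is None:
        sets = define_chromosome_sets(panel, min_snps=min_snps)
    if len(sets) < 2:
        raise ValueError("need at least 2 chromosome sets")
    if grms is None:
        grms = build_partition_grms(panel, subset, sets, anchor_A=anchor_A,
                                    freq_source=freq_source,
                                    blend_weight=blend_weight)
    spec = ModelSpec(trait=trait, data=data, fixed=list(fixed), random=[])
    df = spec.records()
    df = df[df["individual_id"].isin(subset)].reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    X, _ = build_design(df, list(fixed))
    extra_comps, extra_names = [], []
    for t in random:
        C, _, _ = _term_component(df, t)
        extra_comps.append(C)
        extra_names.append(t.label())
    vy = np.var(y)
    rows, failures = [], []
    for cs in sets:
        G_rest, G_focal = grms[cs.name]
        Crest, _, _ = _term_component(df, RandomTerm("individual_id", G_rest))
        Cfocal, _, _ = _term_component(df, RandomTerm("individual_id", G_focal))
        try:
            base = fit_components(
                y, X, [Crest] + extra_comps + [np.eye(len(y))],
                names=["rest"] + extra_names + ["residual"])
            full = fit_components(
                y, X, [Crest, Cfocal] + extra_comps + [np.eye(len(y))],
                names=["rest", "focal"] + extra_names + ["residual"],
                start=np.concatenate([[base.extras["theta"][0], 1e-4 * vy],
                                      base.extras["theta"][1:]]))
        except RemlError as e:
            failures.append(f"{cs.name}: {e}")
            continue
        lrt = max(0.0, 2.0 * (full.loglik - base.loglik))
        theta = full.extras["theta"]
        total = float(theta.sum())
        prop = float(theta[1] / total) if total > 0 else 0.0
        se = full.varcomp_se.get("focal", np.nan) / total if total > 0 else np.nan
        rows.append((cs.name, cs.size_mbp, cs.gene_count, prop, se, lrt,
                     mixture_pvalue(lrt)))
    table = pd.DataFrame(rows, columns=[
        "set", "size_mbp", "gene_count", "proportion", "se", "lrt", "p"])
    regs = []
    for pred in ("size_mbp", "gene_count"):
        x = table[pred].to_numpy(dtype=float)
        yprop = table["proportion"].to_numpy(dtype=float)
        if len(x) >= 3 and np.var(x) > 0:
            res = stats.linregress(x, yprop)
            regs.append((pred, res.slope, res.slope * 1e4, res.rvalue ** 2,
                         res.pvalue))
        else:
            regs.append((pred, np.nan, np.nan, np.nan, np.nan))
    regressions = pd.DataFrame(regs, columns=[
        "predictor", "slope", "slope_x1e4", "r2", "p"])
    return PartitionResult(table=table, regressions=regressions, failures=failures)


def build_partition_grms(panel, subset, sets, anchor_A=None, freq_source=None,
                         blend_weight=None):
    """Precompute (genome-minus-focal, focal) GRM pairs for each set."""
    out = {}
    all_idx = np.arange(panel.n_snps)
    for cs in sets:
        rest_idx = np.setdiff1d(all_idx, cs.marker_idx)
        G_rest = build_G(panel, subset, marker_subset=rest_idx,
                         freq_source=freq_source, anchor_A=anchor_A)
        G_focal = build_G(panel, subset, marker_subset=cs.marker_idx,
                          freq_source=freq_source, anchor_A=anchor_A)
        if anchor_A is not None and blend_weight is not None:
            G_rest = blend_G_with_pedigree(G_rest, anchor_A, blend_weight)
            G_focal = blend_G_with_pedigree(G_focal, anchor_A, blend_weight)
        out[cs.name] = (G_rest, G_focal)
    return out
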