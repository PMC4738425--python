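"""Pedigree (A), genomic (G), blended and cross-population relatedness matrices.

The A matrix is the numerator relationship matrix from Henderson's tabular
recursion.  The raw GRM is the allele-frequency-centred dosage cross-product;
its off-diagonal scale is then calibrated against the pedigree expectation
over linked pairs (variance-in-relatedness anchoring), and the result is
optionally blended entrywise toward A to shrink marker sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .synthpop import GenotypePanel, Pedigree


@dataclass
class RelatednessMatrix:
    values: np.ndarray
    ids: list[str]
    kind: str  # A | G_raw | G_blended | G_chromosome | G_crosspop
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match id list")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("matrix is not symmetric")

    def submatrix(self, subset: Sequence[str]) -> "RelatednessMatrix":
        idx = {i: k for k, i in enumerate(self.ids)}
        rows = np.array([idx[i] for i in subset])
        return RelatednessMatrix(self.values[np.ix_(rows, rows)], list(subset),
                                 self.kind, dict(self.provenance))

    def align(self, subset: Sequence[str]) -> np.ndarray:
        return self.submatrix(subset).values


# ---------------------------------------------------------------------------
# pedigree relationship matrix
# ---------------------------------------------------------------------------

def _ancestor_closure(pedigree: Pedigree, subset: Sequence[str]) -> list[str]:
    needed = set()
    stack = list(subset)
    while stack:
        i = stack.pop()
        if i in needed:
            continue
        needed.add(i)
        for p in pedigree.parents_of(i):
            if p is not None:
                stack.append(p)
    order = [i for i in pedigree.topological_order() if i in needed]
    return order


def build_A(pedigree: Pedigree, subset: Sequence[str] | None = None) -> RelatednessMatrix:
    """Numerator relationship matrix via the tabular (Henderson) recursion.

    Computed over the subset's full ancestor closure, then restricted to the
    subset.  Handles inbreeding through the recursion itself.
    """
    if subset is None:
        subset = pedigree.ids
    known = set(pedigree.ids)
    for i in subset:
        if i not in known:
            raise ValueError(f"individual {i!r} not in pedigree")
    order = _ancestor_closure(pedigree, subset)
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for k, i in enumerate(order):
        sire, dam = pedigree.parents_of(i)
        s = idx.get(sire)
        d = idx.get(dam)
        row = np.zeros(k)
        if s is not None:
            row += 0.5 * A[s, :k]
        if d is not None:
            row += 0.5 * A[d, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
    rows = np.array([idx[i] for i in subset])
    return RelatednessMatrix(A[np.ix_(rows, rows)], list(subset), "A",
                             {"n_pedigree": len(order)})


# ---------------------------------------------------------------------------
# QTL pedigree (close-relative sub-pedigree)
# ---------------------------------------------------------------------------

def relationship_degree(pedigree: Pedigree, a: str, b: str,
                        max_degree: int = 4) -> int | None:
    """Relationship degree from the expected relatedness: degree k means
    A_ab ~ (1/2)^k, so parent-offspring and full sibs are first degree,
    half sibs and grandparent-grandoffspring second, and so on.  Returns
    None when relatedness falls below the max_degree class."""
    if a == b:
        return 0
    A = build_A(pedigree, [a, b])
    r = A.values[0, 1]
    if r <= 0:
        return None
    degree = int(round(-np.log2(r)))
    return degree if degree <= max_degree else None


def build_qtl_pedigree(pedigree: Pedigree, genotyped: Sequence[str],
                       max_degree: int = 4) -> Pedigree:
    """Sub-pedigree of genotyped individuals related to another genotyped
    individual at degree <= max_degree (A >= 0.5^max_degree, allowing for
    rounding of compounded relationships), plus their linking ancestors."""
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    genotyped = list(genotyped)
    A = build_A(pedigree, genotyped)
    # threshold halfway between the max_degree class and the next one down
    cutoff = 0.5 ** max_degree * 0.75
    linked = (A.values >= cutoff)
    np.fill_diagonal(linked, False)
    keep = {genotyped[k] for k in np.flatnonzero(linked.any(axis=1))}
    members = set(_ancestor_closure(pedigree, sorted(keep))) if keep else set()
    tab = pedigree.table
    sub = tab[tab["id"].isin(members)].copy()
    for col in ("sire", "dam"):
        sub.loc[~sub[col].isin(members), col] = None
    return Pedigree(sub.reset_index(drop=True))


# ---------------------------------------------------------------------------
# genomic relatedness
# ---------------------------------------------------------------------------

def _pairwise_grm(d: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Centred cross-product GRM with pairwise-complete missing handling.

    G_ij = sum_m (x_im - 2 p_m)(x_jm - 2 p_m) / sum_m 2 p_m (1 - p_m), the
    denominator restricted, per pair, to markers observed in both individuals.
    """
    x = d - 2.0 * p
    obs = ~np.isnan(d)
    x = np.where(obs, x, 0.0)
    het = 2.0 * p * (1.0 - p)
    num = x @ x.T
    den = obs.astype(float) @ (het[:, None] * obs.astype(float).T)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / den
    g[~np.isfinite(g)] = 0.0
    return 0.5 * (g + g.T)


def build_G(panel: GenotypePanel, subset: Sequence[str] | None = None,
            marker_subset: np.ndarray | None = None,
            freq_source: str | None = None,
            anchor_A: RelatednessMatrix | None = None) -> RelatednessMatrix:
    """Genomic relatedness calibrated against the realized variance in
    relatedness.

    The centred cross-product GRM is computed first; if ``anchor_A`` is
    given, off-diagonal deviations are rescaled by var(A)/cov(G, A) over
    pedigree-linked pairs, a noise-free calibration of the relatedness scale
    (an unbiased GRM gets scale ~1, a mis-centred or mis-normalized one is
    corrected).  ``freq_source`` selects the allele-frequency reference:
    None (subset mean), a population label, ``"founder:<pop>"`` for the
    simulator's founder frequencies, or an explicit frequency array.
    """
    if subset is None:
        subset = panel.ids
    rows = panel.rows(subset)
    d = panel.dosages[rows]
    if marker_subset is not None:
        d = d[:, marker_subset]
    if freq_source is None:
        p = np.nanmean(d, axis=0) / 2.0
    elif isinstance(freq_source, np.ndarray):
        p = freq_source
        if marker_subset is not None:
            p = p[marker_subset]
    elif isinstance(freq_source, str) and freq_source.startswith("founder:"):
        if panel.founder_freqs is None:
            raise ValueError("panel carries no founder frequencies")
        p = panel.founder_freqs[freq_source.split(":", 1)[1]]
        if marker_subset is not None:
            p = p[marker_subset]
    else:
        p = panel.population_freqs()[freq_source]
        if marker_subset is not None:
            p = p[marker_subset]
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers")
    g = _pairwise_grm(d[:, poly], p[poly])
    prov = {"n_markers": int(poly.sum()), "freq_source": freq_source or "subset"}
    kind = "G_raw"
    if anchor_A is not None:
        a = anchor_A.align(subset)
        iu = np.triu_indices(len(subset), k=1)
        linked = a[iu] > 0
        if linked.sum() >= 2 and np.std(g[iu][linked]) > 0:
            # calibrate the spread of G against the pedigree expectation:
            # cov(G, A) over linked pairs estimates the signal scale free of
            # marker sampling noise and Mendelian-sampling deviations, so an
            # unbiased GRM gets scale ~= 1 while a mis-scaled one is corrected
            cov_ga = np.cov(g[iu][linked], a[iu][linked])[0, 1]
            var_a = np.var(a[iu][linked])
            if cov_ga <= 0:
                scale = 1.0
            else:
                scale = var_a / cov_ga
            diag = np.diag(g).copy()
            mu = g[iu][linked].mean()
            g = mu + (g - mu) * scale
            np.fill_diagonal(g, diag)
            g = 0.5 * (g + g.T)
            prov["variance_anchor_scale"] = float(scale)
    return RelatednessMatrix(g, list(subset), kind, prov)


def default_blend_weight(n_markers: int, c: float = 100.0) -> float:
    """Marker-count-driven shrinkage weight w = M / (M + c).

    c approximates 1 / var(relatedness signal): per-pair GRM sampling
    variance scales as 1/M while the spread of true relatedness among
    pedigree-linked pairs is ~1e-2, so the entrywise shrinkage optimum
    signal/(signal + noise) is M/(M + ~100)."""
    return n_markers / (n_markers + c)


def blend_G_with_pedigree(G: RelatednessMatrix, A: RelatednessMatrix,
                          weight_rule: Callable[[int], float] | float = default_blend_weight
                          ) -> RelatednessMatrix:
    """Entrywise shrinkage of marker relatedness toward pedigree expectation:
    G* = w G + (1-w) A."""
    if G.ids != A.ids:
        raise ValueError("G and A must be over the same ordered individuals")
    if callable(weight_rule):
        w = weight_rule(G.provenance.get("n_markers", 0))
    else:
        w = float(weight_rule)
    vals = w * G.values + (1.0 - w) * A.values
    return RelatednessMatrix(vals, list(G.ids), "G_blended",
                             {**G.provenance, "blend_weight": w})


def build_crosspop_G(panel: GenotypePanel, pedigrees: dict[str, Pedigree] | None = None,
                     blend: bool = True,
                     weight_rule: Callable[[int], float] | float = default_blend_weight
                     ) -> RelatednessMatrix:
    """Global relatedness over both populations.

    Dosages are centred by each individual's own population allele
    frequencies before the cross-product; within-population blocks are then
    optionally blended with that population's pedigree A.
    """
    if panel.populations is None:
        raise ValueError("panel has no population labels")
    freqs = panel.population_freqs()
    d = panel.dosages.copy()
    # exclude markers monomorphic (or absent) in either population
    ok = np.ones(panel.n_snps, dtype=bool)
    for p in freqs.values():
        ok &= np.isfinite(p)
    excluded = int((~ok).sum())
    pops = np.array([panel.populations[i] for i in panel.ids])
    x = np.empty_like(d)
    het = np.zeros(panel.n_snps)
    for pop, p in freqs.items():
        rows = pops == pop
        x[rows] = d[rows] - 2.0 * p
        het += np.where(rows.sum() > 0, 2.0 * p * (1.0 - p), 0.0) * rows.sum()
    het /= len(panel.ids)
    x = x[:, ok]
    obs = ~np.isnan(x)
    x = np.where(obs, x, 0.0)
    num = x @ x.T
    den = obs.astype(float) @ (het[ok][:, None] * obs.astype(float).T)
    g = num / den
    g = 0.5 * (g + g.T)
    prov = {"n_markers": int(ok.sum()), "excluded_markers": excluded}
    if blend and pedigrees is not None:
        for pop, ped in pedigrees.items():
            members = [i for i in panel.ids if panel.populations[i] == pop]
            rows = np.array([panel.ids.index(i) for i in members])
            A = build_A(ped, members)
            if callable(weight_rule):
                w = weight_rule(int(ok.sum()))
            else:
                w = float(weight_rule)
            block = g[np.ix_(rows, rows)]
            g[np.ix_(rows, rows)] = w * block + (1 - w) * A.values
            prov[f"blend_weight_{pop}"] = w
    return RelatednessMatrix(g, list(panel.ids), "G_crosspop", prov)


def ridge(matrix: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Diagonal ridge for numerical invertibility before factorization."""
    out = matrix.copy()
    out[np.diag_indices_from(out)] += eps
    return out


# ---------------------------------------------------------------------------
# text dialect: GCTA-like lower-triangle matrix files
# ---------------------------------------------------------------------------

def write_relmat(path, rm: RelatednessMatrix) -> None:
    """Whitespace-delimited lower triangle with an id header line."""
    with open(path, "w") as fh:
        fh.write("#ids\t" + "\t".join(rm.ids) + "\n")
        fh.write(f"#kind\t{rm.kind}\n")
        for i in range(len(rm.ids)):
            fh.write("\t".join(repr(float(v)) for v in rm.values[i, : i + 1]) + "\n")


def read_relmat(path) -> RelatednessMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids = header[1:]
        kind = fh.readline().rstrip("\n").split("\t")[1]
        n = len(ids)
        vals = np.zeros((n, n))
        for i in range(n):
            row = [float(v) for v in fh.readline().split()]
            vals[i, : i + 1] = row
            vals[: i + 1, i] = row
    return RelatednessMatrix(vals, ids, kind)
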