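"""Synthetic two-population datasets for wild quantitative genetics.

Emulates the structure of long-term passerine nest-box studies: two weakly
differentiated populations with overlapping-generation pedigrees, a shared SNP
linkage map, repeated phenotype measures, maternal traits, and nuisance random
effects (cohort year, nest/brood, permanent environment).

The generator is the study-condition oracle for every downstream analysis
stage: all its outputs are deterministic functions of (SimConfig, seed) and it
records the simulation truth (causal SNPs, effects, breeding values) alongside
the phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

UNKNOWN = "0"  # missing-parent code in pedigree text files


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Variance fractions in ``nuisance_variances`` plus ``h2`` must sum to 1;
    phenotypes are simulated on a unit total-variance scale.
    """

    n_founders_per_pop: int = 60
    n_generations: int = 4
    mean_offspring: float = 4.0
    survival_to_breed: float = 0.5
    n_chromosomes: int = 10
    chrom_lengths_cM: Sequence[float] | None = None
    chrom_sizes_Mbp: Sequence[float] | None = None
    chrom_gene_counts: Sequence[int] | None = None
    n_snps: int = 1000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    between_pop_freq_corr: float = 0.98
    architecture: str = "polygenic"  # polygenic | oligogenic | null
    n_causal: int = 200
    h2: float = 0.4
    shared_fraction: float = 1.0
    causal_weighting: str = "per_gene"  # per_gene | uniform_snp
    repeat_records: int = 1
    nuisance_variances: dict | None = None
    maternal: bool = False
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths_cM is None:
            # decreasing lengths, avian-like size spread
            self.chrom_lengths_cM = [
                120, 110, 100, 90, 80, 70, 60, 50, 40, 30][: self.n_chromosomes]
        if self.chrom_sizes_Mbp is None:
            self.chrom_sizes_Mbp = [length for length in self.chrom_lengths_cM]
        if self.chrom_gene_counts is None:
            self.chrom_gene_counts = [int(10 * s) for s in self.chrom_sizes_Mbp]
        if self.nuisance_variances is None:
            resid = 1.0 - self.h2
            self.nuisance_variances = {
                "year": 0.0, "nest": 0.0, "permanent_environment": 0.0,
                "residual": resid}
        for name in ("chrom_lengths_cM", "chrom_sizes_Mbp", "chrom_gene_counts"):
            if len(getattr(self, name)) != self.n_chromosomes:
                raise ValueError(f"{name} must have length n_chromosomes")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        total = self.h2 + sum(self.nuisance_variances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"h2 + nuisance variance fractions must sum to 1, got {total}")


@dataclass
class Pedigree:
    """Parentage records for one or two populations.

    ``table`` has columns id, sire, dam, sex, cohort, population, nest; sire and
    dam are ``None`` for founders.  The parentage graph is acyclic and every
    named parent is itself a row.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        ids = self.table["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        for col in ("sire", "dam"):
            parents = self.table[col].dropna()
            missing = set(parents) - known
            if missing:
                raise ValueError(f"unknown {col} ids: {sorted(missing)[:5]}")
        self._index = {i: k for k, i in enumerate(ids)}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if len(order) != len(self.table):
            seen = set(order)
            bad = [i for i in self.table["id"] if i not in seen]
            raise ValueError(f"pedigree contains a parentage cycle involving {bad[:5]}")

    def topological_order(self) -> list[str]:
        """Ids sorted parents-before-offspring (Kahn's algorithm)."""
        tab = self.table
        children: dict[str, list[str]] = {}
        indeg = {}
        for _, row in tab.iterrows():
            n = sum(1 for p in (row["sire"], row["dam"]) if p is not None and pd.notna(p))
            indeg[row["id"]] = n
            for p in (row["sire"], row["dam"]):
                if p is not None and pd.notna(p):
                    children.setdefault(p, []).append(row["id"])
        queue = [i for i, d in indeg.items() if d == 0]
        order = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children.get(i, ()):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def parents_of(self, ind: str) -> tuple[str | None, str | None]:
        row = self.table.iloc[self._index[ind]]
        sire = row["sire"] if pd.notna(row["sire"]) else None
        dam = row["dam"] if pd.notna(row["dam"]) else None
        return sire, dam

    def founders(self) -> list[str]:
        t = self.table
        return list(t.loc[t["sire"].isna() & t["dam"].isna(), "id"])

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["population"]))


@dataclass
class GenotypePanel:
    """SNP dosages with a linkage map and chromosome metadata.

    ``dosages`` is individuals x SNPs with values 0/1/2 (np.nan = missing);
    ``snp_map`` has columns snp, chrom, cM sorted by (chrom, cM);
    ``chrom_meta`` has columns chrom, size_mbp, gene_count.
    ``haplotypes`` (individuals x SNPs x 2, int8) is retained from simulation
    when available; real-data panels may leave it ``None``.
    """

    ids: list[str]
    dosages: np.ndarray
    snp_map: pd.DataFrame
    chrom_meta: pd.DataFrame
    populations: dict[str, str] | None = None
    haplotypes: np.ndarray | None = None
    founder_freqs: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError("dosage matrix shape does not match ids x map")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["cM"].to_numpy()) >= 0):
                raise ValueError("cM positions must be non-decreasing within chromosome")
        self._row = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def rows(self, subset: Sequence[str]) -> np.ndarray:
        return np.array([self._row[i] for i in subset])

    def allele_freqs(self, subset: Sequence[str] | None = None) -> np.ndarray:
        """Per-SNP frequency of the counted allele (missing ignored)."""
        d = self.dosages if subset is None else self.dosages[self.rows(subset)]
        return np.nanmean(d, axis=0) / 2.0

    def population_freqs(self) -> dict[str, np.ndarray]:
        if self.populations is None:
            raise ValueError("panel has no population labels")
        out = {}
        for pop in sorted(set(self.populations.values())):
            members = [i for i in self.ids if self.populations[i] == pop]
            out[pop] = self.allele_freqs(members)
        return out


@dataclass
class TraitDataset:
    """Phenotype records plus (for simulations) the generating truth.

    ``records`` columns: individual_id, trait, value, plus covariate and
    random-factor columns (year, nest).  ``truth`` holds causal SNP indices,
    effect vectors, per-individual breeding values and realized variance
    fractions, keyed by population where applicable.
    """

    records: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait]


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a two-population, overlapping-generation pedigree.

    Random male-female pairing within population and cohort, one brood per
    pair-year; parents survive to later cohorts with probability
    ``survival_to_breed`` per year, so generations overlap.  No migration.
    """
    if config.n_founders_per_pop < 2:
        raise ValueError("n_founders_per_pop must be >= 2")
    if config.n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    for pop in ("NL", "UK"):
        alive: list[tuple[str, str]] = []  # (id, sex)
        counter = 0
        for k in range(config.n_founders_per_pop):
            counter += 1
            ind = f"{pop}{counter:05d}"
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append((ind, None, None, sex, 0, pop, None))
            alive.append((ind, sex))
        for cohort in range(1, config.n_generations):
            males = [i for i, s in alive if s == "M"]
            females = [i for i, s in alive if s == "F"]
            rng.shuffle(males)
            rng.shuffle(females)
            n_pairs = min(len(males), len(females), config.n_founders_per_pop)
            if n_pairs == 0:
                raise ValueError(
                    "no breeding pairs survive to cohort "
                    f"{cohort}; increase survival_to_breed or n_founders_per_pop")
            chicks = []
            for p in range(n_pairs):
                nest = f"{pop}_y{cohort}_n{p}"
                brood = rng.poisson(config.mean_offspring)
                for _ in range(brood):
                    counter += 1
                    ind = f"{pop}{counter:05d}"
                    sex = "M" if rng.random() < 0.5 else "F"
                    rows.append((ind, males[p], females[p], sex, cohort, pop, nest))
                    chicks.append((ind, sex))
            # per-year survival of previous breeders plus recruitment of chicks
            survivors = [a for a in alive if rng.random() < config.survival_to_breed]
            recruits = [c for c in chicks if rng.random() < config.survival_to_breed]
            alive = survivors + recruits
    table = pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "cohort", "population", "nest"])
    return Pedigree(table)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def _founder_frequencies(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Correlated per-population founder allele frequencies.

    A base frequency is drawn per SNP (uniform MAF mirrored to the full range);
    each population's frequency is base + independent noise sized so that the
    between-population correlation equals ``between_pop_freq_corr``.
    """
    lo, hi = config.founder_maf_range
    maf = rng.uniform(lo, hi, size=config.n_snps)
    flip = rng.random(config.n_snps) < 0.5
    base = np.where(flip, maf, 1.0 - maf)
    c = config.between_pop_freq_corr
    if c >= 1.0:
        return {"NL": base.copy(), "UK": base.copy()}
    var_base = np.var(base)
    tau = np.sqrt(var_base * (1.0 - c) / c)
    freqs = {}
    for pop in ("NL", "UK"):
        f = base + rng.normal(0.0, tau, size=config.n_snps)
        freqs[pop] = np.clip(f, 0.01, 0.99)
    return freqs


def build_snp_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNP positions allocated to chromosomes proportionally to map length."""
    lengths = np.asarray(config.chrom_lengths_cM, dtype=float)
    probs = lengths / lengths.sum()
    counts = rng.multinomial(config.n_snps, probs)
    counts = np.maximum(counts, 2)  # every chromosome carries >= 2 markers
    while counts.sum() > config.n_snps:
        counts[np.argmax(counts)] -= 1
    rows = []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, lengths[c], size=counts[c]))
        for j, p in enumerate(pos):
            rows.append((f"snp_c{c + 1}_{j}", f"chr{c + 1}", float(p)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "cM"])


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _gamete(hap: np.ndarray, chrom_codes: np.ndarray, rec: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Sample one recombinant gamete from a (n_snp, 2) parental haplotype pair.

    ``rec`` holds the switch probability between adjacent markers (0.5 at
    chromosome boundaries, Haldane within).
    """
    n = hap.shape[0]
    switches = rng.random(n) < rec
    switches[0] = rng.random() < 0.5
    slot = np.cumsum(switches) % 2
    return hap[np.arange(n), slot]


def gene_drop(pedigree: Pedigree, config: SimConfig,
              snp_map: pd.DataFrame | None = None,
              founder_freqs: dict[str, np.ndarray] | None = None) -> GenotypePanel:
    """Drop founder haplotypes through the pedigree with Haldane crossovers.

    Founders receive Hardy-Weinberg genotypes from their population's allele
    frequencies; each meiosis recombines along the cM map without
    interference.  Deterministic given (config, seed).
    """
    rng = np.random.default_rng(config.seed + 1)
    if snp_map is None:
        snp_map = build_snp_map(config, rng)
    if snp_map["cM"].isna().any():
        raise ValueError("marker with undefined map position")
    if founder_freqs is None:
        founder_freqs = _founder_frequencies(config, rng)
    order = pedigree.topological_order()
    pops = pedigree.population_of()
    n_snp = len(snp_map)
    cm = snp_map["cM"].to_numpy()
    chrom_codes, _ = pd.factorize(snp_map["chrom"])
    d = np.diff(cm, prepend=cm[0])
    rec = _haldane_r(d)
    rec[0] = 0.5
    rec[np.flatnonzero(np.diff(chrom_codes, prepend=chrom_codes[0]) != 0)] = 0.5

    hap = np.zeros((len(order), n_snp, 2), dtype=np.int8)
    row = {ind: k for k, ind in enumerate(order)}
    for ind in order:
        sire, dam = pedigree.parents_of(ind)
        k = row[ind]
        if sire is None and dam is None:
            f = founder_freqs[pops[ind]]
            hap[k, :, 0] = rng.random(n_snp) < f
            hap[k, :, 1] = rng.random(n_snp) < f
        elif sire is not None and dam is not None:
            hap[k, :, 0] = _gamete(hap[row[sire]], chrom_codes, rec, rng)
            hap[k, :, 1] = _gamete(hap[row[dam]], chrom_codes, rec, rng)
        else:  # one known parent: other gamete from population frequencies
            parent = sire if sire is not None else dam
            hap[k, :, 0] = _gamete(hap[row[parent]], chrom_codes, rec, rng)
            f = founder_freqs[pops[ind]]
            hap[k, :, 1] = rng.random(n_snp) < f
    ids = list(pedigree.ids)
    perm = np.array([row[i] for i in ids])
    hap = hap[perm]
    dos = hap.sum(axis=2).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan
    chrom_meta = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in range(config.n_chromosomes)],
        "size_mbp": list(config.chrom_sizes_Mbp),
        "gene_count": list(config.chrom_gene_counts)})
    return GenotypePanel(ids=ids, dosages=dos, snp_map=snp_map.reset_index(drop=True),
                         chrom_meta=chrom_meta, populations=pops, haplotypes=hap,
                         founder_freqs=founder_freqs)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def _scaled(x: np.ndarray, target_var: float, rng: np.random.Generator) -> np.ndarray:
    """Rescale a component so its realized sample variance equals target_var."""
    if target_var <= 0:
        return np.zeros_like(x)
    v = np.var(x)
    if v < 1e-12:
        x = rng.normal(size=x.shape)
        v = np.var(x)
    return x * np.sqrt(target_var / v)


def _choose_causal(panel: GenotypePanel, config: SimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    n_causal = {"null": 0, "oligogenic": min(config.n_causal, 3),
                "polygenic": config.n_causal}[config.architecture]
    if n_causal > panel.n_snps:
        raise ValueError("n_causal exceeds number of SNPs")
    if n_causal == 0:
        return np.array([], dtype=int)
    if config.causal_weighting == "per_gene":
        genes = dict(zip(panel.chrom_meta["chrom"], panel.chrom_meta["gene_count"]))
        w = np.array([genes[c] for c in panel.snp_map["chrom"]], dtype=float)
        w /= w.sum()
    else:
        w = None
    return rng.choice(panel.n_snps, size=n_causal, replace=False, p=w)


def simulate_traits(pedigree: Pedigree, panel: GenotypePanel, config: SimConfig,
                    trait: str = "trait") -> TraitDataset:
    """Simulate phenotypes as genetic value + nuisance effects + residual.

    Components (breeding value from causal SNP effects; year, nest, permanent
    environment; residual) are each rescaled so realized variance fractions
    match the configured fractions; total phenotypic variance is 1.  With
    ``config.maternal`` each record attaches to the mother's genotype and
    breeding value.  Per-population causal architectures share a fraction
    ``shared_fraction`` of identical SNP effects.
    """
    rng = np.random.default_rng(config.seed + 2)
    nv = config.nuisance_variances
    total = config.h2 + sum(nv.values())
    if total > 1.0 + 1e-9:
        raise ValueError("h2 + nuisance fractions exceed 1")
    ped = pedigree.table.set_index("id")
    pops = pedigree.population_of()
    ids = panel.ids
    dos = np.nan_to_num(panel.dosages, nan=0.0)

    causal = _choose_causal(panel, config, rng)
    shared_effects = rng.normal(size=len(causal))
    n_shared = int(round(config.shared_fraction * len(causal)))
    bv = {}
    causal_by_pop, effects_by_pop = {}, {}
    for pop in sorted(set(pops.values())):
        eff = shared_effects.copy()
        idx = causal.copy()
        if n_shared < len(causal):
            # population-specific tail: new positions, new effects
            repl = rng.choice(
                np.setdiff1d(np.arange(panel.n_snps), causal),
                size=len(causal) - n_shared, replace=False)
            idx = np.concatenate([causal[:n_shared], repl])
            eff = np.concatenate(
                [shared_effects[:n_shared],
                 rng.normal(size=len(causal) - n_shared)])
        causal_by_pop[pop], effects_by_pop[pop] = idx, eff
        members = [i for i in ids if pops[i] == pop]
        rows = panel.rows(members)
        if len(idx):
            centred = dos[np.ix_(rows, idx)] - dos[rows][:, idx].mean(axis=0)
            raw = centred @ eff
        else:
            raw = np.zeros(len(members))
        raw = _scaled(raw, config.h2, rng) if config.h2 > 0 else np.zeros(len(members))
        bv.update(dict(zip(members, raw)))

    # whose genotype carries the trait
    carriers = []
    for i in ids:
        if config.maternal:
            dam = ped.loc[i, "dam"]
            if pd.isna(dam):
                continue
            carriers.append((i, dam))
        else:
            carriers.append((i, i))
    if config.maternal:
        # one record per brood, attached to the mother
        units = sorted({c for _, c in carriers})
    else:
        units = [i for i, _ in carriers]

    # components built at record level, each rescaled to its exact fraction of
    # the unit total variance; the residual is orthogonalized against the
    # breeding values so realized h2 matches the request tightly
    years = ped["cohort"].to_dict()
    nests = ped["nest"].to_dict()
    records = []
    realized = {}
    for pop in sorted(set(pops.values())):
        members = [u for u in units if pops[u] == pop]
        n_rec = config.repeat_records
        rec_unit = np.repeat(np.arange(len(members)), n_rec)
        year_lab = np.repeat([years[m] for m in members], n_rec)
        nest_lab = np.repeat([str(nests[m]) for m in members], n_rec)

        def level_effect(labels, frac):
            lv, inv = np.unique(labels, return_inverse=True)
            draws = rng.normal(size=len(lv))
            vec = draws[inv]
            return _scaled(vec, frac, rng)

        g_unit = np.array([bv[m] for m in members])
        g_unit = _scaled(g_unit, config.h2, rng) if config.h2 > 0 else np.zeros(len(members))
        for k, m in enumerate(members):
            bv[m] = g_unit[k]
        g_rec = g_unit[rec_unit]
        ye = level_effect(year_lab, nv.get("year", 0.0))
        ne = level_effect(nest_lab, nv.get("nest", 0.0))
        pe = level_effect(rec_unit, nv.get("permanent_environment", 0.0))
        resid = rng.normal(size=len(rec_unit))
        if np.var(g_rec) > 0:
            resid = resid - g_rec * (resid @ g_rec) / (g_rec @ g_rec)
        resid = _scaled(resid, nv.get("residual", 0.0), rng)
        value = g_rec + ye + ne + pe + resid
        realized[pop] = {
            "h2": float(np.var(g_rec) / np.var(value)) if np.var(value) > 0 else 0.0}
        for r, m_idx in enumerate(rec_unit):
            m = members[m_idx]
            records.append((m, trait, float(value[r]), year_lab[r], nest_lab[r],
                            pops[m]))
    rec = pd.DataFrame(records, columns=[
        "individual_id", "trait", "value", "year", "nest", "population"])
    truth = {
        "causal_by_pop": causal_by_pop,
        "effects_by_pop": effects_by_pop,
        "breeding_values": {m: bv[m] for m in units},
        "h2": config.h2,
        "realized": realized,
        "nuisance_variances": dict(nv),
    }
    return TraitDataset(records=rec, truth=truth)


# ---------------------------------------------------------------------------
# population-genetic summaries used by the tests and examples
# ---------------------------------------------------------------------------

def hudson_fst(p1: np.ndarray, p2: np.ndarray, n1: int, n2: int) -> float:
    """Hudson estimator of F_ST (ratio of averages over SNPs)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())


def mendelian_errors(pedigree: Pedigree, panel: GenotypePanel) -> int:
    """Count offspring dosages incompatible with parental dosages."""
    row = panel._row
    d = panel.dosages
    errs = 0
    for ind in panel.ids:
        sire, dam = pedigree.parents_of(ind)
        for parent in (sire, dam):
            if parent is None or parent not in row:
                continue
            po = d[row[ind]]
            pp = d[row[parent]]
            ok = ~(np.isnan(po) | np.isnan(pp))
            # a homozygous parent must transmit its allele
            errs += int(np.sum((pp[ok] == 0) & (po[ok] == 2)))
            errs += int(np.sum((pp[ok] == 2) & (po[ok] == 0)))
    return errs
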