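"""End-to-end driver: simulate (or load) a two-population study and run the
requested analysis stages, writing per-stage text outputs.

Stage order mirrors the analysis workflow: heritability -> chromosome
partitioning -> QTL scan -> power -> GWAS -> BVSR -> concordance.  Every
output file carries a header comment with the config hash and seed; all
stochastic stages derive their seeds from the global seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import io as wio
from .bvsr import BvsrConfig, run_bvsr
from .chrpart import define_chromosome_sets, partition_variance
from .concordance import gwas_qtl_overlap, interpolate_lod_at_snps
from .gwas import bonferroni_threshold, effective_tests, score_test_scan
from .qtl import estimate_ibd_grid, power_simulation, qtl_scan
from .relmat import build_A, build_G, blend_G_with_pedigree
from .reml import ModelSpec, RandomTerm, compute_EPV, fit_reml, lrt_variance
from .synthpop import SimConfig, gene_drop, simulate_pedigree, simulate_traits

ALL_STAGES = ("heritability", "partition", "qtlscan", "power", "gwas", "bvsr",
              "concordance")


@dataclass
class RunConfig:
    sim: SimConfig | None = None
    pedigree_path: str | None = None
    plink_prefix: str | None = None
    phenotype_path: str | None = None
    stages: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str = "wildqg_out"
    grid_step_cM: float = 10.0
    ibd_samples: int = 300
    bvsr: BvsrConfig | None = None
    power_reps: int = 5

    def config_hash(self) -> str:
        fields = {k: str(v) for k, v in asdict(self).items()
                  if k != "out_dir"}  # hash the analysis, not its destination
        blob = json.dumps(fields, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"# wildqg config={config.config_hash()} seed={config.seed}\n"


def _write_df(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns a report bundle of in-memory
    results keyed by stage (also written under ``config.out_dir``)."""
    bad = [s for s in config.stages if s not in ALL_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash()}

    if config.sim is not None:
        sim = config.sim
        ped = simulate_pedigree(sim)
        panel = gene_drop(ped, sim)
        data = simulate_traits(ped, panel, sim)
        wio.write_pedigree(out / "pedigree.tsv", ped)
        wio.write_plink(out / "genotypes", panel)
        wio.write_phenotypes(out / "phenotypes.csv", data)
        wio.write_truth(out / "truth.csv", data)
    else:
        ped, panel, data = wio.read_inputs(config.pedigree_path,
                                           config.plink_prefix,
                                           config.phenotype_path)
    report["n_individuals"] = len(ped.table)
    report["n_snps"] = panel.n_snps
    if not config.stages:
        return report

    pops = sorted(set(ped.table["population"]))
    trait = str(data.records["trait"].iloc[0])
    per_pop: dict[str, dict] = {}
    for pop in pops:
        members = [i for i in panel.ids
                   if panel.populations.get(i) == pop
                   and i in set(data.records["individual_id"])]
        A = build_A(ped, members)
        G = build_G(panel, members, anchor_A=A)
        Gb = blend_G_with_pedigree(G, A)
        per_pop[pop] = {"members": members, "A": A, "G": Gb}

    if "heritability" in config.stages:
        rows = []
        for pop in pops:
            sub = data.records[data.records["population"] == pop]
            for label, K in (("pedigree", per_pop[pop]["A"]),
                             ("marker", per_pop[pop]["G"])):
                fit = fit_reml(ModelSpec(trait, sub, random=[
                    RandomTerm("individual_id", K)]))
                null = fit_reml(ModelSpec(trait, sub, random=[]))
                lrt, p = lrt_variance(fit, null)
                rows.append((pop, label, fit.h2, fit.h2_se, lrt, p))
        df = pd.DataFrame(rows, columns=["population", "relatedness", "h2",
                                         "se", "lrt", "p"])
        _write_df(out / "heritability.csv", df, config)
        report["heritability"] = df

    if "partition" in config.stages:
        pop = pops[0]
        sets = define_chromosome_sets(panel)
        part = partition_variance(trait, data, panel, ped,
                                  per_pop[pop]["members"], sets=sets,
                                  anchor_A=per_pop[pop]["A"])
        _write_df(out / "partition.csv", part.table, config)
        _write_df(out / "partition_regressions.csv", part.regressions, config)
        report["partition"] = part

    ibd = None
    scan = None
    if "qtlscan" in config.stages or "power" in config.stages:
        pop = pops[0]
        members = per_pop[pop]["members"]
        subped_tab = ped.table[ped.table["id"].isin(set(members))].copy()
        for col in ("sire", "dam"):
            subped_tab.loc[~subped_tab[col].isin(set(members)), col] = None
        from .synthpop import Pedigree as _Ped
        subped = _Ped(subped_tab.reset_index(drop=True))
        ibd = estimate_ibd_grid(subped, panel, grid_step_cM=config.grid_step_cM,
                                n_samples=config.ibd_samples, seed=config.seed)
        if "qtlscan" in config.stages:
            scan = qtl_scan(trait, data, ibd, per_pop[pop]["A"])
            with open(out / "qtl_scan.tsv", "w") as fh:
                fh.write(_header(config))
                for k, v in scan.thresholds.items():
                    fh.write(f"# threshold {k}\t{v}\n")
                scan.table.to_csv(fh, sep="\t", index=False)
            report["qtlscan"] = scan
        if "power" in config.stages:
            power = power_simulation(subped, ibd, per_pop[pop]["A"],
                                     n_reps=config.power_reps,
                                     seed=config.seed + 7)
            _write_df(out / "power.csv", power, config)
            report["power"] = power

    epvs = {}
    gwas_results = {}
    if "gwas" in config.stages or "bvsr" in config.stages:
        for pop in pops:
            sub = data.records[data.records["population"] == pop]
            random_terms = []
            if sub["year"].nunique() > 1:
                random_terms.append(RandomTerm("year"))
            if sub["nest"].nunique() > 1:
                random_terms.append(RandomTerm("nest"))
            epvs[pop] = compute_EPV(ModelSpec(trait, sub, random=random_terms))
    if "gwas" in config.stages:
        k_eff = effective_tests(panel)
        thr = bonferroni_threshold(0.05, k_eff)
        for pop in pops:
            res = score_test_scan(epvs[pop], panel, per_pop[pop]["G"])
            res.k_eff = k_eff
            res.thresholds["genome_wide"] = thr
            gwas_results[pop] = res
            _write_df(out / f"gwas_{pop}.tsv", res.table, config)
        report["gwas"] = gwas_results
        report["k_eff"] = k_eff

    if "bvsr" in config.stages:
        bcfg = config.bvsr or BvsrConfig(iterations=6000, burn_in=1000,
                                         chains=2, seed=config.seed)
        bres = {}
        for pop in pops:
            bres[pop] = run_bvsr(epvs[pop], panel, bcfg)
            _write_df(out / f"bvsr_{pop}.tsv", bres[pop].samples, config)
        report["bvsr"] = bres

    if "concordance" in config.stages:
        rows = []
        if scan is not None and "gwas" in report:
            pop = pops[0]
            interp = interpolate_lod_at_snps(scan, panel)
            overlap = gwas_qtl_overlap(
                gwas_results[pop].table.set_index("snp")["p"],
                interp.set_index("snp")["p"])
            rows.append((overlap.test, overlap.statistic, overlap.p,
                         overlap.null))
        if rows:
            df = pd.DataFrame(rows, columns=["test", "statistic", "p", "null"])
            _write_df(out / "concordance.csv", df, config)
            report["concordance"] = df
    return report
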