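"""Synthetic-data generator: determinism, pedigree structure, Haldane
recombination, trait variance composition."""

import numpy as np
import pandas as pd
import pytest

from wildqg.synthpop import (SimConfig, gene_drop, hudson_fst,
                             mendelian_errors, simulate_pedigree,
                             simulate_traits)


def test_single_generation_gives_founders_only():
    cfg = SimConfig(n_founders_per_pop=10, n_generations=1, n_snps=20, seed=1)
    ped = simulate_pedigree(cfg)
    assert len(ped.table) == 20
    assert ped.table["sire"].isna().all() and ped.table["dam"].isna().all()


def test_same_seed_reproduces_everything(base_config):
    ped1 = simulate_pedigree(base_config)
    ped2 = simulate_pedigree(base_config)
    pd.testing.assert_frame_equal(ped1.table, ped2.table)
    pan1 = gene_drop(ped1, base_config)
    pan2 = gene_drop(ped2, base_config)
    np.testing.assert_array_equal(pan1.dosages, pan2.dosages)
    tr1 = simulate_traits(ped1, pan1, base_config)
    tr2 = simulate_traits(ped2, pan2, base_config)
    pd.testing.assert_frame_equal(tr1.records, tr2.records)


def test_impossible_config_names_parameter():
    cfg = SimConfig(n_founders_per_pop=4, n_generations=6,
                    survival_to_breed=0.001, mean_offspring=0.01, seed=0)
    with pytest.raises(ValueError, match="survival_to_breed"):
        simulate_pedigree(cfg)


def test_parent_offspring_pair_count_matches_brute_force():
    cfg = SimConfig(n_founders_per_pop=60, n_generations=5, mean_offspring=4,
                    survival_to_breed=0.25, n_snps=10, seed=9)
    ped = simulate_pedigree(cfg)
    tab = ped.table
    # direct count of parent-offspring links
    links = tab["sire"].notna().sum() + tab["dam"].notna().sum()
    po = 0
    parents = {r["id"]: {r["sire"], r["dam"]} for _, r in tab.iterrows()}
    for a in tab["id"]:
        for p in parents[a]:
            if p is not None and pd.notna(p):
                po += 1
    assert po == links
    # offspring cohorts exceed parent cohorts
    cohort = dict(zip(tab["id"], tab["cohort"]))
    for _, r in tab.iterrows():
        for p in (r["sire"], r["dam"]):
            if p is not None and pd.notna(p):
                assert cohort[r["id"]] > cohort[p]


def test_no_cross_population_matings(pedigree):
    pop = pedigree.population_of()
    for _, r in pedigree.table.iterrows():
        for p in (r["sire"], r["dam"]):
            if p is not None and pd.notna(p):
                assert pop[p] == pop[r["id"]]


def test_mendelian_consistency(pedigree, panel):
    assert mendelian_errors(pedigree, panel) == 0


def test_identical_founder_freqs_give_near_zero_fst():
    cfg = SimConfig(n_founders_per_pop=150, n_generations=1, n_snps=2000,
                    between_pop_freq_corr=1.0, seed=3)
    ped = simulate_pedigree(cfg)
    panel = gene_drop(ped, cfg)
    f = panel.population_freqs()
    fst = hudson_fst(f["NL"], f["UK"], 150, 150)
    assert abs(fst) < 0.005


def test_between_population_frequency_correlation():
    cfg = SimConfig(n_founders_per_pop=300, n_generations=1, n_snps=2500,
                    between_pop_freq_corr=0.98, seed=4)
    ped = simulate_pedigree(cfg)
    panel = gene_drop(ped, cfg)
    f = panel.population_freqs()
    r = np.corrcoef(f["NL"], f["UK"])[0, 1]
    assert r == pytest.approx(0.98, abs=0.01)


def test_zero_distance_markers_cosegregate():
    cfg = SimConfig(n_founders_per_pop=40, n_generations=3, n_snps=2,
                    n_chromosomes=1, chrom_lengths_cM=[50.0],
                    chrom_sizes_Mbp=[50.0], chrom_gene_counts=[500], seed=5)
    snp_map = pd.DataFrame({"snp": ["a", "b"], "chrom": ["chr1", "chr1"],
                            "cM": [25.0, 25.0]})
    ped = simulate_pedigree(cfg)
    panel = gene_drop(ped, cfg, snp_map=snp_map)
    hap = panel.haplotypes
    row = {i: k for k, i in enumerate(panel.ids)}
    # every informative transmission (parental strands distinguishable at
    # both loci) is non-recombinant: one parental strand matches both loci
    checked = 0
    for ind in panel.ids:
        for slot, parent in zip((0, 1), ped.parents_of(ind)):
            if parent is None:
                continue
            child = hap[row[ind], :, slot]
            par = hap[row[parent]]
            if np.array_equal(par[:, 0], par[:, 1]):
                continue
            assert (np.array_equal(child, par[:, 0])
                    or np.array_equal(child, par[:, 1]))
            checked += 1
    assert checked > 50


def test_haldane_recombination_fraction_at_50cM():
    """Transmission between markers 50 cM apart recombines at the Haldane
    rate (1 - e^-1)/2 ~ 0.316."""
    cfg = SimConfig(n_founders_per_pop=60, n_generations=3, n_snps=2,
                    n_chromosomes=1, chrom_lengths_cM=[50.0],
                    chrom_sizes_Mbp=[50.0], chrom_gene_counts=[500],
                    mean_offspring=8, seed=6)
    snp_map = pd.DataFrame({"snp": ["a", "b"], "chrom": ["chr1", "chr1"],
                            "cM": [0.0, 50.0]})
    recomb = []
    for seed in range(12):
        cfg.seed = seed
        ped = simulate_pedigree(cfg)
        panel = gene_drop(ped, cfg, snp_map=snp_map)
        hap = panel.haplotypes
        row = {i: k for k, i in enumerate(panel.ids)}
        for ind in panel.ids:
            sire, dam = ped.parents_of(ind)
            for slot, parent in ((0, sire), (1, dam)):
                if parent is None:
                    continue
                child = hap[row[ind], :, slot]
                par = hap[row[parent]]
                # recombinant iff no single parental strand matches both loci
                same0 = np.array_equal(child, par[:, 0])
                same1 = np.array_equal(child, par[:, 1])
                informative = not np.array_equal(par[:, 0], par[:, 1])
                if informative and (par[0, 0] != par[0, 1]) and (par[1, 0] != par[1, 1]):
                    recomb.append(0 if (same0 or same1) else 1)
    assert len(recomb) >= 2000
    assert np.mean(recomb) == pytest.approx((1 - np.exp(-1)) / 2, abs=0.02)


def test_null_architecture_breeding_values_flat(pedigree, panel):
    cfg = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                    n_chromosomes=6, architecture="null", h2=0.0,
                    nuisance_variances={"year": 0.0, "nest": 0.0,
                                        "permanent_environment": 0.0,
                                        "residual": 1.0}, seed=7)
    tr = simulate_traits(pedigree, panel, cfg)
    bv = np.array([tr.truth["breeding_values"][i]
                   for i in tr.records["individual_id"]])
    y = tr.records["value"].to_numpy()
    assert np.allclose(bv, 0.0)
    assert abs(np.polyfit(np.arange(len(y)), y, 1)[0]) < 1e-2


def test_realized_h2_matches_request(pedigree, panel):
    cfg = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                    n_chromosomes=6, h2=0.4, n_causal=200, seed=8)
    tr = simulate_traits(pedigree, panel, cfg)
    for pop in ("NL", "UK"):
        rec = tr.records[tr.records["population"] == pop]
        bv = np.array([tr.truth["breeding_values"][i]
                       for i in rec["individual_id"]])
        frac = np.var(bv) / np.var(rec["value"].to_numpy())
        assert frac == pytest.approx(0.40, abs=0.02)


def test_repeat_structure_repeatability():
    """With 3 records each and pe = 0.2, intra-individual correlation of the
    phenotype ~ h2 + pe."""
    cfg = SimConfig(n_founders_per_pop=60, n_generations=3, n_snps=400,
                    n_chromosomes=4, h2=0.3, n_causal=80, repeat_records=3,
                    nuisance_variances={"year": 0.0, "nest": 0.0,
                                        "permanent_environment": 0.2,
                                        "residual": 0.5}, seed=9)
    ped = simulate_pedigree(cfg)
    panel = gene_drop(ped, cfg)
    tr = simulate_traits(ped, panel, cfg)
    rec = tr.records[tr.records["population"] == "NL"]
    k = 3
    grp = rec.groupby("individual_id")["value"]
    ms_b = k * grp.mean().var(ddof=1)
    ms_w = grp.var(ddof=1).mean()
    icc = (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)
    assert icc == pytest.approx(0.5, abs=0.08)


def test_maternal_trait_attaches_to_mother(pedigree, panel):
    cfg = SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                    n_chromosomes=6, h2=0.4, n_causal=100, maternal=True,
                    seed=10)
    tr = simulate_traits(pedigree, panel, cfg)
    dams = set(pedigree.table["dam"].dropna())
    assert set(tr.records["individual_id"]) <= dams


def test_variance_fractions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(h2=0.5, nuisance_variances={"year": 0.2, "nest": 0.0,
                                              "permanent_environment": 0.0,
                                              "residual": 0.5})
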