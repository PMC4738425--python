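"""Shared simulated fixtures.

Everything is generated programmatically; session scope keeps the heavier
objects (pedigree, genotype panel, relatedness matrices) shared across tests.
"""

import numpy as np
import pandas as pd
import pytest

from wildqg.relmat import build_A
from wildqg.synthpop import (GenotypePanel, Pedigree, SimConfig, gene_drop,
                             simulate_pedigree, simulate_traits)


@pytest.fixture(scope="session")
def base_config() -> SimConfig:
    return SimConfig(n_founders_per_pop=40, n_generations=4, n_snps=600,
                     n_chromosomes=6, h2=0.4, n_causal=120, seed=42)


@pytest.fixture(scope="session")
def pedigree(base_config) -> Pedigree:
    return simulate_pedigree(base_config)


@pytest.fixture(scope="session")
def panel(pedigree, base_config) -> GenotypePanel:
    return gene_drop(pedigree, base_config)


@pytest.fixture(scope="session")
def traits(pedigree, panel, base_config):
    return simulate_traits(pedigree, panel, base_config)


@pytest.fixture(scope="session")
def nl_ids(panel):
    return [i for i in panel.ids if panel.populations[i] == "NL"]


@pytest.fixture(scope="session")
def nl_pedigree(pedigree, nl_ids) -> Pedigree:
    tab = pedigree.table[pedigree.table["id"].isin(set(nl_ids))].copy()
    for col in ("sire", "dam"):
        tab.loc[~tab[col].isin(set(nl_ids)), col] = None
    return Pedigree(tab.reset_index(drop=True))


@pytest.fixture(scope="session")
def nl_A(nl_pedigree):
    return build_A(nl_pedigree)


def nuclear_family() -> tuple[Pedigree, pd.DataFrame]:
    """Two parents, two full-sib offspring; markers at 0 and 10 cM."""
    tab = pd.DataFrame({
        "id": ["P1", "P2", "O1", "O2"],
        "sire": [None, None, "P1", "P1"],
        "dam": [None, None, "P2", "P2"],
        "sex": ["M", "F", "M", "F"],
        "cohort": [0, 0, 1, 1],
        "population": ["NL"] * 4,
        "nest": [None, None, "n1", "n1"]})
    snp_map = pd.DataFrame({"snp": ["m1", "m2"], "chrom": ["chr1", "chr1"],
                            "cM": [0.0, 10.0]})
    return Pedigree(tab), snp_map


def make_panel(ids, dosages, snp_map, populations=None) -> GenotypePanel:
    chroms = list(dict.fromkeys(snp_map["chrom"]))
    meta = pd.DataFrame({"chrom": chroms, "size_mbp": 50.0,
                         "gene_count": 500})
    return GenotypePanel(ids=list(ids), dosages=np.asarray(dosages, dtype=float),
                         snp_map=snp_map.reset_index(drop=True),
                         chrom_meta=meta, populations=populations)


def montecarlo_kinship(pedigree: Pedigree, n_rep: int = 200_000, seed: int = 0
                       ) -> np.ndarray:
    """Gene-drop oracle: relationship = 2 x single-locus kinship averaged
    over independent drops of one unlinked locus."""
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    row = {i: k for k, i in enumerate(order)}
    n = len(order)
    lab = np.zeros((n_rep, n, 2), dtype=np.int32)
    counter = 0
    for i in order:
        s, d = pedigree.parents_of(i)
        k = row[i]
        for slot, p in enumerate((s, d)):
            if p is None:
                lab[:, k, slot] = counter
                counter += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                lab[:, k, slot] = lab[np.arange(n_rep), row[p], pick]
    out = np.zeros((n, n))
    for a in range(2):
        for b in range(2):
            out += np.mean(lab[:, :, None, a] == lab[:, None, :, b], axis=0)
    out *= 0.5
    ids = list(pedigree.ids)
    perm = np.array([row[i] for i in ids])
    return out[np.ix_(perm, perm)]
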