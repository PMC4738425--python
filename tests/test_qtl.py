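"""QTL linkage machinery: threshold analytics, IBD sampler vs enumeration
oracle, scan definitions, multi-QTL fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wildqg.qtl import (IbdGrid, LOD_SCALE, ThresholdSpec, _PedigreeIndex,
                        _exceedance_rate, estimate_ibd_grid, lod_thresholds,
                        multi_qtl_fit, prune_by_ld, qtl_scan,
                        simulate_qtl_trait)
from wildqg.relmat import build_A
from wildqg.synthpop import Pedigree, SimConfig, gene_drop, simulate_pedigree

from conftest import make_panel, nuclear_family


class TestThresholds:
    def test_study_map_values(self):
        thr = lod_thresholds(ThresholdSpec(31, 19.16))
        assert thr["nominal"] == 0.588
        assert thr["suggestive"] == 1.620

    def test_exceedance_selfconsistency(self):
        spec = ThresholdSpec(31, 19.16)
        thr = lod_thresholds(spec)
        assert _exceedance_rate(thr["suggestive"], spec) == pytest.approx(
            1.0, abs=0.01)
        assert _exceedance_rate(thr["significant"], spec) == pytest.approx(
            0.05, abs=0.002)

    def test_nominal_is_map_independent(self):
        a = lod_thresholds(ThresholdSpec(5, 3.0))
        b = lod_thresholds(ThresholdSpec(40, 30.0))
        assert a["nominal"] == b["nominal"] == 0.588

    def test_larger_genome_needs_larger_threshold(self):
        small = lod_thresholds(ThresholdSpec(5, 3.0))
        big = lod_thresholds(ThresholdSpec(40, 30.0))
        assert big["suggestive"] > small["suggestive"]
        assert big["significant"] > small["significant"]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(0, 19.16)
        with pytest.raises(ValueError):
            ThresholdSpec(31, -1.0)


def _enumeration_ibd(pedigree, dosages, cm, x, freq=0.5):
    """Brute-force expected IBD at position x given genotypes at two markers:
    sum over all segregation vectors at (L, x, R) and founder allele
    assignments."""
    from wildqg.synthpop import _haldane_r
    pidx = _PedigreeIndex(pedigree)
    n = len(pidx.order)
    n_m = pidx.n_meioses
    r1 = _haldane_r(x - cm[0])
    r2 = _haldane_r(cm[1] - x)
    exp = np.zeros((n, n))
    tot = 0.0

    def lik(seg, col):
        lab = pidx.drop_labels(np.array([seg]))[0]
        p = 0.0
        for alleles in itertools.product([0, 1], repeat=pidx.n_founder_genes):
            okk = True
            for r in range(n):
                g = dosages[r, col]
                if np.isnan(g):
                    continue
                if alleles[lab[r, 0]] + alleles[lab[r, 1]] != g:
                    okk = False
                    break
            if okk:
                p += np.prod([freq if a == 1 else 1 - freq for a in alleles])
        return p

    for sL in itertools.product([0, 1], repeat=n_m):
        for sx in itertools.product([0, 1], repeat=n_m):
            for sR in itertools.product([0, 1], repeat=n_m):
                pr = 0.5 ** n_m
                for a, b in zip(sL, sx):
                    pr *= r1 if a != b else 1 - r1
                for a, b in zip(sx, sR):
                    pr *= r2 if a != b else 1 - r2
                w = pr * lik(sL, 0) * lik(sR, 1)
                if w == 0:
                    continue
                lab = pidx.drop_labels(np.array([sx]))[0]
                sh = np.zeros((n, n))
                for i in range(n):
                    for j in range(n):
                        sh[i, j] = 0.5 * sum(
                            lab[i, a] == lab[j, b]
                            for a in range(2) for b in range(2))
                exp += w * sh
                tot += w
    return exp / tot


class TestIbdSampler:
    def test_founders_only_identity(self):
        tab = pd.DataFrame({"id": ["a", "b"], "sire": [None, None],
                            "dam": [None, None], "sex": ["M", "F"],
                            "cohort": [0, 0], "population": ["NL", "NL"],
                            "nest": [None, None]})
        ped = Pedigree(tab)
        snp_map = pd.DataFrame({"snp": ["m"], "chrom": ["chr1"], "cM": [0.0]})
        panel = make_panel(["a", "b"], [[1.0], [1.0]], snp_map)
        grid = estimate_ibd_grid(ped, panel, grid_step_cM=5.0, n_samples=50)
        np.testing.assert_allclose(grid.matrices[0], np.eye(2))

    def test_matches_enumeration_on_nuclear_family(self):
        """Weighted-particle IBD equals exhaustive enumeration over
        segregation vectors and founder alleles (2-offspring family)."""
        ped, snp_map = nuclear_family()
        dos = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        panel = make_panel(ped.ids, dos, snp_map)
        grid = estimate_ibd_grid(ped, panel, grid_step_cM=5.0,
                                 n_samples=4000, seed=1)
        oracle = _enumeration_ibd(ped, dos, [0.0, 10.0], 5.0)
        k = grid.positions.index[grid.positions["cM"] == 5.0][0]
        np.testing.assert_allclose(grid.matrices[k], oracle, atol=0.02)
        # at the marker itself the sibs share nothing (opposite homozygotes)
        k0 = grid.positions.index[grid.positions["cM"] == 0.0][0]
        idx = {i: r for r, i in enumerate(grid.ids)}
        assert grid.matrices[k0][idx["O1"], idx["O2"]] == pytest.approx(0.0, abs=1e-9)

    def test_far_from_markers_reverts_to_pedigree_expectation(self):
        """With uninformative (missing) marker data the expected IBD is the
        pedigree relationship."""
        ped, snp_map = nuclear_family()
        dos = np.full((4, 2), np.nan)
        panel = make_panel(ped.ids, dos, snp_map)
        grid = estimate_ibd_grid(ped, panel, grid_step_cM=5.0,
                                 n_samples=6000, seed=2)
        A = build_A(ped)
        k = grid.positions.index[grid.positions["cM"] == 5.0][0]
        sub = grid.matrix_at(k).align(A.ids)
        np.testing.assert_allclose(sub, A.values, atol=0.03)

    def test_entries_in_relationship_range(self, nl_pedigree, panel):
        sub_ids = nl_pedigree.ids
        grid = estimate_ibd_grid(nl_pedigree, panel, grid_step_cM=30.0,
                                 n_samples=60, seed=3,
                                 chromosomes=["chr1"])
        for m in grid.matrices:
            assert np.all(m >= -1e-9) and np.all(m <= 2 + 1e-9)
            assert np.all(np.diag(m) >= 1 - 1e-9)


class TestPruneByLd:
    def test_duplicate_column_dropped(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(50, 1)).astype(float)
        d = np.column_stack([base, base, rng.integers(0, 3, size=50)])
        snp_map = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": "chr1",
                                "cM": [0.0, 0.1, 50.0]})
        panel = make_panel([f"i{k}" for k in range(50)], d, snp_map)
        kept = prune_by_ld(panel, r2_cap=0.95)
        assert list(kept) == [0, 2]


@pytest.fixture(scope="module")
def scan_setup(nl_pedigree, panel, nl_A):
    grid = estimate_ibd_grid(nl_pedigree, panel, grid_step_cM=20.0,
                             n_samples=150, seed=4,
                             chromosomes=["chr1", "chr2"])
    return grid


class TestScan:
    def test_lod_is_lrt_over_2ln10(self, scan_setup, nl_pedigree, nl_A):
        rng = np.random.default_rng(5)
        data = simulate_qtl_trait(nl_pedigree, scan_setup, 0, 0.3, nl_A,
                                  0.2, rng)
        scan = qtl_scan("sim", data, scan_setup, nl_A,
                        thresholds={"nominal": 0.588, "suggestive": 1.0,
                                    "significant": 2.0})
        tab = scan.table.dropna()
        np.testing.assert_allclose(tab["lod"], tab["lrt"] / LOD_SCALE)
        assert (tab[["chrom", "cM"]].sort_values(["chrom", "cM"]).index
                == tab.index).all()

    def test_strong_qtl_detected_at_its_position(self, scan_setup,
                                                 nl_pedigree, nl_A):
        rng = np.random.default_rng(6)
        target = 1  # a grid position on chr1
        data = simulate_qtl_trait(nl_pedigree, scan_setup, target, 0.5,
                                  nl_A, 0.1, rng)
        scan = qtl_scan("sim", data, scan_setup, nl_A,
                        thresholds={"nominal": 0.588, "suggestive": 1.0,
                                    "significant": 2.0})
        tab = scan.table.dropna()
        peak = tab.loc[tab["lod"].idxmax()]
        assert peak["chrom"] == scan_setup.positions.iloc[target]["chrom"]

    def test_plot_scan_writes_figure(self, tmp_path, scan_setup, nl_pedigree,
                                     nl_A):
        from wildqg.qtl import plot_scan
        rng = np.random.default_rng(9)
        data = simulate_qtl_trait(nl_pedigree, scan_setup, 0, 0.2, nl_A,
                                  0.2, rng)
        scan = qtl_scan("sim", data, scan_setup, nl_A,
                        thresholds={"nominal": 0.588, "suggestive": 1.0,
                                    "significant": 2.0})
        out = tmp_path / "scan.png"
        plot_scan(scan, out, title="example scan")
        assert out.stat().st_size > 0

    def test_multi_qtl_consistency_and_collinearity(self, scan_setup,
                                                    nl_pedigree, nl_A):
        rng = np.random.default_rng(7)
        data = simulate_qtl_trait(nl_pedigree, scan_setup, 0, 0.4, nl_A,
                                  0.1, rng)
        single = multi_qtl_fit("sim", data, scan_setup, [0], nl_A)
        assert 0.0 <= single["genetic_shares"]["qtl_0"] <= 1.0
        with pytest.raises(ValueError, match="collinear"):
            multi_qtl_fit("sim", data, scan_setup, [0, 0], nl_A)
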