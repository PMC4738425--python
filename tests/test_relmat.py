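"""Relatedness matrices: textbook identities, gene-drop oracle, blending,
cross-population centring."""

import numpy as np
import pandas as pd
import pytest

from wildqg.relmat import (RelatednessMatrix, blend_G_with_pedigree, build_A,
                           build_crosspop_G, build_G, build_qtl_pedigree,
                           read_relmat, relationship_degree, write_relmat)
from wildqg.synthpop import Pedigree, SimConfig, gene_drop, simulate_pedigree

from conftest import make_panel, montecarlo_kinship


def _ped(rows):
    tab = pd.DataFrame(rows, columns=["id", "sire", "dam"])
    tab["sex"] = "M"
    tab["cohort"] = [0 if s is None and d is None else 1
                     for s, d in zip(tab["sire"], tab["dam"])]
    tab["population"] = "NL"
    tab["nest"] = None
    return Pedigree(tab)


class TestBuildA:
    def test_founders_identity(self):
        ped = _ped([("a", None, None), ("b", None, None)])
        A = build_A(ped)
        np.testing.assert_allclose(A.values, np.eye(2))

    def test_textbook_relationships(self):
        ped = _ped([("s", None, None), ("d", None, None), ("d2", None, None),
                    ("c1", "s", "d"), ("c2", "s", "d"), ("h", "s", "d2")])
        A = build_A(ped)
        idx = {i: k for k, i in enumerate(A.ids)}
        assert A.values[idx["s"], idx["c1"]] == pytest.approx(0.5)
        assert A.values[idx["c1"], idx["c2"]] == pytest.approx(0.5)  # full sibs
        assert A.values[idx["c1"], idx["h"]] == pytest.approx(0.25)  # half sibs
        assert A.values[idx["c1"], idx["c1"]] == pytest.approx(1.0)

    def test_inbred_offspring_diagonal(self):
        # full-sib mating: offspring F = 0.25
        ped = _ped([("s", None, None), ("d", None, None),
                    ("c1", "s", "d"), ("c2", "s", "d"), ("x", "c1", "c2")])
        A = build_A(ped)
        idx = {i: k for k, i in enumerate(A.ids)}
        assert A.values[idx["x"], idx["x"]] == pytest.approx(1.25)

    def test_unknown_individual_raises(self):
        ped = _ped([("a", None, None)])
        with pytest.raises(ValueError, match="ghost"):
            build_A(ped, ["ghost"])

    def test_matches_genedrop_oracle_on_random_pedigrees(self):
        """Tabular A equals Monte-Carlo gene-drop kinship x 2 (tol 0.005)."""
        for seed in range(5):
            cfg = SimConfig(n_founders_per_pop=6, n_generations=3,
                            mean_offspring=2, survival_to_breed=0.9,
                            n_snps=10, seed=100 + seed)
            ped = simulate_pedigree(cfg)
            sub = ped.table[ped.table["population"] == "NL"]["id"].tolist()[:8]
            A = build_A(ped, sub)
            tab = ped.table[ped.table["id"].isin(
                set(sub) | set(ped.table["sire"].dropna())
                | set(ped.table["dam"].dropna()))]
            oracle_ped = Pedigree(_close_parents(tab))
            mc = montecarlo_kinship(oracle_ped, n_rep=150_000, seed=seed)
            idx = {i: k for k, i in enumerate(oracle_ped.ids)}
            rows = np.array([idx[i] for i in sub])
            np.testing.assert_allclose(A.values, mc[np.ix_(rows, rows)],
                                       atol=0.006)

    def test_positive_semidefinite(self, pedigree):
        A = build_A(pedigree, pedigree.ids[:150])
        assert np.linalg.eigvalsh(A.values).min() >= -1e-8


def _close_parents(tab):
    tab = tab.copy()
    known = set(tab["id"])
    for col in ("sire", "dam"):
        tab.loc[~tab[col].isin(known), col] = None
    return tab.reset_index(drop=True)


class TestQtlPedigree:
    def test_unrelated_individuals_empty(self):
        ped = _ped([("a", None, None), ("b", None, None), ("c", None, None)])
        out = build_qtl_pedigree(ped, ["a", "b", "c"], max_degree=4)
        assert len(out.table) == 0

    def test_single_family_degree_one(self):
        ped = _ped([("s", None, None), ("d", None, None),
                    ("c1", "s", "d"), ("c2", "s", "d"),
                    ("lone", None, None)])
        out = build_qtl_pedigree(ped, ["c1", "c2", "lone"], max_degree=1)
        assert set(out.table["id"]) >= {"c1", "c2"}
        assert "lone" not in set(out.table["id"])

    def test_membership_matches_degree_enumeration(self, nl_pedigree):
        genotyped = nl_pedigree.ids[: 60]
        out = build_qtl_pedigree(nl_pedigree, genotyped, max_degree=4)
        members = set(out.table["id"])
        for a in genotyped:
            linked = any(
                relationship_degree(nl_pedigree, a, b, max_degree=4) is not None
                for b in genotyped if b != a)
            assert (a in members) == linked


class TestBuildG:
    def test_duplicate_genotypes_look_like_twins(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 400)).astype(float)
        d[4] = d[0]  # duplicate row
        snp_map = pd.DataFrame({"snp": [f"s{i}" for i in range(400)],
                                "chrom": "chr1",
                                "cM": np.linspace(0, 100, 400)})
        panel = make_panel([f"i{k}" for k in range(5)], d, snp_map)
        G = build_G(panel)
        assert G.values[0, 4] == pytest.approx(G.values[0, 0], rel=0.05)

    def test_unrelated_founders_centre_to_zero(self):
        cfg = SimConfig(n_founders_per_pop=120, n_generations=1, n_snps=4000,
                        seed=11)
        ped = simulate_pedigree(cfg)
        panel = gene_drop(ped, cfg)
        nl = [i for i in panel.ids if panel.populations[i] == "NL"]
        G = build_G(panel, nl, freq_source="founder:NL")
        iu = np.triu_indices(len(nl), 1)
        assert abs(G.values[iu].mean()) < 0.01

    def test_monomorphic_markers_rejected(self):
        d = np.zeros((4, 3))
        snp_map = pd.DataFrame({"snp": ["a", "b", "c"], "chrom": "chr1",
                                "cM": [0.0, 1.0, 2.0]})
        panel = make_panel(list("wxyz"), d, snp_map)
        with pytest.raises(ValueError, match="polymorphic"):
            build_G(panel)

    def test_grm_regression_slope_on_A(self, pedigree, panel, nl_ids, nl_A):
        sub = nl_ids[:250]
        A = nl_A.submatrix(sub)
        G = build_G(panel, sub, freq_source="founder:NL", anchor_A=A)
        iu = np.triu_indices(len(sub), 1)
        slope = np.polyfit(A.values[iu], G.values[iu], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.08)


class TestBlend:
    @pytest.fixture()
    def small(self):
        g = np.array([[1.0, 0.2, 0.0], [0.2, 1.1, 0.4], [0.0, 0.4, 0.9]])
        a = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        ids = ["x", "y", "z"]
        return (RelatednessMatrix(g, ids, "G_raw", {"n_markers": 100}),
                RelatednessMatrix(a, ids, "A"))

    @pytest.mark.parametrize("w", [0.0, 0.8, 1.0])
    def test_blend_is_convex_combination(self, small, w):
        G, A = small
        out = blend_G_with_pedigree(G, A, w)
        np.testing.assert_allclose(out.values, w * G.values + (1 - w) * A.values)

    def test_ordering_mismatch_rejected(self, small):
        G, A = small
        bad = RelatednessMatrix(A.values, ["y", "x", "z"], "A")
        with pytest.raises(ValueError, match="ordered"):
            blend_G_with_pedigree(G, bad)


class TestCrosspop:
    def test_independent_populations_centre_between_to_zero(self):
        cfg = SimConfig(n_founders_per_pop=100, n_generations=1, n_snps=3000,
                        between_pop_freq_corr=0.9, seed=12)
        ped = simulate_pedigree(cfg)
        panel = gene_drop(ped, cfg)
        G = build_crosspop_G(panel, blend=False)
        pops = np.array([panel.populations[i] for i in G.ids])
        between = G.values[np.ix_(pops == "NL", pops == "UK")]
        assert abs(between.mean()) < 0.01

    def test_per_population_centring_beats_pooled(self):
        cfg = SimConfig(n_founders_per_pop=100, n_generations=1, n_snps=3000,
                        between_pop_freq_corr=0.7, seed=13)
        ped = simulate_pedigree(cfg)
        panel = gene_drop(ped, cfg)
        Gc = build_crosspop_G(panel, blend=False)
        pops = np.array([panel.populations[i] for i in Gc.ids])
        sel = np.ix_(pops == "NL", pops == "UK")
        pooled = build_G(panel)  # pooled-frequency centring
        assert abs(Gc.values[sel].mean()) < abs(pooled.values[sel].mean())


def test_relmat_text_roundtrip(tmp_path, nl_A):
    sub = nl_A.submatrix(nl_A.ids[:40])
    path = tmp_path / "a.grm.txt"
    write_relmat(path, sub)
    back = read_relmat(path)
    assert back.ids == sub.ids
    np.testing.assert_array_equal(back.values, sub.values)
    assert back.kind == sub.kind
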