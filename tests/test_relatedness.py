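"""Relationship matrices against closed forms and dense-algebra oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from shedeval.io_formats import GenotypeMatrix, build_pedigree
from shedeval.relatedness import (
    RelationshipMatrix,
    a22,
    a_inverse,
    a_matrix,
    blend_g,
    genotype_qc,
    h_inverse,
    inbreeding,
    inverse_of,
    vanraden_g,
)
from shedeval.simulate import SimConfig, simulate_genotypes, simulate_pedigree


class TestAMatrix:
    def test_founders_identity(self):
        ped = build_pedigree(
            pd.DataFrame({"animal": list("abc"), "sire": "", "dam": ""})
        )
        np.testing.assert_allclose(a_matrix(ped).dense(), np.eye(3))

    def test_parent_offspring_half(self, trio_pedigree):
        A = a_matrix(trio_pedigree).dense()
        idx = {a: i for i, a in enumerate(trio_pedigree.animals)}
        assert A[idx["s"], idx["x"]] == 0.5
        assert A[idx["x"], idx["x"]] == 1.0

    def test_fullsib_offspring_diagonal(self, fullsib_inbred_pedigree):
        # Path counting: full sibs c,d have a_cd = 0.5, so their offspring e
        # has F = 0.25 and a_ee = 1.25.
        A = a_matrix(fullsib_inbred_pedigree).dense()
        idx = {a: i for i, a in enumerate(fullsib_inbred_pedigree.animals)}
        assert A[idx["e"], idx["e"]] == pytest.approx(1.25)

    def test_inbreeding_matches_wright_paths(self, fullsib_inbred_pedigree):
        f = inbreeding(fullsib_inbred_pedigree)
        idx = {a: i for i, a in enumerate(fullsib_inbred_pedigree.animals)}
        # Wright: F_e = sum over paths (1/2)^(n+1): two paths c-a-d, c-b-d.
        assert f[idx["e"]] == pytest.approx(0.25)
        assert f[idx["c"]] == 0.0


class TestAInverse:
    def test_founders_identity(self):
        ped = build_pedigree(
            pd.DataFrame({"animal": list("ab"), "sire": "", "dam": ""})
        )
        np.testing.assert_allclose(a_inverse(ped).dense(), np.eye(2))

    def test_trio_closed_form(self, trio_pedigree):
        Ainv = a_inverse(trio_pedigree).dense()
        idx = {a: i for i, a in enumerate(trio_pedigree.animals)}
        s, d, x = idx["s"], idx["d"], idx["x"]
        assert Ainv[s, s] == pytest.approx(1.5)
        assert Ainv[d, d] == pytest.approx(1.5)
        assert Ainv[x, x] == pytest.approx(2.0)
        assert Ainv[s, x] == pytest.approx(-1.0)
        assert Ainv[s, d] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_inverts_tabular_a_on_random_pedigrees(self, seed):
        cfg = SimConfig(n_founders=10, n_generations=2, progeny_per_dam=2, seed=seed)
        ped = simulate_pedigree(cfg)
        assert len(ped) <= 50
        A = a_matrix(ped).dense()
        Ainv = a_inverse(ped).dense()
        np.testing.assert_allclose(Ainv @ A, np.eye(len(A)), atol=1e-8)

    def test_inverts_with_inbreeding(self, fullsib_inbred_pedigree):
        A = a_matrix(fullsib_inbred_pedigree).dense()
        Ainv = a_inverse(fullsib_inbred_pedigree).dense()
        np.testing.assert_allclose(Ainv @ A, np.eye(5), atol=1e-10)


class TestVanRadenG:
    def _geno(self, counts):
        counts = np.asarray(counts, dtype=float)
        n, m = counts.shape
        snps = pd.DataFrame(
            {"snp": [f"s{j}" for j in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1), "a1": "B", "a2": "A"}
        )
        return GenotypeMatrix(pd.Index([f"a{i}" for i in range(n)]), snps, counts)

    def test_hand_case_three_animals_two_snps(self):
        # M rows (0,2),(1,1),(2,0); p=(0.5,0.5); denom = 2*(0.25+0.25) = 1.
        g = vanraden_g(self._geno([[0, 2], [1, 1], [2, 0]]))
        Z = np.array([[-1, 1], [0, 0], [1, -1]], dtype=float)
        np.testing.assert_allclose(g.dense(), Z @ Z.T)

    def test_identical_animals_equal_rows(self):
        g = vanraden_g(self._geno([[0, 1, 2], [0, 1, 2], [2, 1, 0]])).dense()
        np.testing.assert_allclose(g[0], g[1])
        assert g[0, 1] == pytest.approx(g[0, 0])

    def test_centering_identity_rows_sum_zero(self, rng):
        counts = rng.integers(0, 3, size=(12, 40)).astype(float)
        g = vanraden_g(self._geno(counts)).dense()
        np.testing.assert_allclose(g @ np.ones(12), 0.0, atol=1e-10)

    def test_invariant_to_snp_order_and_allele_flip(self, rng):
        counts = rng.integers(0, 3, size=(10, 30)).astype(float)
        base = vanraden_g(self._geno(counts)).dense()
        perm = rng.permutation(30)
        np.testing.assert_allclose(
            vanraden_g(self._geno(counts[:, perm])).dense(), base, atol=1e-12
        )
        np.testing.assert_allclose(
            vanraden_g(self._geno(2.0 - counts)).dense(), base, atol=1e-12
        )

    def test_gene_dropped_kinship_approaches_pedigree_a(self):
        # Oracle: tabular A. More unlinked SNPs -> smaller mean |G - A|.
        # Enough founders that the observed-frequency centering bias is
        # small relative to the marker-sampling noise being tested.
        ped = simulate_pedigree(
            SimConfig(n_founders=60, n_generations=1, progeny_per_dam=2, seed=9)
        )
        A = a_matrix(ped).dense()
        devs = {}
        for n_snps in (100, 3000):
            cfg = SimConfig(n_founders=60, n_generations=1, progeny_per_dam=2,
                            genotyped_fraction=1.0, n_snps=n_snps,
                            maf_range=(0.3, 0.5), seed=9)
            G = vanraden_g(simulate_genotypes(ped, cfg)).dense()
            devs[n_snps] = np.abs(G - A).mean()
        assert devs[3000] < devs[100]
        assert devs[3000] < 0.05


class TestBlendAndH:
    def test_blend_arithmetic(self):
        idx = pd.Index(["a", "b"])
        G = RelationshipMatrix(idx, np.array([[1.0, 0.80], [0.80, 1.0]]), "G")
        A22m = RelationshipMatrix(idx, np.array([[1.0, 0.50], [0.50, 1.0]]), "A22")
        gw = blend_g(G, A22m, weight=0.05).dense()
        assert gw[0, 1] == pytest.approx(0.95 * 0.80 + 0.05 * 0.50)

    def test_blend_weight_limits(self):
        idx = pd.Index(["a", "b"])
        G = RelationshipMatrix(idx, np.array([[1.0, 0.3], [0.3, 1.1]]), "G")
        A22m = RelationshipMatrix(idx, np.array([[1.0, 0.5], [0.5, 1.2]]), "A22")
        np.testing.assert_allclose(blend_g(G, A22m, 0.0).dense(), G.dense())
        np.testing.assert_allclose(blend_g(G, A22m, 1.0).dense(), A22m.dense())

    def test_h_inverse_reduces_to_a_inverse(self, small_pedigree):
        gen = pd.Index(list(small_pedigree.animals[-6:]))
        A22m = a22(small_pedigree, gen)
        hinv = h_inverse(
            a_inverse(small_pedigree), inverse_of(A22m), inverse_of(A22m), gen
        )
        np.testing.assert_allclose(
            hinv.dense(), a_inverse(small_pedigree).dense(), atol=1e-9
        )

    def test_h_inverse_matches_conditional_joint_construction(self):
        """Dense oracle: H built by conditioning non-genotyped animals on
        the genotyped block (textbook single-step joint distribution)."""
        cfg = SimConfig(n_founders=4, n_generations=1, progeny_per_dam=1, seed=7)
        ped = simulate_pedigree(cfg)
        A = a_matrix(ped).dense()
        gidx, nidx = [3, 4, 5], [0, 1, 2]
        Gw = A[np.ix_(gidx, gidx)] * 0.9 + 0.1 * np.eye(3)
        A11, A12 = A[np.ix_(nidx, nidx)], A[np.ix_(nidx, gidx)]
        A22d = A[np.ix_(gidx, gidx)]
        A22i = np.linalg.inv(A22d)
        H11 = A11 + A12 @ A22i @ (Gw - A22d) @ A22i @ A12.T
        H12 = A12 @ A22i @ Gw
        H = np.block([[H11, H12], [H12.T, Gw]])
        gindex = pd.Index(ped.animals[gidx])
        hinv = h_inverse(
            a_inverse(ped),
            RelationshipMatrix(gindex, A22i, "A22_inv"),
            RelationshipMatrix(gindex, np.linalg.inv(Gw), "G_w_inv"),
            gindex,
        )
        Hpkg = np.linalg.inv(hinv.dense())
        order = nidx + gidx
        Horacle = np.empty_like(Hpkg)
        for a, i in enumerate(order):
            for b, j in enumerate(order):
                Horacle[i, j] = H[a, b]
        np.testing.assert_allclose(Hpkg, Horacle, atol=1e-8)

    def test_correction_block_is_linear(self, small_pedigree):
        gen = pd.Index(list(small_pedigree.animals[-5:]))
        A22m = a22(small_pedigree, gen)
        corr = np.eye(5) * 0.2
        a22i = inverse_of(A22m)
        ainv = a_inverse(small_pedigree)
        gw1 = RelationshipMatrix(gen, np.linalg.inv(
            np.linalg.inv(A22m.dense()) + corr), "G_w")
        gw2 = RelationshipMatrix(gen, np.linalg.inv(
            np.linalg.inv(A22m.dense()) + 2 * corr), "G_w")
        d1 = h_inverse(ainv, a22i, inverse_of(gw1), gen).dense() - ainv.dense()
        d2 = h_inverse(ainv, a22i, inverse_of(gw2), gen).dense() - ainv.dense()
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-9)


class TestGenotypeQC:
    def _geno(self, counts, animals=None):
        counts = np.asarray(counts, dtype=float)
        n, m = counts.shape
        snps = pd.DataFrame(
            {"snp": [f"s{j}" for j in range(m)], "chrom": "1",
             "pos": np.arange(1, m + 1), "a1": "B", "a2": "A"}
        )
        idx = pd.Index(animals or [f"a{i}" for i in range(n)])
        return GenotypeMatrix(idx, snps, counts)

    def _ped(self, animals):
        return build_pedigree(
            pd.DataFrame({"animal": animals, "sire": "", "dam": ""})
        )

    def test_monomorphic_snp_dropped(self):
        g = self._geno([[2, 0], [2, 1], [2, 2], [2, 0]])
        out, report, _ = genotype_qc(g, self._ped(["a0", "a1", "a2", "a3"]))
        assert list(out.snps["snp"]) == ["s1"]
        assert (report.dropped_snps["reason"] == "monomorphic").any()

    def test_low_call_rate_animal_dropped(self, rng):
        counts = rng.integers(0, 3, size=(10, 10)).astype(float)
        counts[0, :2] = np.nan  # animal call rate 80%, SNP call rates 90%
        g = self._geno(counts)
        out, report, _ = genotype_qc(g, self._ped([f"a{i}" for i in range(10)]))
        assert "a0" in set(report.dropped_animals["animal"])
        assert "a0" not in set(out.animals)

    def test_opposing_homozygotes_unlink_parent(self):
        # Child 2 vs parent 0 at 5 of 100 SNPs: rate 5% > 2%.
        rng = np.random.default_rng(0)
        child = rng.integers(0, 3, size=100).astype(float)
        parent = child.copy()
        hets = np.where(child == 1)[0]
        parent[hets] = 1.0
        opp = np.where(child != 1)[0][:5]
        child[opp] = 2.0
        parent[opp] = 0.0
        other = rng.integers(0, 3, size=100).astype(float)
        g = self._geno(np.vstack([parent, child, other]),
                       ["p", "c", "x"])
        ped = build_pedigree(
            pd.DataFrame({"animal": ["p", "c", "x"], "sire": ["", "p", ""],
                          "dam": ["", "", ""]})
        )
        out, report, ped_qc = genotype_qc(g, ped)
        assert list(report.unlinked_parents["animal"]) == ["c"]
        row = ped_qc.table.set_index("animal").loc["c"]
        assert row["sire"] == ""

    def test_empty_after_qc_raises(self):
        g = self._geno([[2, 2], [2, 2]])
        with pytest.raises(ValueError):
            genotype_qc(g, self._ped(["a0", "a1"]))
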