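"""Filters, diversity estimators, Weir-Cockerham theta and genotype PCA
against hand enumerations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landgen.genio import MISSING, RunConfig
from landgen.popstats import (
    allele_freq_table,
    diversity,
    filter_snps,
    genotype_pca,
    multilocus_theta,
    pairwise_fst,
    _pop_counts,
)
from landgen.synthdata import balding_nichols_freqs

from conftest import make_genotypes
from oracles import ho_he_fis, pi_pairwise, wc_theta


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def _filter_fixture():
    """10 loci, 10 diploids in two populations; exactly four loci violate
    exactly one rule each (linked second SNP, presence, MAF, het excess)."""
    n = 10
    pops = ["A"] * 5 + ["B"] * 5
    clean = [0, 0, 1, 1, 2, 2, 0, 1, 2, 0]          # MAF 0.45, het 0.3
    loci = {
        "dup":      (list(clean), "tA", 42),         # second SNP on tag tA
        "keep_a":   (list(clean), "tA", 10),
        "presence": (clean[:7] + [MISSING] * 3, "tB", 10),   # 70 % presence
        "maf":      ([0] * 10, "tC", 10),            # monomorphic, MAF 0
        "het":      ([1] * 6 + [0, 0, 2, 2], "tD", 10),      # H_O = 0.6
        "keep_b":   ([0, 1, 1, 0, 2, 0, 1, 2, 0, 1], "tE", 10),
        "keep_c":   ([2, 2, 1, 0, 0, 1, 2, 0, 1, 0], "tF", 10),
        "keep_d":   ([0, 0, 0, 1, 1, 2, 0, 1, 0, 2], "tG", 10),
        "keep_e":   ([1, 0, 2, 0, 1, 0, 2, 1, 0, 0], "tH", 10),
        "keep_f":   ([0, 2, 0, 1, 0, 1, 0, 0, 2, 1], "tI", 10),
    }
    d = np.array([v[0] for v in loci.values()]).T
    chrom = [v[1] for v in loci.values()]
    pos = [v[2] for v in loci.values()]
    return make_genotypes(d, pops=pops, chrom=chrom, pos=pos), list(loci)


def _toy_cfg(**kw):
    base = dict(min_populations=2, min_individual_presence=0.85)
    base.update(kw)
    return RunConfig(**base)


class TestFilter:
    def test_enumerated_fixture_counts(self):
        g, names = _filter_fixture()
        filt, rep = filter_snps(g, _toy_cfg())
        assert rep.n_kept == 6
        assert (
            rep.removed_first_snp, rep.removed_presence,
            rep.removed_maf, rep.removed_het,
        ) == (1, 1, 1, 1)
        kept_tags = set(filt.locus_chrom)
        assert kept_tags == {"tA", "tE", "tF", "tG", "tH", "tI"}

    def test_low_maf_locus_removed(self):
        # MAF 0.04 < 0.05: 2 alt alleles among 50
        d = np.zeros((25, 2), dtype=int)
        d[0, 0] = 2
        d[:, 1] = [0, 1] * 12 + [2]
        g = make_genotypes(d, pops=["A"] * 13 + ["B"] * 12)
        filt, rep = filter_snps(g, _toy_cfg())
        assert rep.removed_maf == 1 and filt.n_loci == 1

    def test_idempotent_on_clean_matrix(self):
        g, _ = _filter_fixture()
        filt, _ = filter_snps(g, _toy_cfg())
        again, rep = filter_snps(filt, _toy_cfg())
        np.testing.assert_array_equal(again.dosages, filt.dosages)
        assert rep.n_kept == filt.n_loci

    def test_empty_result_raises(self):
        d = np.zeros((4, 1), dtype=int)     # monomorphic single locus
        g = make_genotypes(d, pops=["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="threshold"):
            filter_snps(g, _toy_cfg())


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


class TestDiversity:
    def test_pi_two_diploids_enumeration(self):
        """Genotypes {0, 2}: 4 of 6 allele pairs differ, pi = 2/3."""
        g = make_genotypes([[0], [2]])
        d = diversity(g)
        assert d.pi[0] == pytest.approx(pi_pairwise([0, 2]))
        assert d.pi[0] == pytest.approx(2 / 3)

    def test_all_heterozygous_ho_one(self):
        g = make_genotypes([[1], [1], [1]])
        d = diversity(g)
        assert d.ho[0] == 1.0

    def test_monomorphic_site_contributes_zero(self):
        g = make_genotypes([[0, 1], [0, 1]])
        d = diversity(g)
        # pi averaged over both sites: (0 + pi_site2) / 2
        assert d.pi[0] == pytest.approx(pi_pairwise([1, 1]) / 2)

    @given(st.lists(
        st.lists(st.integers(0, 2), min_size=5, max_size=5),
        min_size=2, max_size=4,
    ))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force(self, columns):
        if all(sum(c) in (0, 10) for c in columns):
            return
        g = make_genotypes(np.array(columns).T)
        d = diversity(g)
        ho, he, fis = ho_he_fis(columns)
        assert d.ho[0] == pytest.approx(ho, abs=1e-10)
        assert d.he[0] == pytest.approx(he, abs=1e-10)
        if he > 0:
            assert d.fis[0] == pytest.approx(fis, abs=1e-10)

    def test_insufficient_alleles_reported_missing(self):
        d = np.array([[0, 1], [MISSING, MISSING]], dtype=np.int16)
        g = make_genotypes(d, pops=["A", "B"])
        stats = diversity(g)
        assert np.isnan(stats.pi[1])


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


class TestFst:
    def test_fixed_difference_theta_one(self):
        d = np.array([[0] * 4, [0] * 4, [0] * 4, [2] * 4, [2] * 4])
        g = make_genotypes(d, pops=["A", "A", "A", "B", "B"])
        fst = pairwise_fst(g)
        assert fst.theta[0, 1] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        col = [0, 1, 2, 1]
        d = np.tile(np.array(col * 2).reshape(-1, 1), (1, 3))
        g = make_genotypes(d, pops=["A"] * 4 + ["B"] * 4)
        fst = pairwise_fst(g)
        expect = wc_theta([
            [col, col, col],
            [col, col, col],
        ])
        assert fst.theta[0, 1] <= 0
        assert fst.theta[0, 1] == pytest.approx(expect, abs=1e-10)

    def test_three_population_toy_matches_oracle(self):
        rng = np.random.default_rng(11)
        cols = rng.integers(0, 3, size=(12, 6))
        pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        g = make_genotypes(cols, pops=pops)
        fst = pairwise_fst(g)
        for (i, pa), (j, pb) in [((0, "A"), (1, "B")), ((0, "A"), (2, "C")),
                                 ((1, "B"), (2, "C"))]:
            sel_a = [k for k, p in enumerate(pops) if p == pa]
            sel_b = [k for k, p in enumerate(pops) if p == pb]
            expect = wc_theta([
                [list(cols[sel_a, s]) for s in range(6)],
                [list(cols[sel_b, s]) for s in range(6)],
            ])
            assert fst.theta[i, j] == pytest.approx(expect, abs=1e-10)

    def test_individual_reordering_invariance(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(10, 20))
        pops = ["A", "B"] * 5
        g = make_genotypes(d, pops=pops)
        perm = rng.permutation(10)
        g2 = g.take_individuals(perm)
        f1, f2 = pairwise_fst(g), pairwise_fst(g2)
        i = list(f2.pops).index("A")
        j = list(f2.pops).index("B")
        assert f1.theta[0, 1] == pytest.approx(f2.theta[i, j], abs=1e-12)
        d1, d2 = diversity(g), diversity(g2)
        np.testing.assert_allclose(
            sorted(d1.pi), sorted(d2.pi), atol=1e-12
        )

    def test_zero_overlap_pair_missing(self):
        d = np.array(
            [[0, MISSING], [1, MISSING], [MISSING, 1], [MISSING, 2]],
            dtype=np.int16,
        )
        g = make_genotypes(d, pops=["A", "A", "B", "B"])
        fst = pairwise_fst(g)
        assert np.isnan(fst.theta[0, 1])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPca:
    def test_separated_groups_no_score_overlap(self):
        rng = np.random.default_rng(1)
        p = balding_nichols_freqs(rng.uniform(0.2, 0.8, 300), 0.3, 2, rng)
        d = np.vstack([
            rng.binomial(2, p[0], size=(15, 300)),
            rng.binomial(2, p[1], size=(15, 300)),
        ])
        g = make_genotypes(d, pops=["A"] * 15 + ["B"] * 15)
        res = genotype_pca(g)
        a = res.scores[:15, 0]
        b = res.scores[15:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or \
            min(a.max(), b.max()) < max(a.min(), b.min())
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicated_individuals_identical_scores(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(6, 40))
        d = np.vstack([d, d[0]])
        g = make_genotypes(d, pops=["A"] * 7)
        res = genotype_pca(g)
        np.testing.assert_allclose(res.scores[0], res.scores[6], atol=1e-9)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 50))
        g = make_genotypes(d)
        res = genotype_pca(g)
        assert res.var_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.var_fractions) <= 1e-12)

    def test_too_many_components_rejected(self):
        g = make_genotypes(np.random.default_rng(0).integers(0, 3, (5, 20)))
        with pytest.raises(ValueError):
            genotype_pca(g, n_components=5)
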