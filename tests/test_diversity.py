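"""Pi, Dxy, Hudson FST, haplotype PCA, inversion frequencies."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from museomics.datamodel import AlleleCounts, SampleMeta, allele_counts, downsample_counts
from museomics.diversity import (
    diversity_matrix,
    dxy,
    fst,
    inversion_contrast,
    inversion_frequency,
    minor_allele_haplotypes,
    nucleotide_diversity,
    pca_haplotypes,
    per_site_pi,
)

from conftest import matrix_for


def counts(ref, alt, positions=None):
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    pos = (
        np.asarray(positions, dtype=np.int64)
        if positions is not None
        else np.arange(1, len(ref) + 1) * 100
    )
    return AlleleCounts("2L", pos, ref, alt, np.ones(len(ref), dtype=bool))


class TestPi:
    def test_monomorphic_zero(self):
        assert nucleotide_diversity(counts([4, 4], [0, 0])) == 0.0

    def test_unbiased_closed_form(self):
        # n=4, counts (2,2): 2 * 0.25 * 4/3
        assert per_site_pi(counts([2], [2]))[0] == pytest.approx(2 / 3)

    def test_matches_pairwise_hamming_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 9))
            alt = int(rng.integers(0, n + 1))
            alleles = [1] * alt + [0] * (n - alt)
            pairs = list(itertools.combinations(range(n), 2))
            oracle = np.mean([alleles[i] != alleles[j] for i, j in pairs])
            got = per_site_pi(counts([n - alt], [alt]))[0]
            assert got == pytest.approx(oracle)

    def test_downsampling_preserves_expected_pi(self):
        # hypergeometric 4-allele downsampling is unbiased for pi
        rng = np.random.default_rng(7)
        n_rep = 4000
        ref = np.full(n_rep, 7)
        alt = np.full(n_rep, 3)
        full_pi = per_site_pi(counts(ref[:1], alt[:1]))[0]
        ref4, alt4 = downsample_counts(ref, alt, 4, seed=rng)
        down_pi = per_site_pi(counts(ref4, alt4))
        se = np.nanstd(down_pi) / math.sqrt(n_rep)
        assert abs(np.nanmean(down_pi) - full_pi) < 3 * se


class TestDxy:
    def test_identical_fixed(self):
        assert dxy(counts([4], [0]), counts([6], [0])) == 0.0

    def test_fixed_difference(self):
        assert dxy(counts([4], [0]), counts([0], [6])) == 1.0

    def test_half_half(self):
        assert dxy(counts([2], [2]), counts([3], [3])) == pytest.approx(0.5)

    def test_disjoint_sites_rejected(self):
        a = counts([4], [0], positions=[100])
        b = counts([4], [0], positions=[200])
        with pytest.raises(ValueError, match="no usable sites"):
            dxy(a, b)

    def test_nonnegative_property(self):
        rng = np.random.default_rng(3)
        n = rng.integers(2, 10, 200)
        ka = rng.binomial(n, 0.3)
        kb = rng.binomial(n, 0.6)
        val = dxy(counts(n - ka, ka), counts(n - kb, kb))
        assert val >= 0


class TestFst:
    def test_equal_frequencies_near_zero(self):
        a = counts([5, 3, 6], [5, 7, 4])
        b = counts([5, 3, 6], [5, 7, 4])
        assert fst(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_approach_one(self):
        a = counts([200] * 10, [0] * 10)
        b = counts([0] * 10, [200] * 10)
        assert fst(a, b) > 0.99

    def test_two_site_hand_computation(self):
        # direct evaluation of Hudson's estimator on a small case
        a = counts([6, 2], [2, 6])  # n=8, p = 0.25, 0.75
        b = counts([3, 5], [5, 3])  # n=8, p = 0.625, 0.375
        def site(pa, pb, na, nb):
            num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
            den = pa * (1 - pb) + pb * (1 - pa)
            return num, den
        n1, d1 = site(0.25, 0.625, 8, 8)
        n2, d2 = site(0.75, 0.375, 8, 8)
        assert fst(a, b) == pytest.approx(max(0.0, (n1 + n2) / (d1 + d2)))

    def test_windowed_ratio_of_sums(self):
        a = counts([6, 2, 8, 1], [2, 6, 0, 7])
        b = counts([3, 5, 1, 8], [5, 3, 7, 0])
        window_of = {100: 0, 200: 0, 300: 1, 400: 1}
        vals = fst(a, b, window_of, 2)
        assert vals.shape == (2,)
        assert np.isfinite(vals).all()

    def test_bounded_by_dxy_toy_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = 20
            ka = rng.integers(1, n, 3)
            kb = rng.integers(1, n, 3)
            a = counts([n - k for k in ka], list(ka))
            b = counts([n - k for k in kb], list(kb))
            assert fst(a, b) <= 1.0
            assert dxy(a, b) >= 0.0


class TestPcaHaplotypes:
    def test_component_count_matches_haplotypes(self):
        rng = np.random.default_rng(2)
        H = rng.integers(0, 2, (35, 400))  # 5 haplotypes x 7 populations
        loadings, eigvals = pca_haplotypes(H)
        assert loadings.shape == (35, 35)
        assert eigvals.shape == (35,)
        assert np.all(np.diff(eigvals) <= 1e-9)

    def test_identical_haplotypes_identical_loadings(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 2, 300)
        H = np.vstack([base, base, rng.integers(0, 2, (4, 300))])
        loadings, eigvals = pca_haplotypes(H)
        # identical on every non-degenerate component (the null-space
        # component with eigenvalue 0 is exactly their contrast)
        keep = eigvals > 1e-8
        assert np.allclose(loadings[0, keep], loadings[1, keep], atol=1e-8)

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        n_sites = 500
        fa = rng.beta(2, 2, n_sites)
        fb = np.clip(fa + rng.choice([-0.4, 0.4], n_sites), 0.02, 0.98)
        ha = (rng.random((10, n_sites)) < fa).astype(int)
        hb = (rng.random((10, n_sites)) < fb).astype(int)
        H = minor_allele_haplotypes(np.vstack([ha, hb]))
        loadings, _ = pca_haplotypes(H)
        pc1 = loadings[:, 0]
        assert len(set(np.sign(pc1[:10]))) == 1
        assert len(set(np.sign(pc1[10:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[10])

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            pca_haplotypes(np.ones((5, 4)))


class TestInversionFrequency:
    def _panel(self, n=20):
        return pd.DataFrame(
            {
                "inversion": "In(3R)P",
                "chrom": "3R",
                "pos": np.arange(1, n + 1) * 100,
                "linked_allele": "alt",
            }
        )

    def test_absent_inversion_median_zero(self):
        # 4 of 20 markers at low frequency: median 0, mean > 0
        panel = self._panel()
        freqs = {("3R", int(p)): 0.0 for p in panel["pos"]}
        for p in list(panel["pos"])[:4]:
            freqs[("3R", int(p))] = 0.05
        est = inversion_frequency(panel, freqs)
        assert est["In(3R)P"] == 0.0
        assert np.mean(list(freqs.values())) > 0

    def test_consistent_markers(self):
        panel = self._panel()
        freqs = {("3R", int(p)): 0.13 for p in panel["pos"]}
        assert inversion_frequency(panel, freqs)["In(3R)P"] == pytest.approx(0.13)

    def test_missing_markers_dropped(self):
        panel = self._panel(4)
        freqs = {("3R", 100): 0.5, ("3R", 200): 0.5}
        assert inversion_frequency(panel, freqs)["In(3R)P"] == pytest.approx(0.5)


class TestInversionContrast:
    def test_balanced_table(self):
        assert inversion_contrast((5, 5), (5, 5)) == pytest.approx(1.0)

    def test_extreme_table_hypergeometric(self):
        # 2 / C(20,10): only the two perfectly sorted tables are as extreme
        want = 2 / math.comb(20, 10)
        assert inversion_contrast((10, 0), (0, 10)) == pytest.approx(want, rel=1e-6)

    def test_cross_oracle_random_tables(self):
        # independent oracle: enumerate the hypergeometric support directly
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, 4)
            n = a + b + c + d
            if n == 0 or (a + b) == 0 or (c + d) == 0:
                continue
            row1, col1 = a + b, a + c
            support = range(max(0, col1 - (c + d)), min(row1, col1) + 1)
            def prob(x):
                return (
                    math.comb(row1, x)
                    * math.comb(n - row1, col1 - x)
                    / math.comb(n, col1)
                )
            p_obs = prob(a)
            oracle = sum(prob(x) for x in support if prob(x) <= p_obs * (1 + 1e-12))
            assert inversion_contrast((a, b), (c, d)) == pytest.approx(
                oracle, rel=1e-8
            )


class TestDiversityMatrix:
    def test_layout(self):
        pops = {
            "p1": counts([4, 2], [0, 2]),
            "p2": counts([1, 3], [3, 1]),
        }
        tab = diversity_matrix(pops)
        assert tab.loc["p1", "p1"] == pytest.approx(
            nucleotide_diversity(pops["p1"])
        )
        assert tab.loc["p1", "p2"] == pytest.approx(dxy(pops["p1"], pops["p2"]))
        assert tab.loc["p2", "p1"] == pytest.approx(fst(pops["p1"], pops["p2"]))
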