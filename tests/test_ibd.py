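"""IBD detection: distances, rescaling, thresholds, masking."""

import numpy as np
import pytest

from museomics.datamodel import (
    MaskTrack,
    SampleMeta,
    WindowSet,
    allele_counts,
    build_windows,
)
from museomics.ibd import (
    DistanceWindowMatrix,
    IBDCall,
    build_mask,
    classify_inbreeding,
    classify_relatedness,
    detect_ibd,
    ibd_summary,
    rescale_and_baseline,
    window_distances,
)

from conftest import matrix_for


def _simple_windows(n_windows=1, width=10_000):
    bounds = np.array(
        [[i * width, (i + 1) * width] for i in range(n_windows)], dtype=np.int64
    )
    return WindowSet("2L", bounds, 100, np.full(n_windows, 100))


def _metas(ids, **kw):
    return {s: SampleMeta(s, era="e", **kw) for s in ids}


class TestWindowDistances:
    def test_identical_homozygous_diploids_distance_zero(self):
        metas = _metas(["a", "b", "o1", "o2"])
        calls = np.tile(np.array([[2, 2, 0, 2]], dtype=np.int8), (20, 1))
        calls[::2, :2] = 0  # identical hom genotypes, mixed ref/alt
        m = matrix_for(metas, "2L", calls)
        dwm = window_distances(m, _simple_windows(), ["a", "b"], ["o1", "o2"])
        assert dwm.d[0, 0, 1] == pytest.approx(0.0)

    def test_hom_vs_het_half(self):
        # A/A vs A/T: 2 of 4 cross-pairs mismatch
        metas = _metas(["a", "b", "o1"])
        calls = np.tile(np.array([[0, 1, 0]], dtype=np.int8), (10, 1))
        m = matrix_for(metas, "2L", calls)
        dwm = window_distances(m, _simple_windows(), ["a", "b"], ["o1"])
        assert dwm.d[0, 0, 1] == pytest.approx(0.5)

    def test_haploid_vs_het_diploid_half(self):
        # haploid A vs diploid A/T: 1 of 2 cross-pairs mismatch
        metas = {
            "h": SampleMeta("h", era="e", quality_tier="low"),
            "d": SampleMeta("d", era="e"),
            "o": SampleMeta("o", era="e"),
        }
        calls = np.tile(np.array([[0, 1, 0]], dtype=np.int8), (10, 1))
        m = matrix_for(metas, "2L", calls)
        dwm = window_distances(m, _simple_windows(), ["h", "d"], ["o"])
        assert dwm.d[0, 0, 1] == pytest.approx(0.5)

    def test_empty_outgroup_rejected(self):
        metas = _metas(["a", "b"])
        m = matrix_for(metas, "2L", np.zeros((5, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="outgroup"):
            window_distances(m, _simple_windows(), ["a", "b"], [])

    def test_scaling_factor_ratio(self):
        # sample with doubled background distance gets m = 2 x the others'
        metas = _metas(["a", "b", "c", "o"])
        rng = np.random.default_rng(0)
        n = 2000
        calls = np.zeros((n, 4), dtype=np.int8)
        # a,b match the outgroup except 10% of sites; c mismatches 20%
        base_mismatch = rng.random(n) < 0.1
        calls[base_mismatch, 0] = 2
        calls[base_mismatch, 1] = 2
        extra = rng.random(n) < 0.2
        calls[:, 2] = np.where(extra, 2, 0)
        m = matrix_for(metas, "2L",
                       calls, positions=np.arange(1, n + 1) * 10)
        ws = WindowSet("2L", np.array([[0, n * 10 + 10]]), n, np.array([n]))
        dwm = rescale_and_baseline(
            window_distances(m, ws, ["a", "b", "c"], ["o"])
        )
        assert dwm.m[0, 2] / dwm.m[0, 0] == pytest.approx(2.0, rel=0.15)


class TestClassifyRelatedness:
    def _dwm(self, pair_value, ploidy):
        # 6 focal genomes, all pairwise distances 0.2 except pair (0,1)
        nf = 6
        d = np.full((1, nf, nf), 0.2)
        np.fill_diagonal(d[0], 0.0)
        d[0, 0, 1] = d[0, 1, 0] = pair_value
        dwm = DistanceWindowMatrix(
            chromosome="2L",
            windows=_simple_windows(),
            focal_samples=[f"s{i}" for i in range(nf)],
            focal_ploidy=np.array(ploidy, dtype=np.int8),
            d=d,
            d_bg=np.full((1, nf), 0.3),
            bg_all_median=np.array([0.3]),
        )
        return rescale_and_baseline(dwm)

    def test_diploid_pair_below_seven_eighths_flagged(self):
        dwm = self._dwm(0.16, [2] * 6)  # D' = 0.80 D
        calls = classify_relatedness(dwm)
        assert {(c.sample_a, c.sample_b) for c in calls} == {("s0", "s1")}

    def test_diploid_pair_above_threshold_not_flagged(self):
        dwm = self._dwm(0.18, [2] * 6)  # D' = 0.90 D
        assert classify_relatedness(dwm) == []

    def test_haploid_pair_uses_half_threshold(self):
        dwm = self._dwm(0.12, [1, 1, 2, 2, 2, 2])  # D' = 0.60 D, threshold 0.5
        assert classify_relatedness(dwm) == []
        dwm = self._dwm(0.08, [1, 1, 2, 2, 2, 2])  # D' = 0.40 D
        calls = classify_relatedness(dwm)
        assert {(c.sample_a, c.sample_b) for c in calls} == {("s0", "s1")}

    def test_haploid_diploid_uses_three_quarters(self):
        dwm = self._dwm(0.16, [1, 2, 2, 2, 2, 2])  # 0.80 D > 3/4
        assert classify_relatedness(dwm) == []
        dwm = self._dwm(0.14, [1, 2, 2, 2, 2, 2])  # 0.70 D < 3/4
        assert len(classify_relatedness(dwm)) == 1

    def test_baseline_iteration_excludes_flagged_pair(self):
        # one very close pair drags the naive median; iteration restores D
        dwm = self._dwm(0.02, [2] * 6)
        assert dwm.baseline[0] == pytest.approx(0.2, rel=0.01)
        assert dwm.flagged[0, 0, 1]


class TestExpectedDistanceLaw:
    def test_one_haplotype_ibd_ratio_three_quarters(self):
        # mean distance of one-haplotype-IBD pairs / unrelated pairs -> 3/4;
        # the decision threshold sits at the 7/8 midpoint
        rng = np.random.default_rng(42)
        n = 100_000
        p = rng.beta(0.5, 0.5, n)
        h = rng.random((5, n)) < p  # haplotypes; pair A=(0,1), B=(1,2) share 1
        pa = (h[0].astype(float) + h[1]) / 2
        pb = (h[1].astype(float) + h[2]) / 2
        pc = (h[3].astype(float) + h[4]) / 2
        d_shared = np.mean(pa + pb - 2 * pa * pb)
        d_unrel = np.mean(pa + pc - 2 * pa * pc)
        assert d_shared / d_unrel == pytest.approx(0.75, abs=0.01)


class TestClassifyInbreeding:
    def _matrix(self, het_fraction):
        metas = _metas(["a"])
        n = 200
        calls = np.zeros((n, 1), dtype=np.int8)
        k = int(round(het_fraction * n))
        calls[:k, 0] = 1
        return matrix_for(metas, "2L", calls,
                          positions=np.arange(1, n + 1) * 10)

    def test_fully_homozygous_flagged(self):
        ws = WindowSet("2L", np.array([[0, 3000]]), 200, np.array([200]))
        calls = classify_inbreeding(self._matrix(0.0), ws, np.array([0.2]))
        assert len(calls) == 1 and calls[0].kind == "inbreeding"
        assert calls[0].masked_allele in (0, 1)

    def test_heterozygosity_at_pi_not_flagged(self):
        ws = WindowSet("2L", np.array([[0, 3000]]), 200, np.array([200]))
        assert classify_inbreeding(self._matrix(0.2), ws, np.array([0.2])) == []

    def test_heterozygosity_well_below_pi_flagged(self):
        ws = WindowSet("2L", np.array([[0, 3000]]), 200, np.array([200]))
        calls = classify_inbreeding(self._matrix(0.08), ws, np.array([0.2]))
        assert len(calls) == 1  # 0.4 pi < pi/2

    def test_haploids_skipped(self):
        metas = {"h": SampleMeta("h", era="e", quality_tier="low")}
        m = matrix_for(metas, "2L", np.zeros((50, 1), dtype=np.int8))
        ws = WindowSet("2L", np.array([[0, 6000]]), 50, np.array([50]))
        assert classify_inbreeding(m, ws, np.array([0.2])) == []


class TestBuildMask:
    def _windows(self):
        return WindowSet(
            "2L",
            np.array([[0, 100], [100, 200], [200, 300]], dtype=np.int64),
            10,
            np.full(3, 10),
        )

    def test_flank_half_windows(self):
        metas = _metas(["a", "b"])
        call = IBDCall("relatedness", 1, "a", "b", 0.1, 0.15, chromosome="2L")
        track = build_mask([call], self._windows(), metas)
        rec = track.records[0]
        assert (rec.start, rec.end) == (50, 250)  # mid(w0) .. mid(w2)

    def test_first_window_extends_downstream_only(self):
        metas = _metas(["a", "b"])
        call = IBDCall("relatedness", 0, "a", "b", 0.1, 0.15, chromosome="2L")
        rec = build_mask([call], self._windows(), metas).records[0]
        assert (rec.start, rec.end) == (0, 150)

    def test_low_quality_member_preferred(self):
        metas = {
            "hi": SampleMeta("hi", era="e"),
            "lo": SampleMeta("lo", era="e", quality_tier="low"),
        }
        call = IBDCall("relatedness", 1, "hi", "lo", 0.1, 0.15, chromosome="2L")
        rec = build_mask([call], self._windows(), metas).records[0]
        assert rec.sample_id == "lo"

    def test_repeat_offender_masked_again(self):
        metas = _metas(["a", "b", "c"])
        calls = [
            IBDCall("relatedness", 0, "a", "b", 0.1, 0.15, chromosome="2L"),
            IBDCall("relatedness", 1, "b", "c", 0.1, 0.15, chromosome="2L"),
        ]
        track = build_mask(calls, self._windows(), metas)
        # window 0: lexicographic tie-break masks "b"; window 1: "b" again
        assert {r.sample_id for r in track.records} == {"b"}

    def test_inbreeding_masks_one_allele(self):
        metas = _metas(["a"])
        call = IBDCall("inbreeding", 1, "a", None, 0.01, 0.1,
                       masked_allele=0, chromosome="2L")
        rec = build_mask([call], self._windows(), metas).records[0]
        assert rec.alleles_masked == "one" and rec.kind == "inbreeding"


class TestPlantedPedigreeRecovery:
    def _detect(self, cohort):
        config, matrices, metas, truth = cohort
        matrix = matrices["2L"]
        windows = build_windows(
            matrix.positions, config.ibd_segment_sites, "2L", matrix.length
        )
        focal = [s for s in matrix.samples if metas[s].era == "1800s"]
        outgroup = [s for s in matrix.samples if metas[s].era == "1933"]
        calls, mask, dwm = detect_ibd(
            matrix, windows, focal, outgroup, metas, seed=0
        )
        return config, matrix, metas, truth, windows, calls, mask, dwm

    def test_sib_windows_detected(self, sib_cohort):
        config, matrix, metas, truth, windows, calls, mask, dwm = self._detect(
            sib_cohort
        )
        segs = truth.segments_for_pair("1800s_00", "1800s_01", "2L")
        assert segs
        # segments are planted in units of ibd_segment_sites = window content,
        # so each segment maps to exactly one window
        shared_windows = {s.start_idx // config.ibd_segment_sites for s in segs}
        flagged = {
            c.window
            for c in calls
            if c.kind == "relatedness"
            and {c.sample_a, c.sample_b} == {"1800s_00", "1800s_01"}
        }
        hit = len(shared_windows & flagged) / len(shared_windows)
        assert hit >= 0.95

    def test_no_pedigree_specificity(self, plain_cohort):
        config, matrix, metas, truth, windows, calls, mask, dwm = self._detect(
            plain_cohort
        )
        rel = [c for c in calls if c.kind == "relatedness"]
        n_pairs = 8 * 7 // 2
        rate = len(rel) / (n_pairs * windows.n_windows)
        assert rate < 0.01

    def test_masking_restores_unrelated_frequencies(self, sib_cohort):
        config, matrix, metas, truth, windows, calls, mask, dwm = self._detect(
            sib_cohort
        )
        focal = [s for s in matrix.samples if metas[s].era == "1800s"]
        idx = [matrix.sample_index(s) for s in focal]
        from museomics.datamodel import GenotypeMatrix

        sub = GenotypeMatrix(
            chromosome="2L", positions=matrix.positions.copy(),
            ref=matrix.ref.copy(), alt=matrix.alt.copy(),
            calls=matrix.calls[:, idx], samples=focal,
            ploidy=matrix.ploidy[idx], length=matrix.length,
        )
        got = allele_counts(sub, mask)
        # oracle: drop the masked member over the planted truth segments
        from museomics.datamodel import MaskRecord

        oracle_track = MaskTrack()
        for s in truth.segments_for_pair("1800s_00", "1800s_01", "2L"):
            oracle_track.add(MaskRecord("1800s_01", "2L", s.start, s.end,
                                        "relatedness", "all"))
        want = allele_counts(sub, oracle_track)
        ok = got.usable & want.usable
        diff = np.abs(got.frequencies()[ok] - want.frequencies()[ok])
        assert np.nanmean(diff) < 0.05


class TestIbdSummary:
    def test_no_calls_all_zero(self):
        metas = _metas(["a", "b"])
        ws = WindowSet("2L", np.array([[0, 1000]]), 10, np.array([10]))
        sample_tab, pair_tab = ibd_summary(
            [], MaskTrack(), {"2L": ws}, {"2L": 1000}, metas
        )
        assert (sample_tab["genome_fraction"] == 0).all()
        assert pair_tab.empty

    def test_whole_chromosome_pair(self):
        metas = _metas(["a", "b"])
        ws = WindowSet(
            "2L", np.array([[0, 500], [500, 1000]], dtype=np.int64),
            10, np.full(2, 10),
        )
        calls = [
            IBDCall("relatedness", 0, "a", "b", 0.1, 0.2, chromosome="2L"),
            IBDCall("relatedness", 1, "a", "b", 0.1, 0.2, chromosome="2L"),
        ]
        mask = build_mask(calls, ws, metas)
        _, pair_tab = ibd_summary(calls, mask, {"2L": ws}, {"2L": 1000}, metas)
        assert pair_tab["pair_fraction"].iloc[0] == pytest.approx(1.0)
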