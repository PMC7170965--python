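"""Interval merging/overlap, saturation and recurrence curves, coverage
binning, DRAC enrichment and coverage summaries."""

import numpy as np
import pytest
from scipy import stats

from meripdiff.model import CoverageTrack, PeakInterval
from meripdiff.repro import (
    coverage_saturation,
    coverage_summary,
    drac_enrichment,
    merge_intervals,
    merge_replicate_peaks,
    overlap_percent,
    plateau_threshold,
    recurrence_curve,
    replicate_saturation,
)
from meripdiff.simulate import simulate_peak_sets


def iv(start, end, gene="g", chrom="chr1"):
    return PeakInterval(chrom, start, end, peak_id=f"{chrom}:{start}", gene_id=gene)


def brute_force_union(peaks, span=10_000):
    """Per-base union oracle; returns sorted (start, end) runs per chrom."""
    out = {}
    for chrom in {p.chrom for p in peaks}:
        covered = np.zeros(span, dtype=bool)
        for p in peaks:
            if p.chrom == chrom:
                covered[p.start:p.end] = True
        runs, start = [], None
        for i, c in enumerate(covered):
            if c and start is None:
                start = i
            elif not c and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, span))
        out[chrom] = runs
    return out


class TestMerge:
    def test_single_set_returned_sorted(self):
        peaks = [iv(500, 700), iv(0, 100)]
        merged = merge_intervals(peaks)
        assert [(p.start, p.end) for p in merged] == [(0, 100), (500, 700)]

    def test_overlapping_pair_merges(self):
        merged = merge_intervals([iv(0, 100), iv(50, 150)])
        assert [(p.start, p.end) for p in merged] == [(0, 150)]

    def test_bookended_intervals_join_like_per_base_union(self):
        merged = merge_intervals([iv(0, 100), iv(100, 200)])
        assert [(p.start, p.end) for p in merged] == [(0, 200)]

    def test_three_sets_tiling_with_overlaps_merge_to_one(self):
        sets = [[iv(0, 110)], [iv(100, 210)], [iv(200, 300)]]
        merged = merge_replicate_peaks(sets)
        assert [(p.start, p.end) for p in merged] == [(0, 300)]

    def test_matches_per_base_oracle_on_random_sets(self, rng):
        peaks = []
        for chrom in ("chr1", "chr2"):
            for _ in range(40):
                s = int(rng.integers(0, 900))
                peaks.append(iv(s, s + int(rng.integers(1, 120)), chrom=chrom))
        merged = merge_intervals(peaks)
        oracle = brute_force_union(peaks, span=1100)
        got = {}
        for p in merged:
            got.setdefault(p.chrom, []).append((p.start, p.end))
        assert got == oracle


COV_HI = {"g": 50.0}


class TestOverlapPercent:
    def test_identical_sets_give_100(self):
        peaks = [iv(0, 100), iv(500, 600)]
        res = overlap_percent(peaks, peaks, COV_HI, COV_HI)
        assert res.percent_overlap == 100.0

    def test_disjoint_sets_give_0(self):
        res = overlap_percent([iv(0, 100)], [iv(200, 300)], COV_HI, COV_HI)
        assert res.percent_overlap == 0.0

    def test_single_base_overlap_counts(self):
        res = overlap_percent([iv(100, 200)], [iv(199, 300)], COV_HI, COV_HI)
        assert res.percent_overlap == 100.0

    def test_low_coverage_genes_excluded_from_both_sides(self):
        peaks1 = [iv(0, 100, gene="lo"), iv(500, 600, gene="g")]
        peaks2 = [iv(0, 100, gene="lo"), iv(550, 650, gene="g")]
        cov1 = {"lo": 3.0, "g": 40.0}
        cov2 = {"lo": 40.0, "g": 40.0}  # "lo" fails the gate in exp-1
        res = overlap_percent(peaks1, peaks2, cov1, cov2, min_cov=10)
        assert res.n_considered == 1
        assert res.percent_overlap == 100.0

    def test_empty_considered_set_reports_missing(self):
        res = overlap_percent([iv(0, 100)], [iv(0, 100)], {"g": 1.0}, {"g": 1.0})
        assert res.percent_overlap is None


class TestSaturationAndRecurrence:
    def test_identical_replicates_give_flat_curve(self):
        sets = simulate_peak_sets(5, 30, 1.0, seed=0)
        curve = replicate_saturation(sets, n_subsamples_per_k=3, seed=1)
        assert set(curve.y) == {30}

    def test_full_subset_equals_union_size(self):
        sets = simulate_peak_sets(6, 200, 0.5, seed=2)
        union = merge_replicate_peaks(sets)
        curve = replicate_saturation(sets, n_subsamples_per_k=4, seed=3)
        full = [y for x, y in zip(curve.x, curve.y) if x == 6]
        assert full == [len(union)]

    def test_capture_matches_binomial_expectation(self):
        n, p, sites = 8, 0.5, 1500
        sets = simulate_peak_sets(n, sites, p, seed=4)
        curve = replicate_saturation(sets, n_subsamples_per_k=6, seed=5)
        for k in (1, 3, 5):
            ys = [y for x, y in zip(curve.x, curve.y) if x == k]
            expected = sites * (1 - (1 - p) ** k)
            assert np.mean(ys) == pytest.approx(expected, rel=0.05)

    def test_recurrence_identical_sets_all_100(self):
        sets = simulate_peak_sets(4, 25, 1.0, seed=6)
        curve = recurrence_curve(sets)
        assert curve.y == [100.0] * 4

    def test_recurrence_private_peaks_drop_beyond_r1(self):
        # each replicate detects a disjoint slice of the universe
        universe = [iv(i * 500, i * 500 + 100, gene=f"g{i}") for i in range(9)]
        sets = [universe[0:3], universe[3:6], universe[6:9]]
        curve = recurrence_curve(sets)
        assert curve.y == [100.0, 0.0, 0.0]

    def test_recurrence_matches_binomial_tail(self):
        n, p, sites = 7, 0.6, 2000
        sets = simulate_peak_sets(n, sites, p, seed=7)
        curve = recurrence_curve(sets)
        for r, y in zip(curve.x, curve.y):
            # condition on detection in >= 1 replicate (union denominator)
            expected = 100.0 * stats.binom.sf(r - 1, n, p) / (1 - (1 - p) ** n)
            assert y == pytest.approx(expected, abs=3.0)

    def test_monotone_non_increasing(self):
        sets = simulate_peak_sets(6, 300, 0.4, seed=8)
        curve = recurrence_curve(sets)
        assert all(a >= b for a, b in zip(curve.y, curve.y[1:]))

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            recurrence_curve([[iv(0, 10)]])


class TestCoverageSaturation:
    def test_threshold_curves_nest(self):
        rng = np.random.default_rng(0)
        cov = {f"g{i}": float(np.exp(rng.uniform(0, 5))) for i in range(300)}
        peaks = []
        for i, (g, c) in enumerate(cov.items()):
            n_pk = min(int(c // 10), 3)
            for j in range(n_pk):
                peaks.append(PeakInterval("chr1", 10_000 * i + 600 * j,
                                          10_000 * i + 600 * j + 100,
                                          peak_id=f"{g}_{j}", gene_id=g))
        curves = coverage_saturation(cov, [peaks])
        x = curves[1].x
        for b in range(len(x)):
            assert curves[1].y[b] >= curves[2].y[b] >= curves[3].y[b]

    def test_zero_coverage_genes_have_no_peaks(self):
        cov = {"g1": 0.0, "g2": 0.0}
        curves = coverage_saturation(cov, [[]])
        assert all(y == 0.0 for y in curves[1].y)

    def test_plateau_threshold_reads_first_crossing(self):
        from meripdiff.repro import SaturationCurve
        curve = SaturationCurve([1, 10, 50, 100], [5.0, 50.0, 92.0, 95.0])
        assert plateau_threshold(curve) == 50


def _uniform_seq(rng, length=1000, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestDracEnrichment:
    def test_random_placement_is_unenriched(self, rng):
        seqs = {f"g{i}": _uniform_seq(rng) for i in range(40)}
        peaks = []
        for i in range(40):
            s = int(rng.integers(0, 800))
            peaks.append(PeakInterval("chr1", s, s + 150, peak_id=f"p{i}",
                                      gene_id=f"g{i}"))
        res = drac_enrichment(peaks, seqs, n_shuffles=60, seed=1)
        assert res.enrichment_ratio == pytest.approx(1.0, abs=0.15)
        assert res.empirical_p > 0.05

    def test_planted_motifs_on_motif_free_background_cap_ratio(self, rng):
        seqs = {}
        peaks = []
        for i in range(10):
            seq = list(_uniform_seq(rng, alphabet="CT"))
            seq[500:505] = list("GGACT")  # motif only inside the peak
            seqs[f"g{i}"] = "".join(seq)
            peaks.append(PeakInterval("chr1", 450, 600, peak_id=f"p{i}",
                                      gene_id=f"g{i}"))
        res = drac_enrichment(peaks, seqs, n_shuffles=40, seed=2)
        assert res.observed_fraction == 1.0
        # background windows rarely catch the single planted motif; when they
        # never do, the ratio is capped and flagged
        if res.background_fraction == 0.0:
            assert res.capped
        else:
            assert res.enrichment_ratio > 5

    def test_no_motifs_anywhere_reports_missing_ratio(self, rng):
        seqs = {"g0": _uniform_seq(rng, alphabet="CT")}
        peaks = [PeakInterval("chr1", 100, 300, peak_id="p0", gene_id="g0")]
        res = drac_enrichment(peaks, seqs, n_shuffles=30, seed=3)
        assert res.observed_fraction == 0.0
        assert res.enrichment_ratio is None

    def test_u_maps_to_t(self):
        seqs = {"g0": "CC" + "GGACU".replace("U", "U") + "CCCC"}
        peaks = [PeakInterval("chr1", 0, 11, peak_id="p0", gene_id="g0")]
        res = drac_enrichment(peaks, seqs, n_shuffles=25, seed=4)
        assert res.observed_fraction == 1.0


class TestCoverageSummary:
    def test_single_replicate_sd_zero(self):
        t = CoverageTrack("g", "IP", "control", np.arange(5),
                          np.array([[1.0, 2, 3, 4, 5]]))
        df = coverage_summary([t])
        assert (df["sd_depth"] == 0.0).all()

    def test_identical_replicates_sd_zero(self):
        t = CoverageTrack("g", "IP", "control", np.arange(3),
                          np.array([[2.0, 2, 2], [2.0, 2, 2]]))
        df = coverage_summary([t])
        assert (df["sd_depth"] == 0.0).all()
        np.testing.assert_allclose(df["mean_depth"], 2.0)

    def test_sample_sd_formula(self):
        t = CoverageTrack("g", "input", "treated", np.arange(1),
                          np.array([[0.0], [2.0]]))
        df = coverage_summary([t])
        assert df["mean_depth"].iloc[0] == 1.0
        assert df["sd_depth"].iloc[0] == pytest.approx(np.sqrt(2.0))
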