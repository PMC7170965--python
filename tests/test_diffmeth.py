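"""Normalization, dispersion estimation, fold changes, FDR, ensemble rules
and filters."""

import numpy as np
import pandas as pd
import pytest

from meripdiff.diffmeth import (
    adjust_fdr,
    apply_filters,
    combine_calls,
    compute_fold_changes,
    estimate_dispersions,
    estimate_size_factors,
    fit_dispersion_trend,
    run_pipeline,
)
from meripdiff.model import SampleInfo, ValidationError
from meripdiff.simulate import SimulationConfig, simulate_experiment

from conftest import build_experiment, build_samples


def _input_pair_samples():
    """Two paired designs so both fractions exist; the input pair carries the
    counts of interest."""
    return build_samples(1)  # c_in, c_ip, t_in, t_ip


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        exp = build_experiment(np.tile([10, 40], (3, 4)), n_reps=2)
        sf = estimate_size_factors(exp.peak_counts, exp.samples)
        np.testing.assert_allclose(sf.to_numpy(), 1.0)

    def test_doubled_sample_gets_double_factor(self):
        samples = build_samples(2)
        # input samples: control_1 = x, control_2 = 2x; treated copies control
        counts = np.array([
            # order: c1_in c1_ip c2_in c2_ip t1_in t1_ip t2_in t2_ip
            [10, 50, 20, 50, 10, 50, 20, 50],
            [100, 70, 200, 70, 100, 70, 200, 70],
            [4, 90, 8, 90, 4, 90, 8, 90],
        ])
        exp = build_experiment(counts, n_reps=2)
        sf = estimate_size_factors(exp.peak_counts, exp.samples)
        assert sf["control_2_input"] / sf["control_1_input"] == pytest.approx(2.0)

    def test_median_of_ratios_hand_example(self):
        # ratios 20/10, 180/100, 10/4 -> median 2 between the two input samples
        counts = np.array([
            [10, 1, 20, 1],
            [100, 1, 180, 1],
            [4, 1, 10, 1],
        ])
        samples = [
            SampleInfo("a_in", "input", "control", 1),
            SampleInfo("a_ip", "IP", "control", 1),
            SampleInfo("b_in", "input", "treated", 1),
            SampleInfo("b_ip", "IP", "treated", 1),
        ]
        df = pd.DataFrame(counts, index=["p0", "p1", "p2"],
                          columns=[s.sample_id for s in samples])
        sf = estimate_size_factors(df, samples)
        assert sf["b_in"] / sf["a_in"] == pytest.approx(2.0)

    def test_all_zero_sample_rejected_by_name(self):
        counts = np.array([[0, 1, 2, 3, 4, 5, 6, 7]]).T.reshape(1, 8)
        exp_counts = np.tile([5, 20], (2, 4))
        exp_counts[:, 0] = 0
        samples = build_samples(2)
        df = pd.DataFrame(exp_counts, index=["p0", "p1"],
                          columns=[s.sample_id for s in samples])
        with pytest.raises(ValidationError, match="control_1_input"):
            estimate_size_factors(df, samples)

    def test_within_fraction_normalization_ignores_global_ip_enrichment(self):
        # IP counts 10x input everywhere; factors must still all be 1
        counts = np.tile([10, 100], (4, 4))
        exp = build_experiment(counts, n_reps=2)
        sf = estimate_size_factors(exp.peak_counts, exp.samples)
        np.testing.assert_allclose(sf.to_numpy(), 1.0)


class TestDispersions:
    def test_poisson_data_estimates_near_zero(self, rng):
        n_reps = 10  # 40 samples
        samples = build_samples(n_reps)
        mu = np.tile([1000.0, 4000.0], 2 * n_reps)
        counts = rng.poisson(mu, size=(40, mu.size))
        exp = build_experiment(counts, n_reps=n_reps)
        phi = estimate_dispersions(exp.peak_counts, exp.samples,
                                   np.ones(mu.size), variant="trend_shrink")
        assert np.median(phi) < 0.01

    def test_recovers_true_dispersion(self, rng):
        n_reps = 13  # 52 samples; moderately large per-peak information
        samples = build_samples(n_reps)
        phi_true = 0.2
        r = 1.0 / phi_true
        mu = np.tile([300.0, 1200.0], 2 * n_reps)
        counts = rng.negative_binomial(r, r / (r + mu), size=(60, mu.size))
        exp = build_experiment(counts, n_reps=n_reps)
        phi = estimate_dispersions(exp.peak_counts, exp.samples,
                                   np.ones(mu.size), variant="trend_shrink")
        assert 0.14 <= np.median(phi) <= 0.26

    def test_constant_counts_give_zero_dispersion(self):
        counts = np.tile([50, 200], (3, 4))
        exp = build_experiment(counts, n_reps=2)
        phi = estimate_dispersions(exp.peak_counts, exp.samples, np.ones(8))
        assert np.all(phi < 1e-6)

    def test_too_few_replicates_demand_more(self):
        exp = build_experiment(np.arange(1, 5).reshape(1, 4), n_reps=1)
        # 4 samples, 4 parameters: zero residual df
        with pytest.raises(ValidationError, match="replicates"):
            estimate_dispersions(exp.peak_counts, exp.samples, np.ones(4))

    def test_common_tagwise_shrinks_toward_common(self, rng):
        n_reps = 4
        phi_true = 0.1
        r = 1.0 / phi_true
        mu = np.tile([200.0, 800.0], 2 * n_reps)
        counts = rng.negative_binomial(r, r / (r + mu), size=(40, mu.size))
        exp = build_experiment(counts, n_reps=n_reps)
        phi = estimate_dispersions(exp.peak_counts, exp.samples,
                                   np.ones(mu.size), variant="common_tagwise")
        # shrinkage narrows the spread around the common value
        assert np.percentile(phi, 90) / np.percentile(phi, 10) < 20

    def test_trend_fit_recovers_linear_inverse_mean(self):
        mu = np.array([10.0, 20, 50, 100, 200, 500, 1000])
        phi = 0.05 + 5.0 / mu
        a0, a1 = fit_dispersion_trend(phi, mu)
        assert a0 == pytest.approx(0.05, abs=1e-6)
        assert a1 == pytest.approx(5.0, rel=1e-6)


class TestFoldChanges:
    def test_no_change_gives_zero_delta(self):
        counts = np.tile([100, 400], (3, 4))
        exp = build_experiment(counts, n_reps=2)
        fc = compute_fold_changes(exp)
        np.testing.assert_allclose(fc["peak_ip_log2fc"], 0.0, atol=1e-9)
        np.testing.assert_allclose(fc["delta_log2fc"], 0.0, atol=1e-9)

    def test_proportional_change_cancels(self):
        # IP and input both double with treatment -> expression change, not
        # methylation change: delta stays ~0
        samples = build_samples(2)
        counts = []
        for s in samples:
            base = 400 if s.fraction == "IP" else 100
            counts.append(base * (2 if s.condition == "treated" else 1))
        counts = np.tile(counts, (2, 1))
        exp = build_experiment(counts, n_reps=2)
        sf = pd.Series(1.0, index=exp.sample_ids)
        fc = compute_fold_changes(exp, size_factors=sf)
        assert np.all(fc["delta_log2fc"] < 0.02)

    def test_ip_only_change_gives_delta_two(self):
        samples = build_samples(2)
        counts = []
        for s in samples:
            if s.fraction == "IP":
                counts.append(4000 if s.condition == "treated" else 1000)
            else:
                counts.append(1000)
        counts = np.tile(counts, (2, 1))
        exp = build_experiment(counts, n_reps=2)
        sf = pd.Series(1.0, index=exp.sample_ids)
        fc = compute_fold_changes(exp, size_factors=sf)
        np.testing.assert_allclose(fc["delta_log2fc"], 2.0, atol=0.01)

    def test_min_peak_count_is_global_minimum(self):
        counts = np.array([[9, 50, 60, 70, 80, 90, 100, 110]])
        exp = build_experiment(counts, n_reps=2)
        fc = compute_fold_changes(exp, size_factors=pd.Series(1.0, index=exp.sample_ids))
        assert fc["min_peak_count"].iloc[0] == 9


class TestFdr:
    def test_single_p_is_its_own_fdr(self):
        np.testing.assert_allclose(adjust_fdr(np.array([0.05])), [0.05])

    def test_hand_bh_example(self):
        fdr = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(fdr, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one_and_missing_stays_missing(self):
        fdr = adjust_fdr(np.array([1.0, 1.0, np.nan]))
        np.testing.assert_allclose(fdr[:2], 1.0)
        assert np.isnan(fdr[2])


class TestCombineCalls:
    def _df(self, sig_ids, all_ids=("p1", "p2", "p3")):
        return pd.DataFrame({
            "peak_id": list(all_ids),
            "fdr": [0.01 if p in sig_ids else 0.5 for p in all_ids],
        })

    def test_union_and_intersect_set_algebra(self):
        res = {"A": self._df({"p1", "p2"}), "B": self._df({"p2", "p3"})}
        assert combine_calls(res, "union") == {"p1", "p2", "p3"}
        assert combine_calls(res, "intersect") == {"p2"}

    def test_identical_variants_collapse(self):
        res = {"A": self._df({"p1"}), "B": self._df({"p1"})}
        assert combine_calls(res, "union") == combine_calls(res, "intersect")

    def test_disjoint_variants_empty_intersect(self):
        res = {"A": self._df({"p1"}), "B": self._df({"p3"})}
        assert combine_calls(res, "intersect") == set()

    def test_missing_fdr_never_significant(self):
        df = pd.DataFrame({"peak_id": ["p1"], "fdr": [np.nan]})
        assert combine_calls({"A": df}) == set()


class TestApplyFilters:
    def test_threshold_boundaries(self):
        calls = pd.DataFrame({
            "peak_id": ["a", "b", "c", "d"],
            "delta_log2fc": [1.0, 0.99, 1.5, 1.5],
            "min_peak_count": [10, 15, 9, 10],
            "significant": [True, True, True, False],
        })
        out = apply_filters(calls)
        assert list(out["peak_id"]) == ["a"]

    def test_exonic_flag_requires_membership(self):
        calls = pd.DataFrame({
            "peak_id": ["a", "b"],
            "delta_log2fc": [2.0, 2.0],
            "min_peak_count": [20, 20],
            "significant": [True, True],
        })
        out = apply_filters(calls, exonic_only=True, exon_peak_ids={"b"})
        assert list(out["peak_id"]) == ["b"]
        with pytest.raises(ValueError):
            apply_filters(calls, exonic_only=True)


class TestPipeline:
    def test_recovers_strong_planted_changes(self):
        cfg = SimulationConfig(
            n_genes=60, n_replicates_per_condition=6,
            baseline_range=(200.0, 400.0), fraction_changed=0.3,
            methylation_log2fc=2.0, dispersion_model=(0.02, 2.0), seed=9,
        )
        exp, truth = simulate_experiment(cfg)
        res = run_pipeline(exp, variants=("trend_shrink",))
        changed = set(truth.peak_truth.loc[truth.peak_truth["changed"], "peak_id"])
        called = set(res.filtered["peak_id"])
        assert len(called & changed) / len(changed) > 0.6
        # false calls stay rare among unchanged peaks
        unchanged = set(truth.peak_truth["peak_id"]) - changed
        assert len(called & unchanged) <= max(2, 0.1 * len(unchanged))

    def test_intersect_is_subset_of_union(self):
        cfg = SimulationConfig(n_genes=40, n_replicates_per_condition=3,
                               fraction_changed=0.3, methylation_log2fc=2.0,
                               seed=3)
        exp, _ = simulate_experiment(cfg)
        res_u = run_pipeline(exp, rule="union")
        res_i = run_pipeline(exp, rule="intersect")
        assert set(res_i.calls.loc[res_i.calls["significant"], "peak_id"]) <= \
               set(res_u.calls.loc[res_u.calls["significant"], "peak_id"])
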