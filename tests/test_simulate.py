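"""Tests for the synthetic-cohort generator: determinism, marginals, bounds."""

import numpy as np
import pandas as pd
import pytest

from gnas_imprint import (
    PRINTED_THRESHOLDS,
    SimulationConfig,
    assign_groups,
    compute_sample_calls,
    simulate_cohort,
    simulate_normal_pituitaries,
)
from gnas_imprint.methylation import ARRAY_PROBES


class TestDeterminism:
    def test_identical_seed_and_config_bit_identical(self, tmp_path):
        cfg = SimulationConfig(n_tumors=25, n_normals=4, seed=99)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        for name in ("samples", "methylation", "allelic", "qpcr",
                     "standard_curves", "ground_truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        assert a.sequences == b.sequences

        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_tumors=10, seed=1))
        b = simulate_cohort(SimulationConfig(n_tumors=10, seed=2))
        assert not a.methylation.equals(b.methylation)

    def test_resizing_preserves_shared_samples(self):
        # per-sample substreams: growing the cohort leaves early samples intact
        small = simulate_cohort(SimulationConfig(n_tumors=5, n_normals=0, seed=3))
        large = simulate_cohort(SimulationConfig(n_tumors=15, n_normals=0, seed=3))
        pd.testing.assert_frame_equal(
            small.methylation,
            large.methylation[
                large.methylation.sample_id.isin(small.methylation.sample_id)
            ].reset_index(drop=True),
        )


class TestDegenerateConfigs:
    def test_empty_tumor_cohort(self):
        t = simulate_cohort(SimulationConfig(n_tumors=0, n_normals=3, seed=0))
        assert (t.ground_truth.sample_type == "normal").sum() == 3
        assert (t.ground_truth.sample_type == "tumor").sum() == 0

    def test_all_gsp_positive(self):
        t = simulate_cohort(SimulationConfig(n_tumors=30, n_normals=0,
                                             p_gsp=1.0, seed=0))
        assert t.ground_truth.true_gsp.all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="p_gsp"):
            simulate_cohort(SimulationConfig(p_gsp=1.5))

    def test_negative_cohort_size_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_cohort(SimulationConfig(n_tumors=-1))
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_normal_pituitaries(-1, seed=0)

    def test_empty_normals(self):
        t = simulate_normal_pituitaries(0, seed=0)
        assert len(t.ground_truth) == 0


class TestMarginals:
    def test_heterozygous_fraction_matches_hardy_weinberg(self):
        # expected 2 * 0.35 * 0.65 = 0.455 at maf 35%
        t = simulate_cohort(SimulationConfig(n_tumors=2000, n_normals=0, seed=17))
        frac = t.ground_truth.true_heterozygous.mean()
        expected = 2 * 0.35 * 0.65
        se = np.sqrt(expected * (1 - expected) / 2000)
        assert abs(frac - expected) < 3 * se

    def test_gsp_fraction_converges(self):
        t = simulate_cohort(SimulationConfig(n_tumors=2000, n_normals=0, seed=23))
        frac = t.ground_truth.true_gsp.mean()
        se = np.sqrt(0.25 * 0.75 / 2000)
        assert abs(frac - 0.25) < 3 * se

    def test_relaxed_fraction_among_gspneg_converges(self):
        t = simulate_cohort(SimulationConfig(n_tumors=2000, n_normals=0, seed=29))
        gt = t.ground_truth
        informative = gt[(~gt.true_gsp) & (gt.true_relaxed != "NA")]
        frac = (informative.true_relaxed == "true").mean()
        se = np.sqrt(0.44 * 0.56 / len(informative))
        assert abs(frac - 0.44) < 3 * se


class TestNormalPituitaries:
    def test_normals_monoallelic_and_in_range(self):
        t = simulate_normal_pituitaries(6, seed=1)
        calls = compute_sample_calls(t)
        calls = assign_groups(calls, PRINTED_THRESHOLDS)
        assert calls.ml.between(30, 50).all()
        assert (calls.relaxation_status != "relaxed").all()

    def test_large_normal_sample_mean_near_forty(self):
        t = simulate_normal_pituitaries(1000, seed=2)
        calls = compute_sample_calls(t)
        # sample-level ML variance: 2.5^2 + cpg noise 3^2/6
        sd = np.sqrt(2.5**2 + 9.0 / 6.0)
        assert abs(calls.ml.mean() - 40.0) < 3 * sd / np.sqrt(1000)

    def test_no_relaxed_calls_over_thousand_normals(self):
        t = simulate_normal_pituitaries(1000, seed=3)
        calls = assign_groups(compute_sample_calls(t), PRINTED_THRESHOLDS)
        assert (calls.relaxation_status == "relaxed").sum() == 0


class TestValueBounds:
    def test_generated_values_in_physical_ranges(self):
        t = simulate_cohort(SimulationConfig(n_tumors=300, n_normals=10, seed=4))
        assert t.methylation.value.between(0, 100).all()
        assert (t.qpcr.cq > 0).all()
        assert (t.allelic[["signal_c", "signal_t"]] >= 0).all().all()

    def test_six_cpgs_three_probe_annotations(self):
        t = simulate_cohort(SimulationConfig(n_tumors=1, n_normals=0, seed=0))
        per_sample = t.methylation[t.methylation.sample_id == "T0001"]
        assert len(per_sample) == 6
        probes = set(per_sample.probe_id) - {""}
        assert probes == set(ARRAY_PROBES)

    def test_ml_and_three_cpg_subset_agree(self):
        """The 6-CpG ML and the 3-probe subset index of the same sample agree
        within 3 * cpg_noise_sd / sqrt(3) for at least 99% of samples."""
        t = simulate_cohort(SimulationConfig(n_tumors=400, n_normals=0, seed=6))
        meth = t.methylation
        ml6 = meth.groupby("sample_id").value.mean()
        ml3 = meth[meth.probe_id != ""].groupby("sample_id").value.mean()
        diff = (ml6 - ml3).abs()
        tol = 3 * 3.0 / np.sqrt(3)
        assert (diff <= tol).mean() >= 0.99


class TestGroundTruthSchema:
    def test_one_truth_row_per_sample(self):
        t = simulate_cohort(SimulationConfig(n_tumors=40, n_normals=5, seed=8))
        assert len(t.ground_truth) == 45
        assert t.ground_truth.sample_id.is_unique

    def test_relaxation_na_iff_homozygous(self):
        t = simulate_cohort(SimulationConfig(n_tumors=200, n_normals=0, seed=9))
        gt = t.ground_truth
        assert ((gt.true_relaxed == "NA") == ~gt.true_heterozygous).all()

    def test_gsp_sequences_consistent_with_truth(self):
        t = simulate_cohort(SimulationConfig(n_tumors=50, n_normals=0, seed=10))
        seqs = dict(t.sequences)
        for row in t.ground_truth.itertuples():
            mutated = seqs[row.sample_id] != t.reference_cds
            assert mutated == bool(row.true_gsp)
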