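"""Tests for A/B DMR methylation levels and hypo/normo/hyper classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gnas_imprint import (
    CpGMeasurement,
    MethylationProfile,
    NormalRange,
    classify_methylation,
    compute_ml,
)
from gnas_imprint.methylation import (
    ARRAY_PROBES,
    REGION_END,
    REGION_START,
    profiles_from_table,
    region_bed,
)

POSITIONS = (57463609, 57463621, 57463633, 57463650, 57463672, 57463688)


def pyro_profile(values, positions=POSITIONS):
    return MethylationProfile(
        "S1",
        "pyroseq6",
        tuple(CpGMeasurement(p, v) for p, v in zip(positions, values)),
    )


def array_profile(betas):
    return MethylationProfile(
        "S1",
        "array3",
        tuple(
            CpGMeasurement(p, v, probe_id=probe)
            for p, v, probe in zip(POSITIONS[:3], betas, ARRAY_PROBES)
        ),
    )


REFERENCE_RANGE = NormalRange(
    mean=42.4, sd=5.7, k_sd=2.0, lower=31.0, upper=53.8,
    normality_p=0.98, unit="percent",
)


class TestComputeMl:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([40.0] * 6, 40.0),
            ([30, 40, 50, 40, 40, 40], 40.0),
            ([25.5, 31.2, 44.0, 39.9, 50.1, 28.3], np.mean(
                [25.5, 31.2, 44.0, 39.9, 50.1, 28.3])),
        ],
    )
    def test_mean_of_six_cpgs(self, values, expected):
        assert compute_ml(pyro_profile(values)) == pytest.approx(expected)

    def test_array_mode_mean_on_beta_scale(self):
        assert compute_ml(array_profile([0.50, 0.56, 0.62])) == pytest.approx(0.56)

    def test_wrong_measurement_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 6"):
            MethylationProfile(
                "S1", "pyroseq6",
                tuple(CpGMeasurement(p, 40.0) for p in POSITIONS[:5]),
            )

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            pyro_profile([40, 40, 40, 40, 40, 101])

    def test_beta_above_one_rejected_in_array_mode(self):
        with pytest.raises(ValueError, match="outside"):
            array_profile([0.5, 0.6, 1.2])

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            pyro_profile([40] * 6, positions=(POSITIONS[0],) * 6)

    def test_position_outside_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            MethylationProfile(
                "S1", "pyroseq6",
                tuple(
                    CpGMeasurement(p, 40.0)
                    for p in POSITIONS[:5] + (REGION_END + 1,)
                ),
            )

    def test_array_mode_requires_known_probe(self):
        with pytest.raises(ValueError, match="probe_id"):
            MethylationProfile(
                "S1", "array3",
                tuple(
                    CpGMeasurement(p, 0.5, probe_id="cg00000000")
                    for p in POSITIONS[:3]
                ),
            )

    @given(
        st.lists(
            st.floats(0, 100, allow_nan=False), min_size=6, max_size=6
        ),
        st.permutations(range(6)),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_permutation_invariant_and_bounded(self, values, perm):
        ml = compute_ml(pyro_profile(values))
        shuffled = [values[i] for i in perm]
        positions = [POSITIONS[i] for i in perm]
        assert compute_ml(pyro_profile(shuffled, positions)) == pytest.approx(
            ml, abs=1e-9
        )
        assert min(values) - 1e-9 <= ml <= max(values) + 1e-9


class TestClassifyMethylation:
    @pytest.mark.parametrize(
        "ml,expected",
        [
            (39.0, "normo"),
            (60.0, "hyper"),
            (25.0, "hypo"),
            (53.8, "normo"),  # inclusive upper bound
            (31.0, "normo"),  # inclusive lower bound
            (53.8000001, "hyper"),
        ],
    )
    def test_against_published_range(self, ml, expected):
        assert classify_methylation(ml, REFERENCE_RANGE) == expected

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit mismatch"):
            classify_methylation(0.39, REFERENCE_RANGE, unit="fraction")

    @given(st.floats(-50, 150, allow_nan=False))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_every_value_gets_exactly_one_status(self, ml):
        status = classify_methylation(ml, REFERENCE_RANGE)
        assert status in ("hypo", "normo", "hyper")


class TestTableIo:
    def test_round_trip_through_long_table(self):
        table = pd.DataFrame(
            {
                "sample_id": ["A"] * 6,
                "platform": ["pyroseq6"] * 6,
                "position": list(POSITIONS),
                "probe_id": [""] * 6,
                "value": [38.0, 40.0, 42.0, 41.0, 39.0, 40.0],
            }
        )
        profiles = profiles_from_table(table)
        assert len(profiles) == 1
        assert compute_ml(profiles[0]) == pytest.approx(40.0)

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="value"):
            profiles_from_table(pd.DataFrame({"sample_id": [], "platform": [],
                                              "position": []}))

    def test_bed_export_is_zero_based_half_open(self):
        bed = region_bed([REGION_START, REGION_END])
        assert list(bed.start) == [REGION_START - 1, REGION_END - 1]
        assert list(bed.end) == [REGION_START, REGION_END]
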