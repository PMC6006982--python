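"""Possibly-gapped histograms and digital coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from entroflow import (
    FeatureSpec,
    RawDataMatrix,
    RenormalizeConfig,
    build_gapped_histogram,
    encode_categorical_with_anchor,
    encode_feature,
    renormalize_matrix,
)
from entroflow.renormalize import (
    DegenerateFeatureError,
    UnknownCategoryError,
    ValueOutsideSupportError,
)


class TestBuildGappedHistogram:
    def test_constant_vector_single_bin(self):
        h = build_gapped_histogram(np.full(50, 3.7))
        assert h.n_bins == 1
        assert h.gaps == []
        assert h.counts.tolist() == [50]
        assert h.codes.tolist() == [0]

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateFeatureError):
            build_gapped_histogram(np.array([1.0]))

    def test_two_block_sample_has_one_gap(self, two_block_values):
        # the 99-unit hole dwarfs 5x the median spacing of ~0.1
        h = build_gapped_histogram(two_block_values, gap_factor=5)
        assert len(h.gaps) == 1
        lo, hi = h.gaps[0]
        assert lo < 50 < hi
        # bins split cleanly on either side of the gap
        left = [e for e in h.bin_edges if e[1] <= lo]
        right = [e for e in h.bin_edges if e[0] >= hi]
        assert len(left) + len(right) == h.n_bins

    def test_bimodal_with_extreme_tails_gets_flanking_gaps(self):
        # mimics a head-size distribution: a big central mass with a few
        # extreme stragglers separated by empty stretches
        rng = np.random.default_rng(3)
        center = np.concatenate([rng.normal(3500, 80, 110), rng.normal(3900, 80, 110)])
        values = np.concatenate([[2700.0, 2720.0], center, [4500.0, 4520.0]])
        h = build_gapped_histogram(values, gap_factor=5)
        assert len(h.gaps) >= 2
        assert min(g[0] for g in h.gaps) < 3000  # gap below the main mass
        assert max(g[1] for g in h.gaps) > 4300  # gap above the main mass

    def test_counts_sum_to_n_and_bins_tile_range(self):
        rng = np.random.default_rng(7)
        x = rng.gamma(2.0, 3.0, 200)
        h = build_gapped_histogram(x)
        assert h.counts.sum() == 200
        # every observed value lies in exactly one bin
        for v in x:
            assert h.locate(v) >= 0
        # bins and gaps are ordered and disjoint
        points = sorted([e for b in h.bin_edges for e in b])
        assert points == [e for b in h.bin_edges for e in b]

    def test_codes_strictly_increasing_and_on_range(self):
        rng = np.random.default_rng(11)
        h = build_gapped_histogram(rng.normal(0, 1, 150), code_range=10)
        assert (np.diff(h.codes) > 0).all()
        assert h.codes[0] == 0 and h.codes[-1] <= 9

    def test_many_gaps_capped_by_bin_budget(self):
        # 12 far-separated singletons cannot all get their own bin
        x = np.repeat(np.arange(12) * 1000.0, 2) + np.tile([0.0, 0.1], 12)
        h = build_gapped_histogram(x, max_bins=5, code_range=10)
        assert h.n_bins <= 5
        assert h.counts.sum() == 24


class TestEncodeFeature:
    def test_lowest_bin_maps_to_code_zero(self, two_block_values):
        h = build_gapped_histogram(two_block_values)
        assert encode_feature([two_block_values.min()], h)[0] == 0

    def test_two_block_sample_two_plateaus(self, two_block_values):
        h = build_gapped_histogram(two_block_values, max_bins=2, gap_factor=5)
        codes = encode_feature(two_block_values, h)
        assert set(codes) == {0, 9}
        assert (codes[:10] == 0).all() and (codes[10:] == 9).all()

    def test_value_in_gap_raises_unless_lenient(self, two_block_values):
        h = build_gapped_histogram(two_block_values, gap_factor=5)
        with pytest.raises(ValueOutsideSupportError):
            encode_feature([50.0], h)
        snapped = encode_feature([50.0], h, lenient=True)[0]
        assert snapped in set(h.codes)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=60, unique=True))
    def test_encoding_is_order_preserving(self, values):
        x = np.sort(np.asarray(values))
        h = build_gapped_histogram(x)
        codes = encode_feature(x, h)
        assert (np.diff(codes) >= 0).all()


class TestCategoricalAnchor:
    def test_override_applied_verbatim(self):
        codes, mapping = encode_categorical_with_anchor(
            ["0", "1", "1", "0"], override={"0": 0, "1": 5}
        )
        assert codes.tolist() == [0, 5, 5, 0]
        assert mapping == {"0": 0, "1": 5}

    def test_three_level_override(self):
        codes, _ = encode_categorical_with_anchor(
            [0, 1, 2, 1], override={0: 9, 1: 3, 2: 7}
        )
        assert codes.tolist() == [9, 3, 7, 3]

    def test_perfectly_separated_anchor_means_become_codes(self):
        labels = ["A"] * 5 + ["B"] * 5
        anchor = np.array([0] * 5 + [9] * 5)
        codes, mapping = encode_categorical_with_anchor(labels, anchor)
        assert mapping == {"A": 0, "B": 9}
        assert codes.tolist() == [0] * 5 + [9] * 5

    def test_rounding_tie_breaks_toward_smaller_code(self):
        # mean anchor code exactly 4.5 rounds down to 4
        labels = ["A", "A"]
        anchor = np.array([4, 5])
        _, mapping = encode_categorical_with_anchor(labels, anchor)
        assert mapping["A"] == 4

    def test_unknown_label_raises(self):
        with pytest.raises(UnknownCategoryError):
            encode_categorical_with_anchor(["A", "C"], override={"A": 1})


class TestRenormalizeMatrix:
    def test_identical_columns_code_identically(self):
        rng = np.random.default_rng(0)
        col = rng.normal(0, 1, 60)
        frame = pd.DataFrame({"a": col, "b": col.copy()},
                             index=[f"s{i}" for i in range(60)])
        specs = [FeatureSpec("a", "continuous", "covariate"),
                 FeatureSpec("b", "continuous", "covariate")]
        coded, _ = renormalize_matrix(RawDataMatrix(frame, specs))
        assert (coded.codes["a"] == coded.codes["b"]).all()

    def test_heart_style_override_table(self):
        """The manual coding scheme for a 13-feature mixed clinical matrix."""
        rng = np.random.default_rng(5)
        n = 60
        frame = pd.DataFrame(
            {
                "age": rng.normal(54, 9, n),
                "sex": rng.integers(0, 2, n),
                "chest_pain": rng.integers(1, 5, n),
                "rest_ecg": rng.integers(0, 3, n),
                "st_slope": rng.integers(1, 4, n),
                "n_vessels": rng.integers(0, 4, n),
                "thal": rng.choice([3, 6, 7], n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        specs = [
            FeatureSpec("age", "continuous", "covariate"),
            FeatureSpec("sex", "binary", "covariate"),
            FeatureSpec("chest_pain", "categorical", "covariate"),
            FeatureSpec("rest_ecg", "categorical", "covariate"),
            FeatureSpec("st_slope", "categorical", "covariate"),
            FeatureSpec("n_vessels", "categorical", "covariate"),
            FeatureSpec("thal", "categorical", "covariate"),
        ]
        overrides = {
            "sex": {0: 0, 1: 5},
            "chest_pain": {1: 0, 2: 0, 3: 0, 4: 5},
            "rest_ecg": {0: 9, 1: 3, 2: 7},
            "st_slope": {1: 3, 2: 6, 3: 9},
            "n_vessels": {0: 0, 1: 3, 2: 6, 3: 9},
            "thal": {3: 0, 6: 5, 7: 5},
        }
        coded, _ = renormalize_matrix(
            RawDataMatrix(frame, specs), RenormalizeConfig(overrides=overrides)
        )
        assert set(coded.codes["sex"]) <= {0, 5}
        assert set(coded.codes["chest_pain"]) <= {0, 5}
        assert set(coded.codes["rest_ecg"]) <= {9, 3, 7}
        assert set(coded.codes["st_slope"]) <= {3, 6, 9}
        assert set(coded.codes["n_vessels"]) <= {0, 3, 6, 9}
        assert set(coded.codes["thal"]) <= {0, 5}
        # non-override columns all share the common range
        assert coded.codes.to_numpy().min() >= 0
        assert coded.codes.to_numpy().max() <= 9

    def test_auto_anchor_coding_follows_dependent_numeric_feature(
        self, mixed_raw_matrix
    ):
        coded, _ = renormalize_matrix(mixed_raw_matrix)
        # 'level' is a coarsening of 'cont', its auto-anchored codes must be
        # ordered the same way as the underlying continuous feature
        means = {
            lab: coded.codes["level"][mixed_raw_matrix.values["level"] == lab].mean()
            for lab in ("low", "mid", "high")
        }
        # labels with nearly equal anchor means may share a code, but the
        # ordering of the underlying continuous feature is never inverted
        assert means["low"] < means["mid"] <= means["high"]

    def test_continuous_round_trip_preserves_rank_order(self):
        rng = np.random.default_rng(13)
        x = rng.lognormal(1.0, 0.6, 120)
        frame = pd.DataFrame({"x": x, "y": rng.normal(0, 1, 120)},
                             index=[f"s{i}" for i in range(120)])
        specs = [FeatureSpec("x", "continuous", "covariate"),
                 FeatureSpec("y", "continuous", "covariate")]
        coded, hists = renormalize_matrix(RawDataMatrix(frame, specs))
        mids = hists["x"].midpoints()
        code_to_mid = dict(zip(hists["x"].codes, mids))
        decoded = np.array([code_to_mid[c] for c in coded.codes["x"]])
        rho, _ = spearmanr(x, decoded)
        # ties within bins collapse, but order never inverts
        assert rho > 0.97
        order = np.argsort(x)
        assert (np.diff(coded.codes["x"].to_numpy()[order]) >= 0).all()

    def test_renormalization_is_deterministic(self, mixed_raw_matrix):
        coded1, _ = renormalize_matrix(mixed_raw_matrix)
        coded2, _ = renormalize_matrix(mixed_raw_matrix)
        assert coded1.codes.equals(coded2.codes)

    def test_missing_entries_rejected(self):
        frame = pd.DataFrame({"a": [1.0, np.nan, 3.0]}, index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="missing"):
            RawDataMatrix(frame, [FeatureSpec("a", "continuous", "covariate")])

    def test_error_carries_feature_name(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [np.inf, 0.0]},
                             index=["s0", "s1"])
        specs = [FeatureSpec("a", "continuous", "covariate"),
                 FeatureSpec("b", "continuous", "covariate")]
        with pytest.raises(ValueError, match="'b'"):
            renormalize_matrix(RawDataMatrix(frame, specs))
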