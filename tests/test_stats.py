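import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h

from agosort import (
    bh_fdr,
    base_composition,
    composition_from_counts,
    correlate_profiles,
    logo_information,
    mi_profile,
    mutual_information,
    permutation_pvalue,
)
from agosort import SignalSpec, generate_sequences, table1_signal_spec
from tests.conftest import make_confidence_set


def brute_force_mi(labels, bases):
    """Direct summation over joint cells, independent of the implementation."""
    n = len(labels)
    mi = 0.0
    for ago in set(labels):
        p_ago = sum(1 for l in labels if l == ago) / n
        for b in set(bases):
            p_b = sum(1 for x in bases if x == b) / n
            p_joint = sum(1 for l, x in zip(labels, bases) if l == ago and x == b) / n
            if p_joint > 0:
                mi += p_joint * math.log2(p_joint / (p_ago * p_b))
    return mi


class TestMutualInformation:
    @pytest.mark.parametrize(
        "labels,bases,expected",
        [
            ([1, 1, 2, 2], list("UUAA"), 1.0),
            ([1, 1, 2, 2], list("UAUA"), 0.0),
            ([1, 1, 1, 2, 2, 5], list("UUCAAC"), 1.1258),
        ],
    )
    def test_known_values(self, labels, bases, expected):
        assert mutual_information(labels, bases) == pytest.approx(expected, abs=1e-4)

    def test_length_mismatch_and_empty_errors(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], ["A"])
        with pytest.raises(ValueError):
            mutual_information([], [])

    @given(
        st_h.lists(
            st_h.tuples(st_h.sampled_from([1, 2, 5]), st_h.sampled_from("ACGU")),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_bounds_and_oracle(self, pairs):
        labels = [p[0] for p in pairs]
        bases = [p[1] for p in pairs]
        mi = mutual_information(labels, bases)
        assert mi == pytest.approx(mutual_information(bases, labels), abs=1e-12)
        assert mi == pytest.approx(brute_force_mi(labels, bases), abs=1e-12)
        h_l = brute_force_mi(labels, labels)
        h_b = brute_force_mi(bases, bases)
        assert -1e-12 <= mi <= min(h_l, h_b) + 1e-12


class TestPermutationPvalue:
    def test_constant_column_p_is_one(self):
        p, _ = permutation_pvalue([1, 1, 2, 2], ["U"] * 4, n_perm=99, seed=0)
        assert p == 1.0

    def test_perfectly_separating_column_is_significant(self):
        labels = [1] * 20 + [2] * 20
        bases = ["U"] * 20 + ["A"] * 20
        p, _ = permutation_pvalue(labels, bases, n_perm=999, seed=1)
        assert p <= 0.01

    def test_seeded_determinism(self):
        labels = [1, 1, 1, 2, 2, 5] * 5
        bases = list("UUCAAC") * 5
        p1, s1 = permutation_pvalue(labels, bases, n_perm=500, seed=7)
        p2, s2 = permutation_pvalue(labels, bases, n_perm=500, seed=7)
        assert p1 == p2 and s1 == s2

    def test_add_one_convention_never_zero(self):
        labels = [1] * 30 + [2] * 30
        bases = ["U"] * 30 + ["A"] * 30
        p, _ = permutation_pvalue(labels, bases, n_perm=99, seed=2)
        assert p >= 1 / 100


class TestBhFdr:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(0.001, 1.0, size=21)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestMiProfile:
    def test_planted_signal_position_is_argmax(self):
        spec = table1_signal_spec(three_class=True)
        planted = SignalSpec(
            class_names=spec.class_names,
            n_per_class=spec.n_per_class,
            position_signals={6: spec.position_signals[1]},
        )
        seqs, labels = generate_sequences(planted, seed=3)
        prof = mi_profile((seqs, labels), n_perm=999, seed=0)
        assert prof.loc[prof["mi_bits"].idxmax(), "position"] == 6
        assert prof.loc[prof["position"] == 6, "p_fdr"].item() < 0.05

    def test_constant_column_within_subset_has_zero_mi(self):
        seqs = ["U" + "A" * 20] * 5 + ["U" + "C" * 20] * 5
        labels = ["AGO1"] * 5 + ["AGO5"] * 5
        prof = mi_profile((seqs, labels), class_subset=("AGO1", "AGO5"), n_perm=50, seed=0)
        assert prof.loc[prof["position"] == 1, "mi_bits"].item() == 0.0

    def test_empty_class_is_error(self):
        seqs = ["A" * 21] * 4
        labels = ["AGO1"] * 4
        with pytest.raises(ValueError):
            mi_profile((seqs, labels), class_subset=("AGO1", "AGO5"), n_perm=10)

    def test_fdr_spans_profile_positions(self, three_class_cohort):
        seqs, labels = three_class_cohort
        prof = mi_profile((seqs, labels), n_perm=99, seed=4)
        assert len(prof) == 21
        assert (prof["p_fdr"] >= prof["p_emp"] - 1e-12).all()


class TestComposition:
    TABLE = {
        "AGO1": {"A": 0, "C": 6, "G": 1, "U": 63},
        "AGO2": {"A": 21, "C": 0, "G": 1, "U": 3},
        "AGO4": {"A": 5, "C": 0, "G": 0, "U": 4},
        "AGO5": {"A": 0, "C": 6, "G": 0, "U": 16},
    }
    BACKGROUND = {"A": 66, "C": 27, "G": 21, "U": 214}

    @pytest.mark.parametrize(
        "cls,base,printed",
        [
            ("AGO2", "A", 4.2),
            ("AGO1", "U", 1.4),
            ("AGO5", "C", 3.3),
            ("AGO5", "U", 1.1),
            ("AGO2", "G", 0.6),
            ("AGO4", "U", 0.7),
            ("AGO1", "A", 0.0),
        ],
    )
    def test_enrichment_ratios_match_printed_values(self, cls, base, printed):
        df = composition_from_counts(self.TABLE, self.BACKGROUND)
        row = df[(df["ago_class"] == cls) & (df["base"] == base)]
        assert round(row["enrichment_ratio"].item(), 1) == pytest.approx(printed)

    def test_ago1_c_ratio_at_two_decimals(self):
        df = composition_from_counts(self.TABLE, self.BACKGROUND)
        row = df[(df["ago_class"] == "AGO1") & (df["base"] == "C")]
        assert round(row["enrichment_ratio"].item(), 2) == pytest.approx(1.04)

    def test_class_frequency_equal_to_background_gives_one(self):
        df = composition_from_counts(
            {"AGO1": {"A": 10, "C": 10, "G": 10, "U": 10}},
            {"A": 5, "C": 5, "G": 5, "U": 5},
        )
        assert (df["enrichment_ratio"] == 1.0).all()

    def test_zero_background_with_nonzero_count_flagged_infinite(self):
        df = composition_from_counts(
            {"AGO1": {"A": 1, "C": 0, "G": 0, "U": 0}},
            {"A": 0, "C": 1, "G": 1, "U": 1},
        )
        assert np.isinf(df[df["base"] == "A"]["enrichment_ratio"].item())

    def test_counts_derived_from_confidence_set(self):
        seqs = ["U" + "A" * 20] * 3 + ["A" + "C" * 20] * 2
        labels = ["AGO1"] * 3 + ["AGO2"] * 2
        cset = make_confidence_set(seqs, labels)
        df = base_composition(cset, {"A": 10, "C": 10, "G": 10, "U": 10})
        assert df[(df["ago_class"] == "AGO1") & (df["base"] == "U")]["count"].item() == 3
        assert df[(df["ago_class"] == "AGO2") & (df["base"] == "A")]["count"].item() == 2


class TestLogoInformation:
    def test_conserved_column_two_bits(self):
        df = logo_information(["U" * 21] * 10)
        np.testing.assert_allclose(df["info_bits"], 2.0)
        np.testing.assert_allclose(df["height_U"], 2.0)

    def test_uniform_column_zero_bits(self):
        seqs = ["A" * 21, "C" * 21, "G" * 21, "U" * 21]
        df = logo_information(seqs)
        np.testing.assert_allclose(df["info_bits"], 0.0, atol=1e-12)

    def test_half_and_half_one_bit(self):
        df = logo_information(["U" * 21] * 5 + ["A" * 21] * 5)
        np.testing.assert_allclose(df["info_bits"], 1.0)
        np.testing.assert_allclose(df["height_U"], 0.5)
        np.testing.assert_allclose(df["height_A"], 0.5)

    def test_small_sample_correction_subtracts_and_floors(self):
        uncorrected = logo_information(["U" * 21] * 10)
        corrected = logo_information(["U" * 21] * 10, small_sample_correction=True)
        e_n = 3 / (2 * np.log(2) * 10)
        assert corrected["info_bits"].iloc[0] == pytest.approx(2.0 - e_n)
        floor = logo_information(["A" * 21, "C" * 21, "G" * 21, "U" * 21] * 1,
                                 small_sample_correction=True)
        assert (floor["info_bits"] >= 0).all()
        assert uncorrected["info_bits"].iloc[0] > corrected["info_bits"].iloc[0]


class TestCorrelateProfiles:
    def test_linear_relation(self):
        out = correlate_profiles([1, 2, 3, 4], [2, 4, 6, 8])
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_hand_computed_mixed_case(self):
        out = correlate_profiles([1, 2, 3, 4], [1, 3, 2, 4])
        assert out["pearson_r"] == pytest.approx(0.8)
        assert out["spearman_rho"] == pytest.approx(0.8)

    def test_reversed_profile(self):
        out = correlate_profiles([1, 2, 3, 4], [4, 3, 2, 1])
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_profiles([1, 1, 1], [1, 2, 3])
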