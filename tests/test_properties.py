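"""Descriptor computation: worked examples, oracles and invariances."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from pepkin.properties import (
    AMINO_ACIDS,
    GRANTHAM,
    KYTE_DOOLITTLE,
    ZIMMERMAN,
    InvalidSequenceError,
    clean_sequence,
    compute_bulkiness,
    compute_gravy,
    compute_net_charge,
    compute_polarity,
    compute_property_vector,
    compute_residue_fractions,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)


class TestMeanScaleDescriptors:
    @pytest.mark.parametrize(
        "func,seq,expected,places",
        [
            (compute_gravy, "KGSIDEQHPRYGG", -1.73, 2),
            (compute_gravy, "I", 4.5, 6),
            (compute_gravy, "GTWQRPH", -2.114, 3),
            (compute_bulkiness, "G", 3.40, 6),
            (compute_bulkiness, "GTWQRPH", 14.38, 2),
            (compute_bulkiness, "KDIPVPKPK", 17.12, 2),
            (compute_bulkiness, "YFHEDDKF", 15.50, 2),
            (compute_polarity, "G", 9.0, 6),
            (compute_polarity, "GTWQRPH", 8.91, 2),
            (compute_polarity, "GFGRIGR", 8.34, 2),
        ],
    )
    def test_worked_examples(self, func, seq, expected, places):
        assert round(func(seq), places) == pytest.approx(expected)

    def test_unknown_residue_names_position_and_character(self):
        with pytest.raises(InvalidSequenceError) as err:
            compute_gravy("PEPTIDEX")
        assert err.value.position == 7
        assert err.value.character == "X"
        assert "'X'" in str(err.value) and "8" in str(err.value)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidSequenceError):
            compute_gravy("")

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=200)
    def test_matches_naive_per_residue_oracle(self, seq):
        for func, scale in [
            (compute_gravy, KYTE_DOOLITTLE),
            (compute_bulkiness, ZIMMERMAN),
            (compute_polarity, GRANTHAM),
        ]:
            naive = sum(scale.values[r] for r in seq) / len(seq)
            assert func(seq) == pytest.approx(naive, abs=1e-12)

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=100)
    def test_bounded_by_residue_extremes(self, seq):
        lo = min(KYTE_DOOLITTLE.values[r] for r in seq)
        hi = max(KYTE_DOOLITTLE.values[r] for r in seq)
        assert lo - 1e-12 <= compute_gravy(seq) <= hi + 1e-12


class TestNetCharge:
    def test_glycine_dipeptide_termini_nearly_cancel(self):
        assert abs(compute_net_charge("GG", ph=6.0)) < 0.05

    def test_two_arginines_give_plus_two(self):
        assert compute_net_charge("GFGRIGR", ph=6.0) == pytest.approx(2.0, abs=0.1)

    def test_arginine_plus_partial_histidine_above_one(self):
        assert compute_net_charge("GTWQRPH", ph=6.0) > 1.0

    def test_acidic_peptide_is_negative(self):
        assert compute_net_charge("DDEE", ph=6.0) < -3.0

    def test_termini_flag(self):
        with_term = compute_net_charge("GG", include_termini=True)
        without = compute_net_charge("GG", include_termini=False)
        assert without == 0.0
        assert with_term != without

    def test_invalid_ph_rejected(self):
        with pytest.raises(ValueError):
            compute_net_charge("GG", ph=15.0)

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=100)
    def test_charge_additive_under_duplication_without_termini(self, seq):
        single = compute_net_charge(seq, include_termini=False)
        double = compute_net_charge(seq + seq, include_termini=False)
        assert double == pytest.approx(2 * single, abs=1e-10)


class TestResidueFractions:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GTWQRPH", (2 / 7, 0.0, 1 / 7, 1 / 7)),
            ("AAAA", (0.0, 0.0, 0.0, 0.0)),
            ("KDIPVPKPK", (3 / 9, 1 / 9, 0.0, 3 / 9)),
        ],
    )
    def test_direct_counts(self, seq, expected):
        assert compute_residue_fractions(seq) == pytest.approx(expected)

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=100)
    def test_fractions_in_unit_interval(self, seq):
        fracs = compute_residue_fractions(seq)
        assert all(0.0 <= f <= 1.0 for f in fracs)


class TestPropertyVector:
    def test_worked_example_fields(self):
        pv = compute_property_vector("KGSIDEQHPRYGG")
        assert pv.length == 13
        assert round(pv.gravy, 2) == -1.73

    def test_single_proline(self):
        pv = compute_property_vector("P")
        assert pv.length == 1
        assert pv.frac_proline == 1.0

    def test_bulkiness_example(self):
        pv = compute_property_vector("YFHEDDKF")
        assert pv.length == 8
        assert round(pv.bulkiness, 2) == 15.50

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=100)
    def test_all_descriptors_shuffle_invariant(self, seq):
        shuffled = "".join(random.Random(0).sample(seq, len(seq)))
        pv1 = compute_property_vector(seq)
        pv2 = compute_property_vector(shuffled)
        for name in ("length", "gravy", "bulkiness", "polarity", "net_charge",
                     "frac_basic", "frac_acidic", "frac_aromatic",
                     "frac_proline"):
            assert getattr(pv1, name) == pytest.approx(
                getattr(pv2, name), abs=1e-12
            )

    @given(seq=sequences)
    @settings(derandomize=True, max_examples=100)
    def test_mean_descriptors_invariant_under_duplication(self, seq):
        pv1 = compute_property_vector(seq)
        pv2 = compute_property_vector(seq + seq)
        for attr in ("gravy", "bulkiness", "polarity", "frac_basic",
                     "frac_acidic", "frac_aromatic", "frac_proline"):
            assert getattr(pv2, attr) == pytest.approx(
                getattr(pv1, attr), abs=1e-12
            )


class TestCleanSequence:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("M(ox)PEPTIDE", "MPEPTIDE"),
            ("pep tide", "PEPTIDE"),
            ("M[+15.995]K", "MK"),
            ("PLAIN", "PLAIN"),
        ],
    )
    def test_annotations_stripped(self, raw, expected):
        assert clean_sequence(raw) == expected
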