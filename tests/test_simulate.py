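"""Synthetic peptidome generator: laws, planting rules, determinism."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from pepkin.barcoding import assign_barcode
from pepkin.properties import compute_property_vector
from pepkin.simulate import (
    DEFAULT_SIM_CONFIG,
    SimulationConfig,
    generate_dataset,
    generate_peptides,
    plant_profiles,
    simulate_counts,
)

SMALL = replace(DEFAULT_SIM_CONFIG, n_peptides=600)


class TestGeneratePeptides:
    def test_deterministic_under_seed(self):
        a = generate_peptides(SMALL, np.random.default_rng(7))
        b = generate_peptides(SMALL, np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_lengths_within_bounds_and_median_near_ten(self):
        medians = []
        for seed in range(10):
            peps = generate_peptides(SMALL, np.random.default_rng(seed))
            lengths = peps.index.str.len()
            assert lengths.min() >= 6 and lengths.max() <= 30
            medians.append(np.median(lengths))
        assert 9 <= np.median(medians) <= 11

    def test_sequences_distinct(self):
        peps = generate_peptides(SMALL, np.random.default_rng(1))
        assert peps.index.is_unique

    def test_infeasible_config_rejected(self):
        bad = replace(SMALL, length_shape=0.0)
        with pytest.raises(ValueError):
            generate_peptides(bad, np.random.default_rng(0))

    def test_yeast_frequencies_shift_composition(self):
        from pepkin.simulate import YEAST_RESIDUE_FREQS

        cfg = replace(SMALL, residue_freqs=YEAST_RESIDUE_FREQS)
        peps = generate_peptides(cfg, np.random.default_rng(2))
        joined = "".join(peps.index)
        # leucine is ~5x more frequent than tryptophan in the yeast proteome
        assert joined.count("L") > 2 * joined.count("W")


class TestPlantProfiles:
    def test_planting_rules_respect_barcode_eligibility(self):
        peps = generate_peptides(SMALL, np.random.default_rng(3))
        truth = plant_profiles(peps, SMALL, np.random.default_rng(3))
        for cls, row in truth.classes.iterrows():
            if row["label"] == "decreasing":
                assert cls[4] == "3" and cls[0] == "1"
            elif row["label"] == "increasing":
                assert cls[4] == "1" and cls[8] == "3"

    def test_truth_covers_all_peptides_and_classes(self):
        peps = generate_peptides(SMALL, np.random.default_rng(4))
        truth = plant_profiles(peps, SMALL, np.random.default_rng(4))
        assert set(truth.peptides.index) == set(peps.index)
        assert set(truth.peptides["class"]) == set(truth.classes.index)
        for seq, row in truth.peptides.iterrows():
            assert assign_barcode(compute_property_vector(seq)) == row["class"]

    def test_planted_counts_match_config(self):
        cfg = replace(SMALL, n_decreasing=4, n_increasing=3, n_fluctuating=2)
        peps = generate_peptides(cfg, np.random.default_rng(5))
        truth = plant_profiles(peps, cfg, np.random.default_rng(5))
        counts = truth.classes["label"].value_counts()
        assert counts.get("decreasing", 0) <= 4
        assert counts.get("increasing", 0) <= 3
        assert counts.get("fluctuating", 0) == 2


class TestSimulateCounts:
    def test_constant_profile_poisson_mean(self):
        peps = pd.DataFrame(
            {"base_rate": [10.0]}, index=pd.Index(["AAAAAA"], name="sequence")
        )
        truth_classes = pd.DataFrame(
            {"label": ["constant"]},
            index=pd.Index([assign_barcode(compute_property_vector("AAAAAA"))],
                           name="class"),
        )
        from pepkin.simulate import GroundTruth

        truth = GroundTruth(
            classes=truth_classes,
            peptides=peps.assign(**{"class": truth_classes.index[0]})[
                ["class", "base_rate"]
            ],
        )
        cfg = replace(DEFAULT_SIM_CONFIG, replicates=200, timepoints=(0.0, 6.0))
        psm = simulate_counts(truth, cfg, np.random.default_rng(6))
        mean = psm.loc[psm["timepoint_h"] == 0.0, "spectra"].sum() / 200
        assert mean == pytest.approx(10.0, abs=0.7)

    def test_decreasing_profile_four_fold_drop(self):
        from pepkin.simulate import GroundTruth

        cls = assign_barcode(compute_property_vector("KRKRKR"))
        peps = pd.DataFrame(
            {"class": [cls], "base_rate": [40.0]},
            index=pd.Index(["KRKRKR"], name="sequence"),
        )
        truth = GroundTruth(
            classes=pd.DataFrame({"label": ["decreasing"]},
                                 index=pd.Index([cls], name="class")),
            peptides=peps,
        )
        cfg = replace(DEFAULT_SIM_CONFIG, replicates=300, timepoints=(0.0, 6.0))
        psm = simulate_counts(truth, cfg, np.random.default_rng(8))
        by_t = psm.groupby("timepoint_h")["spectra"].sum() / 300
        assert by_t[6.0] / by_t[0.0] == pytest.approx(0.25, abs=0.03)

    def test_zero_rate_emits_nothing(self):
        from pepkin.simulate import GroundTruth

        cls = assign_barcode(compute_property_vector("AAAAAA"))
        truth = GroundTruth(
            classes=pd.DataFrame({"label": ["constant"]},
                                 index=pd.Index([cls], name="class")),
            peptides=pd.DataFrame(
                {"class": [cls], "base_rate": [0.0]},
                index=pd.Index(["AAAAAA"], name="sequence"),
            ),
        )
        psm = simulate_counts(truth, DEFAULT_SIM_CONFIG,
                              np.random.default_rng(9))
        assert len(psm) == 0


class TestEndToEndDataset:
    def test_seed_reproducibility_byte_level(self, tmp_path):
        cfg = replace(DEFAULT_SIM_CONFIG, n_peptides=400)
        paths = []
        for i in (1, 2):
            psm, _ = generate_dataset(cfg, seed=123)
            p = tmp_path / f"run{i}.tsv"
            psm.to_csv(p, sep="\t", index=False)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_singleton_fraction_matches_abundance_law(self):
        from pepkin.io_aggregate import summarize_sample

        psm, _ = generate_dataset(DEFAULT_SIM_CONFIG, seed=11)
        sample = psm[(psm["replicate"] == 1) & (psm["timepoint_h"] == 0.0)]
        n, _, bins = summarize_sample(sample)
        assert 0.7 <= bins["1"] / n <= 0.9
        assert bins[">10"] / n < 0.02
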