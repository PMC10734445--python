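"""Relative abundance, sketch ANI, and re-occurrence matching."""

import numpy as np
import pandas as pd
import pytest

from magtraits.abundance import (
    ani_matrix,
    estimate_ani,
    find_reoccurring,
    relative_abundance,
)
from magtraits.simulate import mutate_dna, random_dna


class TestRelativeAbundance:
    def test_single_sample_fractions(self):
        counts = pd.DataFrame({"g1": [70], "g2": [20], "g3": [10]}, index=["S1"])
        fractions, _ = relative_abundance(counts)
        assert fractions.loc["S1"].tolist() == pytest.approx([0.7, 0.2, 0.1])

    def test_mean_and_sample_sd_across_samples(self):
        """Host fractions 0.65/0.71/0.77 summarize as 0.71 +/- 0.06."""
        counts = pd.DataFrame(
            {"host": [65, 71, 77], "epi": [35, 29, 23]}, index=["S1", "S2", "S3"]
        )
        _, summary = relative_abundance(counts)
        assert summary.loc["host", "mean_fraction"] == pytest.approx(0.71)
        assert summary.loc["host", "sd_fraction"] == pytest.approx(0.06)

    def test_single_genome_fraction_one(self):
        counts = pd.DataFrame({"g1": [123, 7]}, index=["S1", "S2"])
        fractions, summary = relative_abundance(counts)
        assert (fractions["g1"] == 1.0).all()
        assert summary.loc["g1", "sd_fraction"] == 0.0

    def test_zero_total_sample_error_names_sample(self):
        counts = pd.DataFrame({"g1": [10, 0]}, index=["S1", "S2"])
        with pytest.raises(ValueError, match="S2"):
            relative_abundance(counts)

    def test_scale_invariance(self):
        counts = pd.DataFrame({"g1": [10, 4], "g2": [30, 6]}, index=["S1", "S2"])
        scaled = counts.copy()
        scaled.loc["S1"] *= 17
        f1, _ = relative_abundance(counts)
        f2, _ = relative_abundance(scaled)
        assert np.allclose(f1.to_numpy(), f2.to_numpy())


class TestEstimateANI:
    def test_identical_sequences_are_100(self):
        rng = np.random.default_rng(0)
        seq = random_dna(50_000, rng)
        assert estimate_ani(seq, seq) == 100.0

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = random_dna(20_000, rng)
        b = mutate_dna(a, 0.05, rng)
        assert estimate_ani(a, b, seed=3) == estimate_ani(b, a, seed=3)

    def test_three_percent_pair_within_half_point(self):
        rng = np.random.default_rng(2)
        a = random_dna(50_000, rng)
        b = mutate_dna(a, 0.03, rng)
        true = 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
        assert abs(estimate_ani(a, b, k=16, sketch_size=5000) - true) <= 0.5

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            estimate_ani("ACGT" * 10, "ACGT" * 10, k=16)

    def test_k_outside_range_rejected(self):
        rng = np.random.default_rng(3)
        seq = random_dna(1000, rng)
        with pytest.raises(ValueError):
            estimate_ani(seq, seq, k=8)


class TestFindReoccurring:
    def test_shared_identical_genome_matches_at_100(self):
        rng = np.random.default_rng(4)
        shared = random_dna(20_000, rng)
        other = random_dna(20_000, rng)
        matches = find_reoccurring({"a1": shared}, {"b1": shared, "b2": other})
        assert len(matches) == 1
        m = matches[0]
        assert m.genome_b == "b1" and m.ani_pct == 100.0 and m.reoccurring

    def test_exactly_at_threshold_is_not_reoccurring(self):
        identity = pd.DataFrame([[97.5]], index=["a1"], columns=["b1"])
        matches = find_reoccurring(identity=identity)
        assert len(matches) == 1 and not matches[0].reoccurring
        above = pd.DataFrame([[97.51]], index=["a1"], columns=["b1"])
        assert find_reoccurring(identity=above)[0].reoccurring

    def test_planted_pairs_recovered_exactly(self):
        rng = np.random.default_rng(5)
        seqs_a, seqs_b = {}, {}
        planted = []
        for i in range(3):
            base = random_dna(20_000, rng)
            seqs_a[f"p{i}_a"] = base
            seqs_b[f"p{i}_b"] = mutate_dna(base, 0.01, rng)
            planted.append((f"p{i}_a", f"p{i}_b"))
        for i in range(3):  # unrelated noise genomes
            seqs_a[f"n{i}_a"] = random_dna(20_000, rng)
            seqs_b[f"n{i}_b"] = random_dna(20_000, rng)
        matches = find_reoccurring(seqs_a, seqs_b, seed=6)
        reoccurring = {(m.genome_a, m.genome_b) for m in matches if m.reoccurring}
        assert reoccurring == set(planted)

    def test_greedy_matching_is_one_to_one(self):
        identity = pd.DataFrame(
            [[99.0, 98.0], [98.5, 97.0]],
            index=["a1", "a2"],
            columns=["b1", "b2"],
        )
        matches = find_reoccurring(identity=identity)
        assert {m.genome_a for m in matches} == {"a1", "a2"}
        assert len({m.genome_b for m in matches}) == 2
        best = {m.genome_a: m.genome_b for m in matches}
        assert best["a1"] == "b1"  # highest pair claimed first

    def test_empty_sets_give_empty_result(self):
        assert find_reoccurring({}, {}) == []
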