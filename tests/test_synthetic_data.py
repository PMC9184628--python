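import numpy as np
import pytest

from hostdeplete.errors import ConfigError
from hostdeplete.evaluation import cg_fraction
from hostdeplete.sequence_io import read_sequences
from hostdeplete.synthetic_data import (
    CompositionProfile,
    ReadSetSpec,
    apply_noise,
    generate_read_set,
    host_profile,
    microbe_profile,
    read_truth,
    sample_sequence,
    write_read_set,
)


class TestCompositionProfile:
    def test_rows_must_sum_to_one(self):
        bad = np.full((4, 4), 0.2)
        with pytest.raises(ConfigError):
            CompositionProfile(bad)

    def test_default_profiles_valid(self):
        for profile in (host_profile(), microbe_profile()):
            np.testing.assert_allclose(profile.transition_matrix.sum(axis=1), 1.0)

    def test_stationary_distribution_is_fixed_point(self):
        profile = host_profile()
        pi = profile.stationary_distribution()
        np.testing.assert_allclose(pi @ profile.transition_matrix, pi, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)


class TestSampleSequence:
    def test_degenerate_chain_gives_poly_a(self):
        t = np.zeros((4, 4))
        t[:, 0] = 1.0
        profile = CompositionProfile(t, initial_distribution=[1, 0, 0, 0])
        assert sample_sequence(profile, 10, seed=0) == "AAAAAAAAAA"

    def test_seed_determinism(self):
        profile = microbe_profile()
        assert sample_sequence(profile, 500, seed=4) == sample_sequence(profile, 500, seed=4)
        assert sample_sequence(profile, 500, seed=4) != sample_sequence(profile, 500, seed=5)

    def test_cg_fraction_matches_stationary_oracle(self):
        """Eigen-analysis oracle: stationary P(C) * P(G|C) vs the empirical
        CG dimer fraction of a long sampled sequence."""
        profile = host_profile(cg_transition=0.002)
        expected = profile.expected_cg_fraction()
        pi = profile.stationary_distribution()
        assert expected == pytest.approx(pi[1] * 0.002)
        seq = sample_sequence(profile, 100_000, seed=1)
        empirical = cg_fraction(seq)
        assert abs(empirical - expected) <= 0.2 * expected

    def test_uniform_profile_cg_near_one_sixteenth(self):
        seq = sample_sequence(microbe_profile(), 100_000, seed=2)
        assert cg_fraction(seq) == pytest.approx(1 / 16, rel=0.1)

    def test_invalid_length(self):
        with pytest.raises(ConfigError):
            sample_sequence(microbe_profile(), 0, seed=0)


class TestApplyNoise:
    def test_zero_rates_identity(self):
        seq = sample_sequence(microbe_profile(), 300, seed=0)
        assert apply_noise(seq, (0.0, 0.0, 0.0), seed=1) == seq

    def test_substitution_rate_one_changes_every_base(self):
        seq = sample_sequence(microbe_profile(), 200, seed=0)
        noisy = apply_noise(seq, (1.0, 0.0, 0.0), seed=1)
        assert len(noisy) == len(seq)
        assert all(a != b for a, b in zip(seq, noisy))

    def test_substitution_only_hamming_matches_binomial(self):
        """Sub-only edit distance IS the Hamming distance = Binomial(L, p)."""
        length, p, n_seeds = 1000, 0.05, 100
        seq = sample_sequence(microbe_profile(), length, seed=3)
        distances = [
            sum(a != b for a, b in zip(seq, apply_noise(seq, (p, 0.0, 0.0), seed=s)))
            for s in range(n_seeds)
        ]
        expected = length * p
        se = np.sqrt(length * p * (1 - p) / n_seeds)
        assert abs(np.mean(distances) - expected) <= 3 * se

    @pytest.mark.parametrize("rates,sign", [((0.0, 0.04, 0.0), +1), ((0.0, 0.0, 0.04), -1)])
    def test_indel_only_length_change_matches_binomial(self, rates, sign):
        length, n_seeds = 1000, 100
        p = max(rates)
        seq = sample_sequence(microbe_profile(), length, seed=4)
        deltas = [sign * (len(apply_noise(seq, rates, seed=s)) - length) for s in range(n_seeds)]
        expected = length * p
        se = np.sqrt(length * p * (1 - p) / n_seeds)
        assert abs(np.mean(deltas) - expected) <= 3 * se

    def test_combined_rates_expected_length_change(self):
        length, n_seeds = 2000, 60
        sub, ins, dele = 0.05, 0.03, 0.03
        seq = sample_sequence(microbe_profile(), length, seed=5)
        deltas = [
            len(apply_noise(seq, (sub, ins, dele), seed=s)) - length for s in range(n_seeds)
        ]
        expected = length * (ins - dele)  # zero here
        sd = np.sqrt(length * (ins * (1 - ins) + dele * (1 - dele)))
        assert abs(np.mean(deltas) - expected) <= 3 * sd / np.sqrt(n_seeds)


class TestGenerateReadSet:
    def test_host_count_exact(self):
        spec = ReadSetSpec(n_reads=200, host_fraction=0.5, length_median=200,
                           min_length=100, max_length=400, seed=0)
        reads, labels = generate_read_set(spec)
        assert len(reads) == 200
        assert sum(labels) == 100

    def test_ninety_nine_percent_host(self):
        spec = ReadSetSpec(n_reads=300, host_fraction=0.99, length_median=150,
                           min_length=100, max_length=300, seed=1)
        _, labels = generate_read_set(spec)
        assert sum(labels) == round(300 * 0.99)

    def test_lengths_clipped(self):
        spec = ReadSetSpec(n_reads=100, length_median=300, length_sigma=2.0,
                           min_length=100, max_length=500, seed=2)
        reads, _ = generate_read_set(spec)
        assert all(100 <= r.length <= 500 for r in reads)

    def test_byte_identical_outputs(self, tmp_path):
        spec = ReadSetSpec(n_reads=50, length_median=200, min_length=100,
                           max_length=400, substitution_rate=0.02,
                           insertion_rate=0.01, deletion_rate=0.01, seed=7)
        contents = []
        for tag in ("a", "b"):
            reads, labels = generate_read_set(spec)
            fq = tmp_path / f"{tag}.fastq"
            truth = tmp_path / f"{tag}.tsv"
            write_read_set(reads, labels, "fastq", fq, truth)
            contents.append((fq.read_bytes(), truth.read_bytes()))
        assert contents[0] == contents[1]

    def test_truth_table_partitions_read_set(self, tmp_path):
        spec = ReadSetSpec(n_reads=80, host_fraction=0.25, length_median=150,
                           min_length=100, max_length=300, seed=3)
        reads, labels = generate_read_set(spec)
        fq = tmp_path / "reads.fastq"
        truth_path = tmp_path / "truth.tsv"
        write_read_set(reads, labels, "fastq", fq, truth_path)
        truth = read_truth(truth_path)
        file_ids = [r.id for r in read_sequences(fq, "fastq")]
        assert sorted(file_ids) == sorted(truth)
        assert sum(truth.values()) == 20

    def test_composition_contrast(self):
        """Host reads must sit >= 2 CG percentage points below microbe reads."""
        spec = ReadSetSpec(n_reads=500, host_fraction=0.5, length_median=500,
                           min_length=200, max_length=1000, seed=4)
        reads, labels = generate_read_set(spec)
        host_cg = np.mean([cg_fraction(r.bases) for r, l in zip(reads, labels) if l == 1])
        microbe_cg = np.mean([cg_fraction(r.bases) for r, l in zip(reads, labels) if l == 0])
        assert microbe_cg - host_cg >= 0.02

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            ReadSetSpec(host_fraction=1.5)
        with pytest.raises(ConfigError):
            ReadSetSpec(min_length=10)
        with pytest.raises(ConfigError):
            ReadSetSpec(substitution_rate=1.2)
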