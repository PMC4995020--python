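import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_kmer_frequencies, random_sequence_set
from nadda.errors import InputError, ParameterError
from nadda.kmer_profile import (
    KmerFrequencyTable,
    build_profiles,
    count_kmer_frequencies,
    parallel_build_profiles,
    profile_stats,
    read_frequency_table,
    read_profiles,
    write_frequency_table,
    write_profiles,
)
from nadda.sequence_io import ProteinSequence, SequenceSet


class TestCountFrequencies:
    def test_single_sequence_repeats_count_once(self):
        seqs = SequenceSet([ProteinSequence("a", "ABCAB")])
        table = count_kmer_frequencies(seqs, 2)
        # AB appears twice in one sequence but counts that sequence once
        assert table.counts == {"AB": 1, "BC": 1, "CA": 1}

    def test_two_sequence_membership(self, toy_seqs):
        table = count_kmer_frequencies(toy_seqs, 2)
        assert table.counts == {"AB": 2, "BC": 2, "CA": 2}

    def test_identical_copies_double_every_frequency(self):
        seqs = SequenceSet(
            [ProteinSequence("a", "MKVLWAA"), ProteinSequence("b", "MKVLWAA")]
        )
        table = count_kmer_frequencies(seqs, 3)
        assert set(table.counts.values()) == {2}

    def test_short_sequences_contribute_nothing(self):
        seqs = SequenceSet(
            [ProteinSequence("a", "MK"), ProteinSequence("b", "MKVL")]
        )
        table = count_kmer_frequencies(seqs, 3)
        assert table.counts == {"MKV": 1, "KVL": 1}

    @pytest.mark.parametrize("k", [0, -1, 13])
    def test_invalid_k_rejected(self, toy_seqs, k):
        with pytest.raises(ParameterError):
            count_kmer_frequencies(toy_seqs, k)


class TestBuildProfiles:
    def test_worked_profile_with_zero_tail(self, toy_seqs):
        table = count_kmer_frequencies(toy_seqs, 2)
        prof_a, prof_b = build_profiles(toy_seqs, table)
        assert prof_a.values.tolist() == [2, 2, 2, 2, 0]
        assert prof_a.valid_len == 4
        assert prof_b.values.tolist() == [2, 2, 2, 2, 0]

    def test_sequence_shorter_than_k_is_all_zero(self):
        seqs = SequenceSet([ProteinSequence("a", "MK")])
        table = KmerFrequencyTable(k=3, counts={})
        (prof,) = build_profiles(seqs, table)
        assert prof.values.tolist() == [0, 0]
        assert prof.valid_len == 0

    def test_self_table_gives_all_ones(self):
        seqs = SequenceSet([ProteinSequence("a", "MKVLWAACDE")])
        table = count_kmer_frequencies(seqs, 3)
        (prof,) = build_profiles(seqs, table)
        assert prof.values[: prof.valid_len].tolist() == [1] * 8

    def test_missing_kmer_gets_zero_with_warning(self, caplog):
        seqs = SequenceSet([ProteinSequence("a", "MKVL")])
        table = KmerFrequencyTable(k=2, counts={"MK": 5})
        with caplog.at_level("WARNING"):
            (prof,) = build_profiles(seqs, table)
        assert prof.values.tolist() == [5, 0, 0, 0]
        assert "absent" in caplog.text


class TestOracleEquivalence:
    @given(seed=st.integers(0, 200), k=st.integers(1, 4))
    @settings(max_examples=60)
    def test_counts_match_naive_substring_scan(self, seed, k):
        rng = np.random.default_rng(seed)
        seqs = random_sequence_set(rng)
        table = count_kmer_frequencies(seqs, k)
        assert dict(table.counts) == naive_kmer_frequencies(seqs, k)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30)
    def test_profile_bounds_and_tail(self, seed):
        rng = np.random.default_rng(seed)
        seqs = random_sequence_set(rng)
        k = 3
        profiles = build_profiles(seqs, count_kmer_frequencies(seqs, k))
        for prof in profiles:
            assert (prof.values >= 0).all() and (prof.values <= seqs.n).all()
            assert (prof.values[prof.valid_len :] == 0).all()

    def test_permutation_invariance(self, rng):
        seqs = random_sequence_set(rng)
        order = rng.permutation(seqs.n)
        permuted = SequenceSet([list(seqs)[i] for i in order])
        t1 = count_kmer_frequencies(seqs, 3)
        t2 = count_kmer_frequencies(permuted, 3)
        assert dict(t1.counts) == dict(t2.counts)
        p1 = {p.seq_id: p for p in build_profiles(seqs, t1)}
        p2 = {p.seq_id: p for p in build_profiles(permuted, t2)}
        assert p1 == p2

    def test_adding_a_sequence_never_decreases_frequencies(self, rng):
        seqs = random_sequence_set(rng)
        before = count_kmer_frequencies(seqs, 2).counts
        grown = SequenceSet(list(seqs) + [ProteinSequence("extra", "ACDEAC")])
        after = count_kmer_frequencies(grown, 2).counts
        assert all(after[kmer] >= freq for kmer, freq in before.items())


class TestParallel:
    @pytest.mark.parametrize("workers", [1, 2, 4])
    def test_equals_serial_on_random_input(self, rng, workers):
        seqs = random_sequence_set(rng, n_max=50, len_max=80)
        serial = build_profiles(seqs, count_kmer_frequencies(seqs, 3))
        assert parallel_build_profiles(seqs, 3, workers) == serial

    def test_empty_input_gives_empty_list(self):
        assert parallel_build_profiles(SequenceSet(), 6, 4) == []

    def test_invalid_workers_rejected(self, toy_seqs):
        with pytest.raises(ParameterError):
            parallel_build_profiles(toy_seqs, 2, 0)


class TestProfileStats:
    def test_constant_vector(self, toy_seqs):
        profiles = build_profiles(
            toy_seqs, count_kmer_frequencies(toy_seqs, 2)
        )
        stats = profile_stats(profiles[:1])
        assert stats.mean == 2.0
        assert stats.variance == 0.0
        assert stats.n_positions == 4

    def test_pooled_mean_and_population_variance(self):
        # valid entries pooled across profiles: {1, 3} and {2}
        from nadda.kmer_profile import KmerProfile

        p1 = KmerProfile("a", np.array([1, 3, 0]), k=2)
        p2 = KmerProfile("b", np.array([2, 0]), k=2)
        stats = profile_stats([p1, p2])
        assert stats.mean == pytest.approx(2.0)
        assert stats.variance == pytest.approx(2.0 / 3.0)

    def test_all_singleton_dataset_has_mean_one(self):
        seqs = SequenceSet(
            [ProteinSequence("a", "ACDEF"), ProteinSequence("b", "KLMNP")]
        )
        profiles = build_profiles(seqs, count_kmer_frequencies(seqs, 3))
        assert profile_stats(profiles).mean == 1.0

    def test_no_valid_positions_is_an_error(self):
        seqs = SequenceSet([ProteinSequence("a", "MK")])
        profiles = build_profiles(seqs, KmerFrequencyTable(k=3, counts={}))
        with pytest.raises(InputError, match="undefined"):
            profile_stats(profiles)


class TestSerialization:
    def test_profile_round_trip(self, tmp_path, toy_seqs):
        profiles = build_profiles(
            toy_seqs, count_kmer_frequencies(toy_seqs, 2)
        )
        path = tmp_path / "profiles.tsv"
        write_profiles(profiles, path)
        assert read_profiles(path) == profiles

    def test_table_round_trip(self, tmp_path, toy_seqs):
        table = count_kmer_frequencies(toy_seqs, 2)
        path = tmp_path / "table.tsv"
        write_frequency_table(table, path)
        back = read_frequency_table(path)
        assert back.k == 2 and dict(back.counts) == dict(table.counts)
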