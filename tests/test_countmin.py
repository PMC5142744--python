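"""CountMin sketch: overcount-only abundances, medians, histograms, files."""

from collections import Counter

import numpy as np
import pytest

from kmerprep import CountMinSketch, HashFamily, KmerSpec, SequenceRecord, iter_kmers
from kmerprep.countmin import COUNTER_CAP
from kmerprep.errors import EmptySequenceError, InvalidAlphabetError, SketchFileError
from kmerprep.kmer_core import decode_kmer, sequence_codes
from kmerprep.simulate import simulate_genome


def fresh(spec, family):
    return CountMinSketch(spec, family)


class TestAddGet:
    def test_first_add_returns_one(self, spec3, small_family):
        assert fresh(spec3, small_family).add("AAA") == 1

    def test_never_added_reads_zero(self, spec3, small_family):
        assert fresh(spec3, small_family).get("AAA") == 0

    def test_strands_count_together(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        cm.add("AAA")
        assert cm.get("TTT") == 1

    def test_saturates_at_cap(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        for _ in range(COUNTER_CAP + 10):
            cm.add("AAA")
        assert cm.get("AAA") == COUNTER_CAP

    def test_exact_below_cap_without_collisions(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        for _ in range(17):
            cm.add("ACG")
        assert cm.get("ACG") == 17

    def test_invalid_kmer_rejected(self, spec3, small_family):
        with pytest.raises(InvalidAlphabetError):
            fresh(spec3, small_family).add("ANA")
        with pytest.raises(InvalidAlphabetError):
            fresh(spec3, small_family).get("ANA")


class TestOvercountOnly:
    def test_never_undercounts_vs_exact_counter(self, small_family):
        """Estimated count >= true count for every k-mer of a random stream."""
        spec = KmerSpec(k=5, canonical=True)
        cm = CountMinSketch(spec, small_family)
        genome = simulate_genome(2_000, seed=11)
        exact = Counter(km for _, km in iter_kmers(genome, spec))
        cm.consume_sequence(genome)
        agree = sum(cm.get(km) == c for km, c in exact.items())
        assert all(cm.get(km) >= c for km, c in exact.items())
        # tables ~1e5 cells, ~2e3 distinct k-mers: collisions should be rare
        assert agree / len(exact) >= 0.99

    def test_conservation_of_mass_pre_saturation(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        cm.consume_sequence(simulate_genome(500, seed=3))
        for tab in cm._tables:
            assert int(tab.sum()) == cm.n_consumed


class TestConsumeSequence:
    def test_counts_every_window(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        assert cm.consume_sequence("AAAAA") == 3
        assert cm.get("AAA") == 3

    def test_n_windows_skipped(self, small_family):
        cm = CountMinSketch(KmerSpec(2), small_family)
        assert cm.consume_sequence("AANAA") == 2

    def test_stream_batch_equivalence(self, spec20, big_family):
        """Consuming a whole file equals consuming read by read."""
        genome = simulate_genome(1_000, seed=5)
        reads = [genome[i : i + 100] for i in range(0, 900, 50)]
        a = CountMinSketch(spec20, big_family)
        b = CountMinSketch(spec20, big_family)
        a.consume_sequence("".join([]))  # no-op on empty
        for r in reads:
            a.consume_sequence(r)
        for r in reads:
            for _, km in iter_kmers(r, spec20):
                b.add(km)
        _, codes = sequence_codes(genome, spec20)
        assert np.array_equal(a.counts_for_codes(codes), b.counts_for_codes(codes))


class TestMedianCount:
    def test_collision_free_homopolymer(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        cm.consume_sequence("AAAAA")
        assert cm.median_count("AAAAA") == (3, 3.0, 0.0)

    def test_fresh_sketch_all_zero(self, spec3, small_family):
        med, mean, sd = fresh(spec3, small_family).median_count("ACGTACGT")
        assert (med, mean, sd) == (0, 0.0, 0.0)

    def test_upper_median_convention(self, spec3, small_family):
        """Counts [1, 9, 1] -> sorted [1, 1, 9] -> median is index n//2 = 1."""
        cm = fresh(spec3, small_family)
        # the read ATAGA has exactly the k-mers ATA, TAG, AGA at positions 0..2
        cm.add("ATA")
        for _ in range(9):
            cm.add("TAG")
        cm.add("AGA")
        med, mean, _ = cm.median_count("ATAGA")
        assert med == 1
        assert mean == pytest.approx(11 / 3)

    def test_no_valid_kmers_is_an_error(self, spec3, small_family):
        with pytest.raises(EmptySequenceError):
            fresh(spec3, small_family).median_count("AC")
        with pytest.raises(EmptySequenceError):
            fresh(spec3, small_family).median_count("ANANA")


class TestAbundanceDistribution:
    def test_single_repeated_kmer(self, spec3, small_family):
        cm = fresh(spec3, small_family)
        reads = [SequenceRecord(id="r", sequence="AAAA")]
        cm.consume_sequence("AAAA")
        hist = cm.abundance_distribution(reads)
        assert hist[2] == 1 and hist.sum() == 1

    def test_unique_kmers_all_in_bin_one(self, spec20, big_family):
        cm = CountMinSketch(spec20, big_family)
        genome = simulate_genome(300, seed=9)
        cm.consume_sequence(genome)
        hist = cm.abundance_distribution([genome])
        distinct = len({km for _, km in iter_kmers(genome, spec20)})
        assert hist[1] == distinct and hist.sum() == distinct

    def test_mode_near_coverage_on_simulated_reads(self, spec20, big_family, sim_reads):
        cm = CountMinSketch(spec20, big_family)
        for rec in sim_reads:
            cm.consume_sequence(rec.sequence)
        hist = cm.abundance_distribution(sim_reads)
        mode = int(hist[1:].argmax()) + 1
        # 20x nominal coverage; k-mer coverage is slightly lower (edge windows)
        assert 12 <= mode <= 24


class TestFpRate:
    def test_empty_sketch(self, spec3, small_family):
        assert fresh(spec3, small_family).fp_rate() == 0.0

    def test_formula_product_of_occupancies(self, spec3):
        cm = CountMinSketch(KmerSpec(3), HashFamily((5, 7)))
        cm._tables[0][:2] = 1  # 2/5 occupied
        cm._tables[1][:3] = 1  # 3/7 occupied
        assert cm.fp_rate() == pytest.approx((2 / 5) * (3 / 7))

    def test_matches_empirical_false_positive_rate(self, big_family):
        spec = KmerSpec(20)
        cm = CountMinSketch(spec, big_family)
        genome = simulate_genome(20_000, seed=13)
        cm.consume_sequence(genome)
        inserted = set(sequence_codes(genome, spec)[1].tolist())
        rng = np.random.default_rng(99)
        probes = []
        while len(probes) < 10_000:
            code = int(rng.integers(0, 4**20))
            if code not in inserted:
                probes.append(decode_kmer(code, 20))
        hits = sum(cm.get(p) > 0 for p in probes)
        assert abs(hits / len(probes) - cm.fp_rate()) < 0.02


class TestSerialization:
    def test_round_trip_identical_counts(self, spec3, small_family, tmp_path):
        cm = fresh(spec3, small_family)
        cm.consume_sequence(simulate_genome(400, seed=21))
        path = tmp_path / "sketch.mkm"
        cm.save(path)
        back = CountMinSketch.load(path)
        assert back.spec == cm.spec
        assert back.family == cm.family
        for tab_a, tab_b in zip(cm._tables, back._tables):
            assert np.array_equal(tab_a, tab_b)

    def test_truncated_file_is_an_error(self, spec3, small_family, tmp_path):
        cm = fresh(spec3, small_family)
        path = tmp_path / "sketch.mkm"
        cm.save(path)
        data = path.read_bytes()
        for cut in (4, 20, len(data) - 1):
            (tmp_path / "cut.mkm").write_bytes(data[:cut])
            with pytest.raises(SketchFileError):
                CountMinSketch.load(tmp_path / "cut.mkm")

    def test_bad_magic_named(self, tmp_path):
        path = tmp_path / "bogus.mkm"
        path.write_bytes(b"XXXX" + bytes(64))
        with pytest.raises(SketchFileError, match="magic"):
            CountMinSketch.load(path)

    def test_trailing_garbage_rejected(self, spec3, small_family, tmp_path):
        cm = fresh(spec3, small_family)
        path = tmp_path / "sketch.mkm"
        cm.save(path)
        path.write_bytes(path.read_bytes() + b"junk")
        with pytest.raises(SketchFileError, match="trailing"):
            CountMinSketch.load(path)

    def test_header_preserves_k(self, small_family, tmp_path):
        cm = CountMinSketch(KmerSpec(7), small_family)
        path = tmp_path / "k7.mkm"
        cm.save(path)
        assert CountMinSketch.load(path).spec.k == 7
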