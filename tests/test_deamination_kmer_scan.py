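from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from hsreg.deamination_kmer_scan import (
    MutantEntry,
    SeedOligo,
    cross_genome_presence,
    enumerate_mutants,
    per_position_profile,
    reverse_complement,
    scan_genome,
    wild_type_windows,
)


class TestSeedOligo:
    def test_c_positions(self):
        seed = SeedOligo("ACGC")
        assert seed.c_positions == (1, 3)
        assert seed.c_label(1) == "C1"
        assert seed.c_label(3) == "C2"

    def test_eleven_c_seed(self):
        seed = SeedOligo("CACACACACACACACACACACAGT")
        assert len(seed.sequence) == 24
        assert len(seed.c_positions) == 11

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            SeedOligo("ACGN")


class TestEnumerateMutants:
    def test_hand_enumerated_single_site(self):
        seed = SeedOligo("ACGC")
        entries = enumerate_mutants(seed, 4, 4, order=1, min_len_guard=4)
        assert {e.sequence for e in entries} == {"ATGC", "ACGT"}

    def test_order_two_adds_double_mutant(self):
        seed = SeedOligo("ACGC")
        entries = enumerate_mutants(seed, 4, 4, order=2, min_len_guard=4)
        assert {e.sequence for e in entries} == {"ATGC", "ACGT", "ATGT"}

    def test_entries_differ_exactly_at_labels(self):
        seed = SeedOligo("TTCAGGCATCGACTTACGGATCGG")
        for e in enumerate_mutants(seed, 12, 24, order=1):
            start, end = e.window
            wt = seed.sequence[start:end]
            diffs = [i for i, (a, b) in enumerate(zip(wt, e.sequence)) if a != b]
            assert len(diffs) == 1
            assert wt[diffs[0]] == "C" and e.sequence[diffs[0]] == "T"

    def test_brute_force_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 24)])
        seed = SeedOligo(seq)
        entries = enumerate_mutants(seed, 12, 24, order=1)
        # independent oracle: regenerate via set comprehension over all
        # (window, C index) pairs, deduplicating on (sequence, label)
        oracle = set()
        cpos = [i for i, b in enumerate(seq) if b == "C"]
        for start in range(24):
            for end in range(start + 12, 25):
                for p in cpos:
                    if start <= p < end:
                        sub = seq[start:end]
                        mut = sub[:p - start] + "T" + sub[p - start + 1:]
                        oracle.add((mut, f"C{cpos.index(p) + 1}"))
        assert {(e.sequence, e.labels[0]) for e in entries} == oracle

    def test_min_len_guard(self):
        with pytest.raises(ValueError):
            enumerate_mutants(SeedOligo("ACGTACGTACGT"), 4, 12)

    def test_seed_without_c_empty(self):
        entries = enumerate_mutants(SeedOligo("ATGGATTAGGTA"), 12, 12)
        assert entries == []

    def test_lengths_within_range(self):
        seed = SeedOligo("TTCAGGCATCGACTTACGGATCGG")
        entries = enumerate_mutants(seed, 12, 20, order=1)
        assert all(12 <= e.length <= 20 for e in entries)

    def test_wild_type_windows(self):
        wins = wild_type_windows(SeedOligo("ACGTACGTACGTA"), 12, 13)
        assert set(wins) == {"ACGTACGTACGT", "CGTACGTACGTA", "ACGTACGTACGTA"}


class TestScanGenome:
    def test_planted_count(self):
        rng = np.random.default_rng(2)
        filler = "".join(np.array(list("AG"))[rng.integers(0, 2, 500)])
        q = "CCTTACGGATCA"
        genome = {"chr1": filler + (q + filler) * 7}
        assert scan_genome([q], genome, "forward")[q] == 7

    def test_overlapping_occurrences_counted(self):
        genome = {"chr1": "AAAAAAAAAAAAAA"}
        assert scan_genome(["AAAAAAAAAA"], genome, "forward")["AAAAAAAAAA"] == 5

    def test_palindrome_dedup_both_strands(self):
        pal = "ACGTGCACGT"  # revcomp == ACGTGCACGT
        assert reverse_complement(pal) == pal
        genome = {"chr1": "TTTT" + pal + "TTTT"}
        assert scan_genome([pal], genome, "both")[pal] == 1

    def test_both_strands_counts_rc_hit(self):
        q = "ACCGGTTACA"
        genome = {"chr1": "GGGG" + reverse_complement(q) + "GGGG"}
        assert scan_genome([q], genome, "forward")[q] == 0
        assert scan_genome([q], genome, "both")[q] == 1

    def test_non_acgt_query_rejected(self):
        with pytest.raises(ValueError):
            scan_genome(["ACGN"], {"chr1": "ACGT"}, "forward")

    def test_ambiguity_in_genome_never_matches(self):
        genome = {"chr1": "ACGNACGT"}
        assert scan_genome(["ACGTACGT"], genome, "forward")["ACGTACGT"] == 0

    def test_naive_sliding_window_oracle(self):
        rng = np.random.default_rng(17)
        genome_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])
        genome = {"chr1": genome_seq}
        queries = []
        for _ in range(100):
            start = int(rng.integers(0, len(genome_seq) - 12))
            queries.append(genome_seq[start:start + 8] +
                           "".join(np.array(list("ACGT"))[rng.integers(0, 4, 4)]))
        counts = scan_genome(queries, genome, "both")
        for q in queries:
            rc = reverse_complement(q)
            oracle = {
                i for i in range(len(genome_seq) - len(q) + 1)
                if genome_seq[i:i + len(q)] in (q, rc)}
            assert counts[q] == len(oracle)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(19)
        genome_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20_000)])
        rc_genome = {"chr1": reverse_complement(genome_seq)}
        genome = {"chr1": genome_seq}
        queries = [genome_seq[i:i + 12] for i in rng.integers(0, 19_000, 20)]
        a = scan_genome(queries, genome, "both")
        b = scan_genome(queries, rc_genome, "both")
        assert a == b

    def test_appending_sequence_never_decreases(self):
        rng = np.random.default_rng(23)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5_000)])
        extra = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5_000)])
        queries = [base[i:i + 12] for i in range(0, 200, 13)]
        before = scan_genome(queries, {"chr1": base}, "both")
        after = scan_genome(queries, {"chr1": base + extra}, "both")
        assert all(after[q] >= before[q] for q in queries)


class TestPerPositionProfile:
    def test_uniform_flat(self):
        entries = [MutantEntry(f"SEQ{i}", (f"C{i+1}",), 12, (0, 12))
                   for i in range(4)]
        counts = {f"SEQ{i}": 10 for i in range(4)}
        prof = per_position_profile(entries, counts)
        assert set(prof["per_position"].values()) == {10}
        assert prof["asymmetry_ratio"] == pytest.approx(1.0)

    def test_planted_tenfold_split(self):
        entries = [MutantEntry(f"S{i}", (f"C{i+1}",), 12, (0, 12))
                   for i in range(6)]
        counts = {"S0": 100, "S1": 100, "S2": 100, "S3": 10, "S4": 10, "S5": 10}
        prof = per_position_profile(entries, counts)
        assert prof["asymmetry_ratio"] == pytest.approx(10.0)

    def test_empty_catalog(self):
        prof = per_position_profile([], {})
        assert prof["per_position"] == {} and prof["asymmetry_ratio"] is None


class TestCrossGenomePresence:
    def test_primate_only_query(self, cohort):
        # a human-branch insertion's interior sequence is absent from
        # every non-human genome by construction
        ins = next(i for i in cohort.insertions
                   if i.branch == "human" and len(i.sequence) > 100)
        q = ins.sequence[20:52]
        genomes = {sp: cohort.genomes[sp]
                   for sp in ("human", "chimp", "gorilla", "mouse", "rat")}
        out = cross_genome_presence([q], genomes)
        row = out["matrix"][q]
        assert row["human"] and not any(
            row[sp] for sp in ("chimp", "gorilla", "mouse", "rat"))

    def test_absent_everywhere(self):
        genomes = {"a": {"chr1": "ACGT" * 100}, "b": {"chr1": "ACGT" * 100}}
        out = cross_genome_presence(["TTTTTTTTTTTT"], genomes)
        assert out["all_genomes_fraction"] == 0.0

    def test_planted_conservation_rate(self):
        rng = np.random.default_rng(31)
        queries = []
        present_flags = []
        seq_a = []
        seq_b = []
        for i in range(60):
            q = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 16)])
            queries.append(q)
            seq_a.append(q)
            keep = rng.random() < 0.9
            present_flags.append(keep)
            if keep:
                seq_b.append(q)
        spacer = "TT" * 20
        genomes = {"a": {"chr1": spacer.join(seq_a)},
                   "b": {"chr1": spacer.join(seq_b)}}
        out = cross_genome_presence(queries, genomes, strands="forward")
        expected = sum(present_flags) / len(queries)
        assert out["per_genome_fraction"]["b"] >= expected  # chance re-hits only add
        assert out["per_genome_fraction"]["b"] == pytest.approx(expected, abs=0.05)

    def test_requires_two_genomes(self):
        with pytest.raises(ValueError):
            cross_genome_presence(["ACGTACGTACGT"], {"a": {"chr1": "ACGT"}})
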