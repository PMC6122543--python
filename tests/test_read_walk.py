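"""Read indexing, overlap discovery, consensus extension, and the full walk."""

import numpy as np
import pytest

from madswalk.read_walk import (
    Anchor,
    WalkParams,
    build_read_index,
    extend_once,
    find_overlapping_reads,
    sanitize_seed,
    walk,
)
from madswalk.records import SequenceRecord, revcomp
from madswalk.synthetic_data import sim_reads
from tests.conftest import random_dna

SMALL = WalkParams(k=8, min_overlap=10, min_support=1)


def _reads(seqs):
    return [SequenceRecord(f"r{i}", s, "dna") for i, s in enumerate(seqs)]


def test_index_palindromic_read_has_both_strand_postings():
    idx = build_read_index(_reads(["ACGTACGT"]), k=8)
    postings = idx.lookup("ACGTACGT")  # its own reverse complement
    assert sorted(strand for _, _, strand in postings) == ["+", "-"]


def test_index_empty_read_set():
    idx = build_read_index([], k=8)
    assert idx.lookup("ACGTACGT") == []


def test_index_rejects_small_k():
    with pytest.raises(ValueError, match="k must be >= 8"):
        build_read_index(_reads(["ACGTACGTACGT"]), k=4)


def test_index_completeness_on_simulated_reads(rng):
    """Every valid k-mer of every read is findable on the stated strand."""
    transcript = SequenceRecord("t", random_dna(rng, 600), "dna")
    reads = sim_reads([transcript], depth=5, read_len=60, seed=1)[:100]
    idx = build_read_index(reads, k=11)
    for r in reads:
        for strand, seq in (("+", r.seq), ("-", revcomp(r.seq))):
            for off in range(len(seq) - 11 + 1):
                kmer = seq[off : off + 11]
                assert (r.id, off, strand) in idx.lookup(kmer)


def test_find_overlapping_accepts_overhanging_read(rng):
    contig = random_dna(rng, 60)
    read = contig[-20:] + "GGATC"  # 20 nt overlap, 5 nt overhang
    idx = build_read_index(_reads([read]), k=8)
    anchors = find_overlapping_reads(idx, contig, "3", SMALL)
    assert len(anchors) == 1
    assert anchors[0].overlap == 20
    assert anchors[0].overhang == "GGATC"


def test_find_overlapping_rejects_contained_read(rng):
    contig = random_dna(rng, 60)
    idx = build_read_index(_reads([contig[10:40]]), k=8)
    assert find_overlapping_reads(idx, contig, "3", SMALL) == []


def test_find_overlapping_rejects_short_overlap(rng):
    contig = random_dna(rng, 60)
    read = contig[-8:] + random_dna(rng, 20)  # shares a k-mer but overlap 8 < 10
    idx = build_read_index(_reads([read]), k=8)
    assert find_overlapping_reads(idx, contig, "3", SMALL) == []


def test_find_overlapping_respects_mismatch_rate(rng):
    contig = random_dna(rng, 60)
    tail = list(contig[-30:])
    tail[0] = "A" if tail[0] != "A" else "C"
    tail[5] = "A" if tail[5] != "A" else "C"
    tail[11] = "A" if tail[11] != "A" else "C"  # 3 mismatches / 30 = 10%
    read = "".join(tail) + "GG"
    idx = build_read_index(_reads([read]), k=8)
    strict = WalkParams(k=8, min_overlap=10, max_mismatch_rate=0.05)
    loose = WalkParams(k=8, min_overlap=10, max_mismatch_rate=0.15)
    assert find_overlapping_reads(idx, contig, "3", strict) == []
    assert len(find_overlapping_reads(idx, contig, "3", loose)) == 1


def test_extend_once_no_candidates():
    contig = "ACGT" * 10
    new, added, support, reason = extend_once(contig, [], "3", SMALL)
    assert (new, added, support, reason) == (contig, 0, 0, "no_new_reads")


def test_extend_once_unanimous_overhang():
    contig = "ACGT" * 10
    anchors = [Anchor(f"r{i}", "+", 0, 20, 0, "AA") for i in range(3)]
    new, added, support, reason = extend_once(contig, anchors, "3", SMALL)
    assert new == contig + "AA"
    assert (added, support, reason) == (2, 3, None)


def test_extend_once_tie_stops_with_ambiguous():
    contig = "ACGT" * 10
    anchors = [
        Anchor("r1", "+", 0, 20, 0, "A"),
        Anchor("r2", "+", 0, 20, 0, "A"),
        Anchor("r3", "+", 0, 20, 0, "T"),
        Anchor("r4", "+", 0, 20, 0, "T"),
    ]
    new, added, _, reason = extend_once(contig, anchors, "3", SMALL)
    assert added == 0 and new == contig
    assert reason == "ambiguous"


def test_extend_once_five_prime_prepends_revcomp():
    contig = "ACGT" * 10
    anchors = [Anchor("r1", "+", 0, 20, 0, "CA")]  # overhang on the RC side
    new, added, _, _ = extend_once(contig, anchors, "5", SMALL)
    assert added == 2
    assert new == revcomp("CA") + contig


def test_walk_planted_truth_exact_recovery(rng):
    """Error-free tiled reads recover the planted transcript exactly."""
    for trial in range(10):
        L = int(rng.integers(300, 3001))
        truth = random_dna(rng, L)
        lo = int(0.3 * L)
        seed = truth[lo : lo + int(0.4 * L)]
        reads = sim_reads(
            [SequenceRecord("t", truth, "dna")], depth=10, read_len=100, seed=trial
        )
        idx = build_read_index(reads, k=21)
        result = walk(SequenceRecord("s", seed, "dna"), idx)
        assert result.final == truth
        assert result.termination == {"5": "no_new_reads", "3": "no_new_reads"}
        assert result.final[result.seed_offset : result.seed_offset + len(seed)] == seed


def test_walk_seed_only_reads_zero_extension(rng):
    seed = random_dna(rng, 120)
    idx = build_read_index(_reads([seed]), k=21)
    result = walk(SequenceRecord("s", seed, "dna"), idx)
    assert result.final == seed
    assert result.bases_added_5 == result.bases_added_3 == 0


def test_walk_rejects_short_seed(rng):
    idx = build_read_index(_reads([random_dna(rng, 50)]), k=8)
    with pytest.raises(ValueError, match="seed shorter"):
        walk(SequenceRecord("s", "ACGTAC", "dna"), idx, WalkParams(k=8, min_overlap=10))


def test_walk_monotone_safety(rng):
    """Raising min_support or min_overlap never lengthens the result."""
    for trial in range(5):
        truth = random_dna(rng, 800)
        seed = truth[240:560]
        reads = sim_reads(
            [SequenceRecord("t", truth, "dna")], depth=8, read_len=80, seed=trial
        )
        idx = build_read_index(reads, k=21)
        base = len(walk(seed, idx, WalkParams()).final)
        support2 = len(walk(seed, idx, WalkParams(min_support=2)).final)
        overlap51 = len(walk(seed, idx, WalkParams(min_overlap=51)).final)
        assert support2 <= base
        assert overlap51 <= base


def test_walk_iteration_cap_terminates(rng):
    truth = random_dna(rng, 2000)
    seed = truth[900:1100]
    reads = sim_reads([SequenceRecord("t", truth, "dna")], depth=10, read_len=100, seed=0)
    idx = build_read_index(reads, k=21)
    result = walk(seed, idx, WalkParams(max_iterations=2))
    assert set(result.termination.values()) <= {
        "max_iterations", "no_new_reads", "ambiguous"
    }
    assert "max_iterations" in result.termination.values()


def test_walk_length_cap_terminates(rng):
    truth = random_dna(rng, 2000)
    seed = truth[900:1100]
    reads = sim_reads([SequenceRecord("t", truth, "dna")], depth=10, read_len=100, seed=0)
    idx = build_read_index(reads, k=21)
    result = walk(seed, idx, WalkParams(max_length=250))
    assert len(result.final) < 250 + 100  # one extension round past the cap at most
    assert "max_length" in result.termination.values()


def test_walk_result_invariants(rng):
    truth = random_dna(rng, 1000)
    seed = truth[300:700]
    reads = sim_reads([SequenceRecord("t", truth, "dna")], depth=10, read_len=100, seed=3)
    idx = build_read_index(reads, k=21)
    r = walk(seed, idx)
    assert r.final[r.seed_offset : r.seed_offset + len(r.sanitized_seed)] == r.sanitized_seed
    assert r.bases_added_5 + r.bases_added_3 == len(r.final) - len(r.sanitized_seed)
    assert r.reads_consumed <= set(idx.reads)


def test_sanitize_trims_unsupported_prefix(rng):
    truth = random_dna(rng, 900)
    reads = sim_reads([SequenceRecord("t", truth, "dna")], depth=10, read_len=100, seed=2)
    idx = build_read_index(reads, k=21)
    corrupt = random_dna(rng, 150) + truth[150:600]
    clean, (start, end) = sanitize_seed(corrupt, idx, WalkParams())
    # every retained position agrees with the truth (corrupt bases that
    # coincide with the true base by chance are legitimately supported)
    assert clean == truth[start:end]
    assert start >= 140 and end == 600


def test_sanitize_returns_unsupported_seed_unchanged(rng):
    idx = build_read_index(_reads([random_dna(rng, 100)]), k=21)
    seed = random_dna(rng, 200)
    clean, span = sanitize_seed(seed, idx, WalkParams())
    assert clean == seed and span == (0, 200)


def test_walk_params_validation():
    with pytest.raises(ValueError):
        WalkParams(k=21, min_overlap=10)
    with pytest.raises(ValueError):
        WalkParams(max_mismatch_rate=0.7)
    with pytest.raises(ValueError):
        WalkParams(min_support=0)
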