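"""Profile construction and domain scanning against brute-force scoring."""

import math

import numpy as np
import pytest

from madswalk.align import MultipleAlignment
from madswalk.domain_scan import (
    ProfileModel,
    build_profile,
    classify_gene,
    deduplicate_proteins,
    scan_protein,
    scan_scaffold_sixframe,
)
from madswalk.records import AA_ALPHABET, SequenceRecord, revcomp
from madswalk.synthetic_data import _reverse_translate
from tests.conftest import random_protein


def _seed_msa(rows):
    return MultipleAlignment(
        [SequenceRecord(f"s{i}", r, "protein") for i, r in enumerate(rows)]
    )


def test_build_profile_single_row_log_odds():
    """One observation + pseudocount 1: log2(((1+1)/(1+20))/0.05) per match."""
    prof = build_profile(_seed_msa(["ACDEF"]), pseudocount=1.0)
    expected = math.log2(((1 + 1) / (1 + 20)) / 0.05)
    assert prof.log_odds[0, AA_ALPHABET.index("A")] == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(0.9297, abs=1e-4)


def test_build_profile_two_row_log_odds():
    prof = build_profile(_seed_msa(["ACDEF", "ATDEF"]), pseudocount=1.0)
    expected = math.log2(((2 + 1) / (2 + 20)) / 0.05)
    assert prof.log_odds[0, AA_ALPHABET.index("A")] == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(1.4475, abs=1e-4)
    # column 2: C and T each observed once
    one_of_two = math.log2(((1 + 1) / (2 + 20)) / 0.05)
    assert prof.log_odds[1, AA_ALPHABET.index("C")] == pytest.approx(one_of_two, abs=1e-4)


def test_consensus_outscores_every_seed_row(profiles):
    """Column independence: the consensus maximises the window score."""
    for prof, domain in zip(profiles, "MK"):
        seed = __import__("madswalk.synthetic_data", fromlist=["load_seed_alignment"]).load_seed_alignment(domain)
        consensus_score = prof.score_window(prof.consensus())
        for r in seed.records:
            assert consensus_score >= prof.score_window(r.seq)


def test_build_profile_rejects_empty():
    with pytest.raises(ValueError):
        build_profile(MultipleAlignment([]))


def test_profile_tsv_round_trip(profiles, tmp_path):
    m, _ = profiles
    path = tmp_path / "m.tsv"
    m.to_tsv(str(path))
    back = ProfileModel.from_tsv(str(path))
    assert back.label == m.label
    assert back.bit_threshold == pytest.approx(m.bit_threshold, abs=1e-5)
    assert np.allclose(back.log_odds, m.log_odds, atol=1e-5)


def test_scan_protein_finds_planted_consensus(profiles, rng):
    m, _ = profiles
    protein = SequenceRecord(
        "p", random_protein(rng, 10) + m.consensus() + random_protein(rng, 20), "protein"
    )
    hits = scan_protein(m, protein)
    assert len(hits) == 1
    assert hits[0].start == 10
    assert hits[0].end == 10 + m.width


def test_window_scores_equal_brute_force(profiles, rng):
    """Vectorised window scores match an explicit per-window scorer exactly."""
    from madswalk.domain_scan import _window_scores

    m, k = profiles
    for prof in (m, k):
        for _ in range(20):
            seq = random_protein(rng, 120)
            if rng.random() < 0.5:  # plant a domain half the time
                pos = int(rng.integers(0, 120 - prof.width))
                seq = seq[:pos] + prof.consensus() + seq[pos + prof.width :]
            scores = _window_scores(prof, seq)
            for i in range(len(seq) - prof.width + 1):
                assert scores[i] == pytest.approx(
                    prof.score_window(seq[i : i + prof.width]), abs=1e-9
                )


def test_scan_hits_are_thresholded_non_overlapping(profiles, rng):
    m, _ = profiles
    seq = (
        random_protein(rng, 10)
        + m.consensus()
        + random_protein(rng, 5)
        + m.consensus()
        + random_protein(rng, 10)
    )
    hits = scan_protein(m, SequenceRecord("p", seq, "protein"))
    assert all(h.score >= m.bit_threshold for h in hits)
    for a, b in zip(hits, hits[1:]):
        assert a.end <= b.start  # greedy pruning leaves disjoint windows


def test_scan_short_protein_returns_empty(profiles):
    m, _ = profiles
    assert scan_protein(m, SequenceRecord("p", "MKLV", "protein")) == []


def test_threshold_monotonicity(profiles, rng):
    """Raising the bit threshold never adds hits."""
    m, _ = profiles
    seq = random_protein(rng, 80) + m.consensus() + random_protein(rng, 80)
    protein = SequenceRecord("p", seq, "protein")
    low = scan_protein(m, protein)
    stricter = ProfileModel(m.label, m.log_odds, m.background, m.bit_threshold + 10)
    high = scan_protein(stricter, protein)
    assert {(h.start, h.end) for h in high} <= {(h.start, h.end) for h in low}


def test_sixframe_finds_planted_frame(profiles, rng):
    m, _ = profiles
    rng2 = np.random.default_rng(3)
    dna = _reverse_translate(m.consensus(), rng2)
    pad5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    pad3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    scaffold = SequenceRecord("scaf", pad5 + dna + pad3, "dna")
    hits = [h for h in scan_scaffold_sixframe(m, scaffold) if h.frame > 0]
    assert any(h.start == 30 and h.end == 30 + 3 * m.width for h in hits)

    rc = scaffold.reverse_complement()
    rc_hits = [h for h in scan_scaffold_sixframe(m, rc) if h.frame < 0]
    assert any(h.score == pytest.approx(max(x.score for x in hits)) for h in rc_hits)


def test_sixframe_reverse_complement_symmetry(profiles, rng):
    """RC of the scaffold mirrors hits: frame sign flips, coords reflect."""
    m, _ = profiles
    rng2 = np.random.default_rng(4)
    dna = _reverse_translate(m.consensus(), rng2)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=40)) + dna
    fwd = scan_scaffold_sixframe(m, SequenceRecord("s", seq, "dna"))
    rev = scan_scaffold_sixframe(m, SequenceRecord("s", revcomp(seq), "dna"))
    L = len(seq)
    mirrored = {(L - h.end, L - h.start, round(h.score, 6)) for h in rev}
    assert {(h.start, h.end, round(h.score, 6)) for h in fwd} == mirrored


@pytest.mark.parametrize(
    "has_m,has_k,expected",
    [(True, True, "type_II"), (True, False, "type_I"), (False, False, "non_MADS"),
     (False, True, "non_MADS")],
)
def test_classification_rule_table(has_m, has_k, expected, profiles):
    m, k = profiles
    hit = lambda p: [  # noqa: E731
        h for h in scan_protein(p, SequenceRecord("x", p.consensus(), "protein"))
    ]
    m_hits = hit(m) if has_m else []
    k_hits = hit(k) if has_k else []
    c = classify_gene(m_hits, k_hits)
    assert c.gene_type == expected
    assert c.has_M is has_m and c.has_K is has_k


def test_family_classification_recovers_planted_types(small_family, profiles):
    """Round trip: exactly the planted type I genes lack a K hit."""
    m, k = profiles
    type_i = [
        p.id
        for p in small_family.proteins
        if classify_gene(scan_protein(m, p), scan_protein(k, p)).gene_type == "type_I"
    ]
    truth_type_i = [
        gid for gid, clade in small_family.clade_labels.items() if clade == "M-alpha"
    ]
    assert sorted(type_i) == sorted(truth_type_i)
    assert len(type_i) == 2


def test_deduplicate_drops_identical_and_fragments():
    recs = [
        SequenceRecord("full", "MKLVAEQRMKLV", "protein"),
        SequenceRecord("dup", "MKLVAEQRMKLV", "protein"),
        SequenceRecord("frag", "VAEQR", "protein"),
        SequenceRecord("other", "WWWWWW", "protein"),
    ]
    kept = [r.id for r in deduplicate_proteins(recs)]
    assert kept == ["full", "other"]
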