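"""Iterative read-walk completion of incomplete transcript sequences.

The walk emulates targeted "genome walking" against an indexed short-read
set: the current contig terminus is used to fish out reads that overlap it
(k-mer anchored, ungapped), the overhanging bases beyond the contig end are
consensus-voted column by column, and the cycle repeats on the updated
terminus until no read extends either end. Ambiguity (a strict voting tie,
e.g. from a paralogous branch point) stops the walk at that column rather
than exploring branches, so every input yields a single deterministic
sequence.

An optional sanitization step trims seed termini that no indexed read
supports before walking; this lets the walk rebuild seed regions whose
annotated sequence is wrong (the walk itself only ever extends).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import SequenceRecord, WalkHistory, WalkResult, revcomp


@dataclass(frozen=True)
class WalkParams:
    """Free parameters of the walk loop."""

    k: int = 21
    min_overlap: int = 31
    max_mismatch_rate: float = 0.05
    min_support: int = 1
    max_iterations: int = 200
    max_length: int = 20_000

    def __post_init__(self) -> None:
        if self.min_overlap < self.k:
            raise ValueError("min_overlap must be >= k")
        if not 0 <= self.max_mismatch_rate < 0.5:
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class ReadIndex:
    """k-mer postings over a read store, both strands indexed."""

    k: int
    reads: dict[str, str] = field(default_factory=dict)
    postings: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    max_read_len: int = 0

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self.postings.get(kmer, [])

    def oriented(self, read_id: str, strand: str) -> str:
        seq = self.reads[read_id]
        return seq if strand == "+" else revcomp(seq)


def build_read_index(reads: list[SequenceRecord], k: int = 21) -> ReadIndex:
    """Index every valid k-mer of every read on both strands."""
    if k < 8:
        raise ValueError("k must be >= 8 (shorter k-mers collide heavily)")
    index = ReadIndex(k=k)
    for r in reads:
        if len(r.seq) < k:
            raise ValueError(f"read {r.id} shorter than k={k}")
        index.reads[r.id] = r.seq
        index.max_read_len = max(index.max_read_len, len(r.seq))
        for strand, seq in (("+", r.seq), ("-", revcomp(r.seq))):
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                index.postings.setdefault(kmer, []).append((r.id, off, strand))
    return index


@dataclass(frozen=True)
class Anchor:
    """Ungapped placement of an oriented read against a terminus."""

    read_id: str
    strand: str
    offset: int  # read start relative to terminus start (may be negative)
    overlap: int
    mismatches: int
    overhang: str  # bases extending beyond the terminus 3' edge


def _anchor_candidates(
    index: ReadIndex, terminus: str, params: WalkParams, require_overhang: bool
) -> list[Anchor]:
    """All acceptable ungapped read placements against ``terminus``.

    Placements are seeded by shared k-mers; the overlap is the intersection
    of the read with the terminus window, and must reach ``min_overlap`` at
    a mismatch rate <= ``max_mismatch_rate``. With ``require_overhang`` the
    read must extend past the terminus 3' edge.
    """
    k = index.k
    placements: dict[tuple[str, str], set[int]] = {}
    for t in range(len(terminus) - k + 1):
        kmer = terminus[t : t + k]
        if "N" in kmer:
            continue
        for read_id, off, strand in index.lookup(kmer):
            placements.setdefault((read_id, strand), set()).add(t - off)
    out: list[Anchor] = []
    L = len(terminus)
    for (read_id, strand), offsets in placements.items():
        seq = index.oriented(read_id, strand)
        best: Anchor | None = None
        for rel in offsets:
            lo, hi = max(0, rel), min(L, rel + len(seq))
            overlap = hi - lo
            if overlap < params.min_overlap:
                continue
            read_part = seq[lo - rel : hi - rel]
            term_part = terminus[lo:hi]
            mism = sum(a != b for a, b in zip(read_part, term_part))
            if mism > params.max_mismatch_rate * overlap:
                continue
            overhang = seq[L - rel :] if rel + len(seq) > L else ""
            if require_overhang and not overhang:
                continue
            cand = Anchor(read_id, strand, rel, overlap, mism, overhang)
            if best is None or (-cand.overlap, cand.mismatches) < (
                -best.overlap,
                best.mismatches,
            ):
                best = cand
        if best is not None:
            out.append(best)
    out.sort(key=lambda a: (-a.overlap, a.mismatches, a.read_id, a.strand))
    return out


def find_overlapping_reads(
    index: ReadIndex, terminus: str, end: str, params: WalkParams
) -> list[Anchor]:
    """Reads whose ungapped anchor alignment overlaps the terminus by at
    least ``min_overlap`` with a non-empty overhang beyond the contig end.

    ``terminus`` is the last (end='3') or first (end='5') stretch of the
    contig; the 5' case is handled on the reverse complement so overhangs
    are always 3'-ward of the returned anchors.
    """
    if len(terminus) < params.min_overlap:
        return []
    if end == "5":
        terminus = revcomp(terminus)
    elif end != "3":
        raise ValueError("end must be '5' or '3'")
    return _anchor_candidates(index, terminus, params, require_overhang=True)


def extend_once(
    contig: str, candidates: list[Anchor], end: str, params: WalkParams
) -> tuple[str, int, int, str | None]:
    """Majority-vote consensus extension over candidate overhangs.

    Extends column by column while support >= ``min_support`` and the
    majority fraction is strictly above 0.5; a strict tie stops extension
    with reason "ambiguous". Returns (contig', bases_added, support of the
    first extended column, stop reason or None).
    """
    consensus: list[str] = []
    reason: str | None = None
    first_support = 0
    col = 0
    while True:
        votes = Counter(a.overhang[col] for a in candidates if len(a.overhang) > col)
        support = sum(votes.values())
        if support < params.min_support:
            if col == 0:
                reason = "no_new_reads"
            break
        (base, count), *rest = votes.most_common()
        if rest and rest[0][1] == count:
            reason = "ambiguous"
            break
        if count * 2 <= support:
            reason = "ambiguous"
            break
        if col == 0:
            first_support = support
        consensus.append(base)
        col += 1
    ext = "".join(consensus)
    if not ext:
        return contig, 0, 0, reason or "no_new_reads"
    if end == "5":
        contig = revcomp(ext) + contig
    else:
        contig = contig + ext
    return contig, len(ext), first_support, reason


def sanitize_seed(
    seed: str, index: ReadIndex, params: WalkParams
) -> tuple[str, tuple[int, int]]:
    """Trim seed regions that no acceptable read covers.

    Reads are anchored to the whole seed (overhangs allowed, not required);
    a position counts as supported only when an accepted read agrees with
    the seed base there, so positions whose annotated base is wrong (every
    spanning read mismatches them) are left uncovered. The longest
    contiguous run of supported positions is kept. A seed with no support
    at all is returned unchanged.
    """
    anchors = _anchor_candidates(index, seed, params, require_overhang=False)
    coverage = [0] * len(seed)
    for a in anchors:
        read = index.oriented(a.read_id, a.strand)
        lo = max(0, a.offset)
        hi = min(len(seed), a.offset + len(read))
        for i in range(lo, hi):
            if read[i - a.offset] == seed[i]:
                coverage[i] += 1
    best = (0, 0)
    start = None
    for i, c in enumerate(coverage + [0]):
        if c > 0 and start is None:
            start = i
        elif c == 0 and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if best == (0, 0):
        return seed, (0, len(seed))
    return seed[best[0] : best[1]], best


def walk(
    seed: SequenceRecord | str,
    index: ReadIndex,
    params: WalkParams | None = None,
    sanitize: bool = False,
) -> WalkResult:
    """Iteratively extend ``seed`` at both ends until no read extends either.

    Alternates 3' and 5' extension rounds; each round fishes overlapping
    reads for the current terminus and appends the consensus overhang.
    Deterministic for fixed inputs. Termination reason per end is one of
    no_new_reads, ambiguous, max_iterations, max_length.
    """
    params = params or WalkParams()
    seed_id = seed.id if isinstance(seed, SequenceRecord) else "seed"
    seed_seq = seed.seq if isinstance(seed, SequenceRecord) else seed
    if len(seed_seq) < params.min_overlap:
        raise ValueError("seed shorter than min_overlap")
    if sanitize:
        clean, _ = sanitize_seed(seed_seq, index, params)
    else:
        clean = seed_seq
    contig = clean
    seed_offset = 0
    history: list[WalkHistory] = []
    consumed: set[str] = set()
    termination: dict[str, str] = {}
    active = {"3", "5"}
    iterations = 0
    terminus_len = max(index.max_read_len, params.min_overlap)
    while active:
        for end in ("3", "5"):
            if end not in active:
                continue
            iterations += 1
            if iterations > params.max_iterations:
                for e in sorted(active):
                    termination[e] = "max_iterations"
                active.clear()
                break
            if len(contig) >= params.max_length:
                for e in sorted(active):
                    termination[e] = "max_length"
                active.clear()
                break
            L = min(len(contig), terminus_len)
            terminus = contig[-L:] if end == "3" else contig[:L]
            candidates = find_overlapping_reads(index, terminus, end, params)
            new_contig, added, support, reason = extend_once(
                contig, candidates, end, params
            )
            if added:
                history.append(WalkHistory(end=end, bases_added=added, support=support))
                consumed.update(
                    a.read_id for a in candidates if a.overhang
                )
                if end == "5":
                    seed_offset += added
                contig = new_contig
            if added == 0 and reason is not None:
                # a tie (or no reads) with zero progress is final for this
                # end; a tie after progress is re-examined from the new
                # terminus next round, where deeper coverage may resolve it
                termination[end] = reason
                active.discard(end)
    return WalkResult(
        seed_id=seed_id,
        seed=seed_seq,
        final=contig,
        seed_offset=seed_offset,
        sanitized_seed=clean,
        history=history,
        reads_consumed=consumed,
        termination=termination,
    )
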