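"""Pairwise and progressive alignment primitives.

These stand behind probe search (local alignment), the family multiple
alignment (progressive profile alignment over an NJ guide tree), alignment
cropping, and p-distance computation for tree building.

Dynamic programming uses a linear gap penalty (``gap_open`` applied per gap
base; ``gap_extend`` must equal ``gap_open``) so that each DP row can be
vectorised: within a row the horizontal recurrence
``M[j] = max(T[j], M[j-1] + g)`` equals ``max_prefix(T[k] - g*k) + g*j``.
Traceback tie-break is deterministic: diagonal > up (gap in b) > left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .records import AA_ALPHABET, SequenceRecord

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch or matrix scoring with a linear gap penalty."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0
    matrix: str | None = None  # e.g. "BLOSUM62"; overrides match/mismatch

    def __post_init__(self) -> None:
        if self.mismatch > self.match:
            raise ValueError("mismatch score must not exceed match score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_open != self.gap_extend:
            raise NotImplementedError("only linear gaps (open == extend) supported")

    def pair_scores(self, alphabet: str) -> np.ndarray:
        """Square score matrix over ``alphabet`` (rows/cols in that order)."""
        n = len(alphabet)
        if self.matrix is None:
            s = np.full((n, n), self.mismatch, dtype=float)
            np.fill_diagonal(s, self.match)
            return s
        mat = substitution_matrices.load(self.matrix)
        s = np.zeros((n, n))
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                try:
                    s[i, j] = mat[a, b]
                except (KeyError, IndexError):
                    s[i, j] = self.mismatch
        return s


DNA_SCORING = ScoringScheme(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-2.0)
PROTEIN_SCORING = ScoringScheme(
    match=1.0, mismatch=-4.0, gap_open=-8.0, gap_extend=-8.0, matrix="BLOSUM62"
)


@dataclass
class Alignment:
    """A pairwise alignment (gap character '-') with input coordinates."""

    aligned_a: str
    aligned_b: str
    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int

    def identity(self) -> float:
        cols = [
            (x, y) for x, y in zip(self.aligned_a, self.aligned_b) if GAP not in (x, y)
        ]
        if not cols:
            return 0.0
        return sum(x == y for x, y in cols) / len(cols)


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows; de-gapping any row recovers its input."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise ValueError("aligned rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count(GAP) / len(col)


def _alphabet_for(a: str, b: str) -> str:
    letters = set(a) | set(b)
    if letters <= set("ACGTN"):
        return "ACGTN"
    if letters <= set(AA_ALPHABET + "X*"):
        return AA_ALPHABET + "X*"
    raise ValueError("sequences do not share a supported alphabet")


def _encode(seq: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    idx = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (idx < 0).any():
        bad = sorted({c for c in seq if c not in alphabet})
        raise ValueError(f"unsupported characters {bad}")
    return idx


def _dp_matrix(
    sa: np.ndarray, sb: np.ndarray, S: np.ndarray, g: float, local: bool
) -> np.ndarray:
    """Score matrix (len(a)+1, len(b)+1) of NW (local=False) or SW DP."""
    n, m = len(sa), len(sb)
    M = np.empty((n + 1, m + 1))
    jg = g * np.arange(m + 1)
    M[0] = 0.0 if local else jg
    for i in range(1, n + 1):
        sub = S[sa[i - 1]][sb]  # length m
        T = np.empty(m + 1)
        T[0] = 0.0 if local else g * i
        T[1:] = np.maximum(M[i - 1, :-1] + sub, M[i - 1, 1:] + g)
        # resolve horizontal chain: M[j] = max(T[j], M[j-1] + g)
        row = np.maximum.accumulate(T - jg) + jg
        if local:
            row = np.maximum(row, 0.0)
            # clamping can only raise values; re-run prefix fix once
            row = np.maximum.accumulate(row - jg) + jg
        M[i] = row
    return M


def _traceback(
    a: str,
    b: str,
    sa: np.ndarray,
    sb: np.ndarray,
    S: np.ndarray,
    g: float,
    M: np.ndarray,
    i: int,
    j: int,
    local: bool,
) -> Alignment:
    out_a: list[str] = []
    out_b: list[str] = []
    end_i, end_j = i, j
    score = M[i, j]
    eps = 1e-9
    while i > 0 or j > 0:
        if local and M[i, j] <= eps:
            break
        if i > 0 and j > 0 and abs(M[i, j] - (M[i - 1, j - 1] + S[sa[i - 1], sb[j - 1]])) < eps:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and abs(M[i, j] - (M[i - 1, j] + g)) < eps:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return Alignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        a_start=i,
        a_end=end_i,
        b_start=j,
        b_end=end_j,
    )


def global_align(a: str, b: str, scoring: ScoringScheme | None = None) -> Alignment:
    """Optimal global (Needleman-Wunsch) alignment of two sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alphabet = _alphabet_for(a, b)
    if scoring is None:
        scoring = DNA_SCORING if alphabet == "ACGTN" else PROTEIN_SCORING
    sa, sb = _encode(a, alphabet), _encode(b, alphabet)
    S = scoring.pair_scores(alphabet)
    g = scoring.gap_open
    M = _dp_matrix(sa, sb, S, g, local=False)
    return _traceback(a, b, sa, sb, S, g, M, len(a), len(b), local=False)


def _best_local(a: str, b: str, scoring: ScoringScheme) -> Alignment | None:
    alphabet = _alphabet_for(a, b)
    sa, sb = _encode(a, alphabet), _encode(b, alphabet)
    S = scoring.pair_scores(alphabet)
    g = scoring.gap_open
    M = _dp_matrix(sa, sb, S, g, local=True)
    flat = int(np.argmax(M))
    i, j = divmod(flat, M.shape[1])
    if M[i, j] <= 0:
        return None
    return _traceback(a, b, sa, sb, S, g, M, i, j, local=True)


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    top_n: int = 3,
) -> list[Alignment]:
    """Best local (Smith-Waterman) hits, non-overlapping on the target.

    After each hit the covered target interval is excluded and the search
    repeats on the remaining segments; at most ``top_n`` positive-score hits
    are returned, sorted by score descending.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not query or not target:
        return []
    if scoring is None:
        scoring = DNA_SCORING if _alphabet_for(query, target) == "ACGTN" else PROTEIN_SCORING
    segments: list[tuple[int, int]] = [(0, len(target))]
    hits: list[Alignment] = []
    while len(hits) < top_n and segments:
        best: Alignment | None = None
        best_seg = None
        for s, e in segments:
            aln = _best_local(query, target[s:e], scoring)
            if aln is not None and (best is None or aln.score > best.score):
                aln.b_start += s
                aln.b_end += s
                best, best_seg = aln, (s, e)
        if best is None:
            break
        hits.append(best)
        s, e = best_seg
        segments.remove(best_seg)
        if best.b_start - s > 0:
            segments.append((s, best.b_start))
        if e - best.b_end > 0:
            segments.append((best.b_end, e))
    hits.sort(key=lambda h: (-h.score, h.b_start))
    return hits


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """1 - fractional shared k-mers; crude but adequate for a guide tree."""
    sets = [_kmer_set(s, k) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            sim = len(sets[i] & sets[j]) / denom if denom else 0.0
            d[i, j] = d[j, i] = 1.0 - sim
    return d


@dataclass
class _Profile:
    rows: list[str]
    indices: list[int]
    freqs: np.ndarray = field(init=False)  # n_cols x (len(alphabet)+1), gap last

    alphabet: str = AA_ALPHABET + "X*"

    def __post_init__(self) -> None:
        symbols = self.alphabet + GAP
        lut = {c: i for i, c in enumerate(symbols)}
        n_cols = len(self.rows[0])
        f = np.zeros((n_cols, len(symbols)))
        for row in self.rows:
            for j, c in enumerate(row):
                f[j, lut[c]] += 1
        self.freqs = f / len(self.rows)


def _merge_profiles(pa: _Profile, pb: _Profile, scoring: ScoringScheme) -> _Profile:
    symbols = pa.alphabet + GAP
    SM = np.zeros((len(symbols), len(symbols)))
    core = scoring.pair_scores(pa.alphabet)
    SM[:-1, :-1] = core
    SM[-1, :-1] = scoring.gap_open
    SM[:-1, -1] = scoring.gap_open
    SM[-1, -1] = 0.0
    S = pa.freqs @ SM @ pb.freqs.T  # column-by-column expected score
    g = scoring.gap_open
    n, m = S.shape
    M = np.empty((n + 1, m + 1))
    jg = g * np.arange(m + 1)
    M[0] = jg
    for i in range(1, n + 1):
        T = np.empty(m + 1)
        T[0] = g * i
        T[1:] = np.maximum(M[i - 1, :-1] + S[i - 1], M[i - 1, 1:] + g)
        M[i] = np.maximum.accumulate(T - jg) + jg
    # traceback over column indices
    ops: list[str] = []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(M[i, j] - (M[i - 1, j - 1] + S[i - 1, j - 1])) < eps:
            ops.append("D")
            i, j = i - 1, j - 1
        elif i > 0 and abs(M[i, j] - (M[i - 1, j] + g)) < eps:
            ops.append("U")
            i -= 1
        else:
            ops.append("L")
            j -= 1
    ops.reverse()
    rows_a = [[] for _ in pa.rows]
    rows_b = [[] for _ in pb.rows]
    ia = ib = 0
    for op in ops:
        if op in "DU":
            for r, out in zip(pa.rows, rows_a):
                out.append(r[ia])
            ia += 1
        else:
            for out in rows_a:
                out.append(GAP)
        if op in "DL":
            for r, out in zip(pb.rows, rows_b):
                out.append(r[ib])
            ib += 1
        else:
            for out in rows_b:
                out.append(GAP)
    return _Profile(
        rows=["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
        indices=pa.indices + pb.indices,
        alphabet=pa.alphabet,
    )


def progressive_align(
    seqs: Sequence[SequenceRecord], scoring: ScoringScheme | None = None
) -> MultipleAlignment:
    """Progressive profile-profile alignment over an NJ guide tree.

    The guide tree is built by neighbor joining on k-mer distances; profiles
    are merged in postorder. Output row order equals input order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs at least 2 sequences")
    if scoring is None:
        scoring = PROTEIN_SCORING
    alphabet = AA_ALPHABET + "X*"
    for r in seqs:
        bad = set(r.seq) - set(alphabet)
        if bad:
            raise ValueError(f"unsupported residues {sorted(bad)} in {r.id}")
    leaves = {
        i: _Profile(rows=[r.seq], indices=[i], alphabet=alphabet)
        for i, r in enumerate(seqs)
    }
    if len(seqs) == 2:
        merged = _merge_profiles(leaves[0], leaves[1], scoring)
    else:
        from .phylo_classify import DistanceMatrix, nj_tree

        d = kmer_distance_matrix([r.seq for r in seqs])
        ids = [str(i) for i in range(len(seqs))]
        tree = nj_tree(DistanceMatrix(ids, d))

        def build(node) -> _Profile:
            if not node.children:
                return leaves[int(node.label)]
            prof = build(node.children[0])
            for child in node.children[1:]:
                prof = _merge_profiles(prof, build(child), scoring)
            return prof

        merged = build(tree.root)
    order = np.argsort(merged.indices)
    rows = [merged.rows[i] for i in order]
    idx = [merged.indices[i] for i in order]
    return MultipleAlignment(
        [SequenceRecord(seqs[i].id, row, seqs[i].alphabet) for i, row in zip(idx, rows)]
    )


def crop_to_conserved(
    msa: MultipleAlignment, max_gap_fraction: float = 0.5
) -> MultipleAlignment:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``."""
    if not 0 <= max_gap_fraction <= 1:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = [
        j for j in range(msa.n_columns) if msa.gap_fraction(j) <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("all columns removed by cropping")
    return MultipleAlignment(
        [
            SequenceRecord(r.id, "".join(r.seq[j] for j in keep), r.alphabet)
            for r in msa.records
        ]
    )


def pairwise_distance_matrix(msa: MultipleAlignment):
    """p-distance matrix over columns where neither row is gapped."""
    from .phylo_classify import DistanceMatrix

    n = len(msa)
    if n < 3:
        raise ValueError("need at least 3 rows for a distance matrix")
    rows = [r.seq for r in msa.records]
    arr = np.array([list(r) for r in rows])
    gap = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"rows {msa.records[i].id!r} and {msa.records[j].id!r} share no "
                    "ungapped columns"
                )
            diff = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix([r.id for r in msa.records], d)
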