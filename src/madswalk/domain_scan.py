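"""Ungapped log-odds profile scanning for the MADS (M) and K domains.

A ``ProfileModel`` is a per-column log2-odds matrix over the 20 amino acids
built from a seed alignment. It deliberately simplifies a full profile HMM:
the two domains are short and well conserved, an ungapped profile is exactly
checkable against a brute-force window scorer, and the resulting presence/
absence calls are all downstream stages need. Proteins with an M hit and a
K hit are type II (MIKC); M without K is type I; no M hit excludes the
protein from the family (pseudogene candidate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .align import GAP, MultipleAlignment
from .records import AA_ALPHABET, SequenceRecord, revcomp, translate

UNIFORM_BACKGROUND = {a: 0.05 for a in AA_ALPHABET}


@dataclass
class ProfileModel:
    """Per-position log-odds scores (bits) for one domain."""

    label: str  # "M" or "K"
    log_odds: np.ndarray  # W x 20, columns in AA_ALPHABET order
    background: np.ndarray  # length 20
    bit_threshold: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape[0] < 5:
            raise ValueError("profile width must be >= 5")
        if self.log_odds.shape[1] != 20:
            raise ValueError("profile must have 20 residue columns")

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[0])

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.log_odds.argmax(axis=1))

    def score_window(self, window: str) -> float:
        """Bit score of one width-W window; unknown residues contribute 0."""
        if len(window) != self.width:
            raise ValueError("window length must equal profile width")
        total = 0.0
        for j, aa in enumerate(window):
            k = AA_ALPHABET.find(aa)
            if k >= 0:
                total += self.log_odds[j, k]
        return total

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#label\t{self.label}\n")
            fh.write(f"#bit_threshold\t{self.bit_threshold:.6f}\n")
            fh.write("#background\t" + "\t".join(f"{x:.6f}" for x in self.background) + "\n")
            fh.write("pos\t" + "\t".join(AA_ALPHABET) + "\n")
            for i, row in enumerate(self.log_odds):
                fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ProfileModel":
        label, threshold, background = "?", 0.0, None
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#label":
                    label = parts[1]
                elif parts[0] == "#bit_threshold":
                    threshold = float(parts[1])
                elif parts[0] == "#background":
                    background = np.array([float(x) for x in parts[1:]])
                elif parts[0] == "pos":
                    continue
                else:
                    rows.append([float(x) for x in parts[1:]])
        return cls(label, np.array(rows), background, threshold)


@dataclass(frozen=True)
class DomainHit:
    """One profile match. ``frame`` 0 means protein input (residue
    coordinates); otherwise +-1..3 with DNA coordinates on the scaffold."""

    sequence_id: str
    start: int
    end: int
    score: float
    domain: str
    frame: int = 0


def build_profile(
    seed_msa: MultipleAlignment,
    label: str = "M",
    pseudocount: float = 1.0,
    background: dict[str, float] | None = None,
    threshold_fraction: float = 0.6,
) -> ProfileModel:
    """Build a log-odds profile from a seed alignment.

    Columns with >= 50% gaps are dropped. Per column:
    ``log2(((count + pc) / (N + 20 pc)) / background)`` with N the number of
    residues observed in the column. The bit threshold defaults to
    ``threshold_fraction`` of the minimum seed-row self-score.
    """
    if len(seed_msa) == 0:
        raise ValueError("empty seed alignment")
    bg = background or UNIFORM_BACKGROUND
    bg_arr = np.array([bg[a] for a in AA_ALPHABET])
    keep = [j for j in range(seed_msa.n_columns) if seed_msa.gap_fraction(j) < 0.5]
    if len(keep) < 5:
        raise ValueError("fewer than 5 usable columns in seed alignment")
    log_odds = np.zeros((len(keep), 20))
    for w, j in enumerate(keep):
        col = seed_msa.column(j)
        residues = [c for c in col if c != GAP]
        n = len(residues)
        for k, aa in enumerate(AA_ALPHABET):
            count = residues.count(aa)
            p = (count + pseudocount) / (n + 20 * pseudocount)
            log_odds[w, k] = math.log2(p / bg_arr[k])
    profile = ProfileModel(label, log_odds, bg_arr, bit_threshold=0.0)
    self_scores = []
    for r in seed_msa.records:
        s = 0.0
        for w, j in enumerate(keep):
            aa = r.seq[j]
            k = AA_ALPHABET.find(aa)
            if k >= 0:
                s += log_odds[w, k]
        self_scores.append(s)
    profile.bit_threshold = threshold_fraction * min(self_scores)
    return profile


def _window_scores(profile: ProfileModel, seq: str) -> np.ndarray:
    """Scores of all windows (vectorised); windows with a stop are -inf."""
    W = profile.width
    n = len(seq) - W + 1
    if n <= 0:
        return np.empty(0)
    lut = np.full(128, 20, dtype=np.int64)  # 20 = neutral (score 0)
    for i, c in enumerate(AA_ALPHABET):
        lut[ord(c)] = i
    idx = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    lo = np.hstack([profile.log_odds, np.zeros((W, 1))])  # neutral column
    scores = np.zeros(n)
    for j in range(W):
        scores += lo[j, idx[j : j + n]]
    stops = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("*")
    if stops.any():
        bad = np.convolve(stops.astype(int), np.ones(W, dtype=int), mode="valid") > 0
        scores[bad] = -np.inf
    return scores


def scan_protein(profile: ProfileModel, protein: SequenceRecord) -> list[DomainHit]:
    """All windows scoring >= threshold, pruned to non-overlapping best-first."""
    scores = _window_scores(profile, protein.seq)
    candidates = [
        (float(s), i)
        for i, s in enumerate(scores)
        if s >= profile.bit_threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    W = profile.width
    taken: list[tuple[int, int]] = []
    hits: list[DomainHit] = []
    for score, start in candidates:
        if any(start < e and start + W > s for s, e in taken):
            continue
        taken.append((start, start + W))
        hits.append(DomainHit(protein.id, start, start + W, score, profile.label))
    hits.sort(key=lambda h: h.start)
    return hits


def scan_scaffold_sixframe(
    profile: ProfileModel, scaffold: SequenceRecord
) -> list[DomainHit]:
    """Scan all six frame translations; stops break windows. Hits carry the
    frame (+-1..3) and DNA coordinates of the window on the input scaffold."""
    W = profile.width
    L = len(scaffold.seq)
    if L < 3 * W:
        return []
    hits: list[DomainHit] = []
    for strand, seq in (("+", scaffold.seq), ("-", revcomp(scaffold.seq))):
        for offset in range(3):
            aa = translate(seq[offset:], to_stop=False)
            prot = SequenceRecord(scaffold.id, aa, "protein")
            for h in scan_protein(profile, prot):
                dna_start = offset + 3 * h.start
                dna_end = offset + 3 * h.end
                if strand == "-":
                    dna_start, dna_end = L - dna_end, L - dna_start
                    frame = -(offset + 1)
                else:
                    frame = offset + 1
                hits.append(
                    DomainHit(scaffold.id, dna_start, dna_end, h.score, profile.label, frame)
                )
    hits.sort(key=lambda h: (h.start, h.frame))
    return hits


@dataclass(frozen=True)
class GeneClassification:
    gene_type: str  # "type_II" | "type_I" | "non_MADS"
    has_M: bool
    has_K: bool


def classify_gene(
    m_hits: list[DomainHit], k_hits: list[DomainHit]
) -> GeneClassification:
    """M + K -> type II (MIKC); M only -> type I; no M -> not a family member."""
    has_m, has_k = bool(m_hits), bool(k_hits)
    if has_m and has_k:
        kind = "type_II"
    elif has_m:
        kind = "type_I"
    else:
        kind = "non_MADS"
    return GeneClassification(kind, has_m, has_k)


def deduplicate_proteins(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Rule-based curation: drop exact duplicates and proteins that are
    substrings of a longer family member (redundant fragments)."""
    order = {id(r): i for i, r in enumerate(records)}
    ordered = sorted(records, key=lambda r: (-len(r.seq), order[id(r)]))
    kept: list[SequenceRecord] = []
    for r in ordered:
        if any(r.seq in k.seq for k in kept):
            continue
        kept.append(r)
    kept.sort(key=lambda r: order[id(r)])
    return kept
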