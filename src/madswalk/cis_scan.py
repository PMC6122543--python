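"""IUPAC degenerate-motif scanning of promoter and intron sequences.

Promoters are the 1.5 kb immediately upstream of the translational start
codon on the coding strand. Motifs come from a TSV dictionary
(name, IUPAC pattern, category); a curated default dictionary covering nine
functional categories is bundled with the package. Matching is exact per
IUPAC position (no scoring); overlapping matches all count; a palindromic
pattern (equal to its own IUPAC reverse complement) is reported once per
position with strand '±'.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .records import GeneModel, SequenceRecord, revcomp

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

CATEGORIES = (
    "core promoter",
    "protein binding",
    "hormone response",
    "tissue-specific",
    "light response",
    "abiotic/biotic stress",
    "circadian",
    "cell cycle",
    "other",
)


def iupac_revcomp(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name}: empty pattern")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC letters {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(f"motif {self.name}: unknown category {self.category!r}")

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == iupac_revcomp(self.pattern)


def load_motifs(path: str | None = None) -> dict[str, MotifDef]:
    """Load a motif dictionary TSV (name, pattern, category); bundled default."""
    if path is None:
        source = resources.files("madswalk.data").joinpath("cis_elements.tsv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    motifs: dict[str, MotifDef] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, pattern, category = line.rstrip("\n").split("\t")
        if name in motifs:
            raise ValueError(f"duplicate motif name {name!r}")
        motifs[name] = MotifDef(name, pattern.upper(), category)
    return motifs


def _match_positions(seq: str, pattern: str) -> np.ndarray:
    """Start positions (ascending) where ``pattern`` matches ``seq``."""
    L, n = len(pattern), len(seq)
    if n < L:
        return np.empty(0, dtype=int)
    data = np.frombuffer(seq.encode(), dtype=np.uint8)
    ok = np.ones(n - L + 1, dtype=bool)
    for j, letter in enumerate(pattern):
        allowed = np.zeros(128, dtype=bool)
        for c in IUPAC[letter]:
            allowed[ord(c)] = True
        ok &= allowed[data[j : j + n - L + 1]]
    return np.flatnonzero(ok)


def scan_motifs(
    seq: SequenceRecord,
    motifs: dict[str, MotifDef],
    both_strands: bool = True,
    region: str = "promoter",
) -> pd.DataFrame:
    """All motif match positions on the requested strands.

    Returns a table with columns (sequence_id, region, motif, strand,
    start, match); ``start`` is 0-based on the input sequence and ``match``
    is the forward-strand substring at that window.
    """
    rows: list[tuple] = []
    s = seq.seq.upper()
    for m in motifs.values():
        L = len(m.pattern)
        fwd = set(_match_positions(s, m.pattern).tolist())
        if both_strands and not m.is_palindromic:
            rev = set(_match_positions(s, iupac_revcomp(m.pattern)).tolist())
        else:
            rev = set()
        for pos in sorted(fwd | rev):
            if m.is_palindromic and both_strands:
                strand = "±"
            elif pos in fwd:
                strand = "+"
            else:
                strand = "-"
            rows.append((seq.id, region, m.name, strand, pos, s[pos : pos + L]))
    return pd.DataFrame(
        rows, columns=["sequence_id", "region", "motif", "strand", "start", "match"]
    ).sort_values(["motif", "start"], kind="stable").reset_index(drop=True)


def extract_promoter(
    gene: GeneModel, scaffold: SequenceRecord, length: int = 1500
) -> tuple[SequenceRecord, bool]:
    """The ``length`` nt immediately 5' of the translational start codon on
    the coding strand; truncated silently at scaffold edges.

    Returns (promoter record, truncated flag).
    """
    if gene.scaffold_id != scaffold.id:
        raise ValueError(f"gene {gene.gene_id} is not on scaffold {scaffold.id}")
    if not gene.exons:
        raise ValueError("gene has no exon/CDS intervals")
    if gene.strand == "+":
        start = gene.exons[0][0]
        lo = max(0, start - length)
        seq = scaffold.seq[lo:start]
    else:
        start = gene.exons[-1][1]
        hi = min(len(scaffold.seq), start + length)
        seq = revcomp(scaffold.seq[start:hi])
    return SequenceRecord(f"{gene.gene_id}_promoter", seq, "dna"), len(seq) < length


def extract_introns(gene: GeneModel, scaffold: SequenceRecord) -> list[SequenceRecord]:
    """Intron sequences (exon complement within the gene span), coding strand."""
    gaps = [
        (e0[1], e1[0]) for e0, e1 in zip(gene.exons, gene.exons[1:]) if e0[1] < e1[0]
    ]
    seqs = [scaffold.seq[s:e] for s, e in gaps]
    if gene.strand == "-":
        seqs = [revcomp(s) for s in reversed(seqs)]
    return [
        SequenceRecord(f"{gene.gene_id}_intron{i + 1}", s, "dna")
        for i, s in enumerate(seqs)
    ]


def summarize_categories(
    tables: pd.DataFrame | list[pd.DataFrame], motifs: dict[str, MotifDef]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate hit tables into category frequencies and per-gene counts.

    Returns (category table with counts and proportions over non-empty
    categories, per-sequence x motif count table).
    """
    if isinstance(tables, list):
        table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=["sequence_id", "region", "motif", "strand", "start", "match"]
        )
    else:
        table = tables
    unknown = set(table["motif"]) - set(motifs)
    if unknown:
        raise ValueError(f"hits reference motifs missing from the dictionary: {sorted(unknown)}")
    cat_of = {name: m.category for name, m in motifs.items()}
    counts = table.groupby(table["motif"].map(cat_of)).size() if len(table) else pd.Series(dtype=int)
    total = int(counts.sum())
    cat_table = pd.DataFrame(
        {
            "category": counts.index,
            "count": counts.values,
            "proportion": (counts / total).values if total else [],
        }
    ).sort_values("count", ascending=False).reset_index(drop=True)
    per_gene = (
        table.groupby(["sequence_id", "motif"]).size().unstack(fill_value=0)
        if len(table)
        else pd.DataFrame()
    )
    return cat_table, per_gene
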