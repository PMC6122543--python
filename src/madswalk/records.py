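"""Core sequence and gene-model containers shared by every pipeline stage.

All coordinates are 0-based half-open on the forward strand of the named
scaffold; GFF3 emission converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: amino acid -> list of codons (standard genetic code), for reverse translation
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR_AA:
    CODONS_FOR_AA[_aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, to_stop: bool = True) -> str:
    """Standard-genetic-code translation of an in-frame DNA string."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(to_stop=to_stop))


@dataclass(frozen=True)
class SequenceRecord:
    """An identified residue string with a declared alphabet ('dna'|'protein')."""

    id: str
    seq: str
    alphabet: str = "dna"

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse complement is only defined for DNA")
        return SequenceRecord(self.id, revcomp(self.seq), "dna")


@dataclass
class GeneModel:
    """A (possibly incomplete) annotated gene: exon intervals plus derived CDS.

    ``exons`` are (start, end) scaffold intervals in ascending order; for
    minus-strand genes transcription runs through them in descending order
    and each exon substring is reverse complemented.
    """

    gene_id: str
    scaffold_id: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    has_M: bool = True
    has_K: bool = True
    reason: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon interval ({s}, {e})")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced(self, scaffold_seq: str) -> str:
        """Spliced transcript (coding orientation) from the scaffold sequence."""
        parts = [scaffold_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def transcript_to_genomic(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map a transcript interval back onto scaffold exon pieces.

        Returns ascending genomic intervals covering transcript positions
        [t_start, t_end) in coding orientation.
        """
        if not 0 <= t_start <= t_end <= self.cds_len:
            raise ValueError("transcript interval out of range")
        order = self.exons if self.strand == "+" else self.exons[::-1]
        pieces: list[tuple[int, int]] = []
        offset = 0
        for s, e in order:
            length = e - s
            lo, hi = max(t_start, offset), min(t_end, offset + length)
            if lo < hi:
                if self.strand == "+":
                    pieces.append((s + (lo - offset), s + (hi - offset)))
                else:
                    pieces.append((e - (hi - offset), e - (lo - offset)))
            offset += length
        return sorted(pieces)


@dataclass
class WalkHistory:
    """One extension round of the read walk."""

    end: str  # '5' or '3'
    bases_added: int
    support: int


@dataclass
class WalkResult:
    """Outcome of iterative read-walk extension of a seed sequence."""

    seed_id: str
    seed: str
    final: str
    seed_offset: int  # position of the (sanitized) seed within ``final``
    sanitized_seed: str
    history: list[WalkHistory] = field(default_factory=list)
    reads_consumed: set[str] = field(default_factory=set)
    termination: dict[str, str] = field(default_factory=dict)  # end -> reason

    @property
    def bases_added_5(self) -> int:
        return sum(h.bases_added for h in self.history if h.end == "5")

    @property
    def bases_added_3(self) -> int:
        return sum(h.bases_added for h in self.history if h.end == "3")
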