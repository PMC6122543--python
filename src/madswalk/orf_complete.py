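"""ORF finding on walked transcripts and before/after gene-model reporting.

Walked sequences are spliced transcripts, so domain-anchored longest-ORF
selection replaces ab initio gene prediction: the corrected protein is the
longest ATG-to-stop ORF that overlaps the seed region and contains an
M-domain hit.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

from .domain_scan import ProfileModel, scan_protein
from .records import GeneModel, SequenceRecord, WalkResult, revcomp, translate

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCandidate:
    """An ATG-initiated, stop-terminated reading frame.

    ``start``/``end`` are forward-strand coordinates on the input sequence
    covering ATG..stop inclusive; ``frame`` follows the six-frame convention
    (+-1..3). ``protein`` excludes the stop."""

    start: int
    end: int
    frame: int
    protein: str


def find_orfs(transcript: str, min_len_aa: int = 1) -> list[OrfCandidate]:
    """All ATG-initiated, stop-terminated ORFs on both strands, longest first."""
    n = len(transcript)
    out: list[OrfCandidate] = []
    for strand, seq in (("+", transcript), ("-", revcomp(transcript))):
        for offset in range(3):
            # in-frame stop positions, in order
            stops = [
                i for i in range(offset, n - 2, 3) if seq[i : i + 3] in STOPS
            ]
            for i in range(offset, n - 2, 3):
                if seq[i : i + 3] != "ATG":
                    continue
                si = bisect_left(stops, i + 3)
                if si == len(stops):
                    continue
                stop = stops[si]
                aa_len = (stop - i) // 3
                if aa_len < min_len_aa:
                    continue
                protein = translate(seq[i:stop], to_stop=False)
                s, e = i, stop + 3
                if strand == "-":
                    s, e = n - (stop + 3), n - i
                    frame = -(offset + 1)
                else:
                    frame = offset + 1
                out.append(OrfCandidate(s, e, frame, protein))
    out.sort(key=lambda o: (-len(o.protein), o.start, o.frame))
    return out


@dataclass
class OrfReport:
    """Before/after record of one gene-model completion."""

    gene_id: str
    reason: str
    original_len_aa: int
    corrected_len_aa: int
    frame: int
    has_M_before: bool
    has_K_before: bool
    has_M_after: bool
    has_K_after: bool
    status: str = "ok"  # "ok" | "no_orf"
    corrected_protein: str | None = None
    corrected_cds: str | None = None


def complete_model(
    seed_model: GeneModel,
    walk_result: WalkResult,
    m_profile: ProfileModel,
    k_profile: ProfileModel,
    min_len_aa: int = 30,
) -> OrfReport:
    """Select the corrected ORF from a walked transcript and report flags.

    The winning ORF must overlap the seed region within the walked sequence
    and contain an M-domain hit; among those the longest protein wins. If no
    ORF qualifies the report carries status "no_orf" and the original model
    is retained.
    """
    original = seed_model.protein or ""
    before_m = bool(scan_protein(m_profile, SequenceRecord(seed_model.gene_id, original, "protein")))
    before_k = bool(scan_protein(k_profile, SequenceRecord(seed_model.gene_id, original, "protein")))
    seed_lo = walk_result.seed_offset
    seed_hi = seed_lo + len(walk_result.sanitized_seed)
    best: OrfCandidate | None = None
    for orf in find_orfs(walk_result.final, min_len_aa=min_len_aa):
        if orf.end <= seed_lo or orf.start >= seed_hi:
            continue
        prot = SequenceRecord(seed_model.gene_id, orf.protein, "protein")
        if not scan_protein(m_profile, prot):
            continue
        best = orf
        break  # list is sorted longest-first
    if best is None:
        return OrfReport(
            gene_id=seed_model.gene_id,
            reason=seed_model.reason or "",
            original_len_aa=len(original),
            corrected_len_aa=len(original),
            frame=0,
            has_M_before=before_m,
            has_K_before=before_k,
            has_M_after=before_m,
            has_K_after=before_k,
            status="no_orf",
        )
    prot = SequenceRecord(seed_model.gene_id, best.protein, "protein")
    cds = walk_result.final[best.start : best.end]
    if best.frame < 0:
        cds = revcomp(cds)
    return OrfReport(
        gene_id=seed_model.gene_id,
        reason=seed_model.reason or "",
        original_len_aa=len(original),
        corrected_len_aa=len(best.protein),
        frame=best.frame,
        has_M_before=before_m,
        has_K_before=before_k,
        has_M_after=bool(scan_protein(m_profile, prot)),
        has_K_after=bool(scan_protein(k_profile, prot)),
        corrected_protein=best.protein,
        corrected_cds=cds,
    )
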