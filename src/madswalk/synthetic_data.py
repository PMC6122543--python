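"""Synthetic gene families with planted ground truth.

Generates every input the pipeline consumes: scaffolds carrying multi-exon
genes with M-I-K-C protein architecture (type I members lack the K domain),
spliced transcripts, error-bearing short reads tiled over the transcripts,
promoters with planted cis-element instances at recorded positions, and
qPCR Ct tables generated from known fold changes. Annotation defects
(truncations and corrupted ORF regions) are applied on top of the truth so
that the completion stages can be scored against it.

Clade structure is real: each clade derives from one ancestor protein whose
M (and K) domain instance comes from a distinct row of the bundled seed
alignments; members mutate the ancestor lightly, so profiles built from the
same seeds detect every planted domain and trees recover the clades.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .align import MultipleAlignment
from .cis_scan import IUPAC, MotifDef, iupac_revcomp, load_motifs
from .records import (
    AA_ALPHABET,
    CODONS_FOR_AA,
    STOP_CODONS,
    GeneModel,
    SequenceRecord,
    revcomp,
    translate,
)

TYPE_II_CLADES = (
    "AG-like",
    "SQUA-like",
    "SVP-like",
    "TM3-like",
    "PI-like",
    "SEP-like",
    "AGL12-like",
    "GGM13-like",
)
TYPE_I_CLADE = "M-alpha"

M_WIDTH = 57
K_WIDTH = 50
M_START = 1  # after the initiator Met
M_END = M_START + M_WIDTH  # 58

DEFAULT_MOTIF_PLAN = {"CArG": 2, "G-box": 1, "ABRE": 1, "Skn-1": 1, "TATA-box": 1}

#: Bundled 17-gene truncation panel emulating typical annotation defects:
#: (mode, true protein length in aa, mode parameter). For lack_K the
#: parameter is the K-domain start (aa); for corrupt_5prime the number of
#: 5' transcript bases replaced by unrelated sequence.
TRUNCATION_PANEL: list[tuple[str, int, int | None]] = [
    ("lack_K", 257, 124),
    ("lack_K", 183, 132),
    ("lack_K", 244, 79),
    ("lack_K", 258, 152),
    ("lack_K", 215, 105),
    ("lack_K", 205, 86),
    ("corrupt_5prime", 216, 319),
    ("lack_M", 192, None),
    ("lack_M", 229, None),
    ("lack_M", 229, None),
    ("corrupt_5prime", 251, 150),
    ("corrupt_5prime", 228, 184),
    ("corrupt_5prime", 221, 100),
    ("lack_M", 152, None),
    ("lack_M", 230, None),
    ("lack_M", 259, None),
    ("lack_M", 224, None),
]


def load_seed_alignment(domain: str) -> MultipleAlignment:
    """Bundled synthetic seed alignment for the M or K domain."""
    fname = {"M": "m_domain_seed.synthetic.afa", "K": "k_domain_seed.synthetic.afa"}[
        domain
    ]
    text = resources.files("madswalk.data").joinpath(fname).read_text()
    records = []
    for chunk in text.split(">")[1:]:
        lines = chunk.strip().splitlines()
        records.append(SequenceRecord(lines[0].split()[0], "".join(lines[1:]), "protein"))
    return MultipleAlignment(records)


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            alt = AA_ALPHABET.replace(c, "")
            out.append(alt[rng.integers(len(alt))])
        else:
            out.append(c)
    return "".join(out)


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=n))


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = CODONS_FOR_AA[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _resize(seq: str, n: int, rng: np.random.Generator) -> str:
    if n <= len(seq):
        return seq[:n]
    return seq + _random_protein(n - len(seq), rng)


@dataclass
class TruncationRecord:
    """One planted annotation defect; lengths are filled in when applied."""

    gene_id: str
    mode: str  # lack_M | lack_K | corrupt_5prime | corrupt_3prime
    param: int | None = None  # bp replaced, for corrupt_* modes
    original_len_aa: int | None = None
    true_len_aa: int | None = None

    def __post_init__(self) -> None:
        valid = {"lack_M", "lack_K", "corrupt_5prime", "corrupt_3prime"}
        if self.mode not in valid:
            raise ValueError(f"unknown truncation mode {self.mode!r}")
        if self.mode.startswith("corrupt") and not self.param:
            raise ValueError(f"{self.mode} requires a bp count parameter")


@dataclass
class FamilyTruth:
    """Complete planted ground truth for one synthetic gene family."""

    scaffolds: list[SequenceRecord]
    genes: list[GeneModel]
    transcripts: list[SequenceRecord]
    proteins: list[SequenceRecord]
    clade_labels: dict[str, str]
    rng_seed: int
    domain_spans: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    reference_proteins: list[SequenceRecord] = field(default_factory=list)
    reference_labels: dict[str, str] = field(default_factory=dict)
    promoter_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoter_background: pd.DataFrame = field(default_factory=pd.DataFrame)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene id {gene_id!r}")

    def scaffold(self, scaffold_id: str) -> SequenceRecord:
        for s in self.scaffolds:
            if s.id == scaffold_id:
                return s
        raise KeyError(f"unknown scaffold id {scaffold_id!r}")


def _iupac_match_at(seq: str, pattern: str, pos: int) -> bool:
    if pos + len(pattern) > len(seq):
        return False
    return all(seq[pos + j] in IUPAC[c] for j, c in enumerate(pattern))


def _record_background(
    seq_id: str, seq: str, motifs: dict[str, MotifDef], planted: set[tuple[str, int]]
) -> list[tuple[str, str, int]]:
    """All scanner-visible matches that were not planted (chance matches)."""
    out = []
    for m in motifs.values():
        rc = iupac_revcomp(m.pattern)
        for pos in range(len(seq) - len(m.pattern) + 1):
            hit = _iupac_match_at(seq, m.pattern, pos) or (
                not m.is_palindromic and _iupac_match_at(seq, rc, pos)
            )
            if hit and (m.name, pos) not in planted:
                out.append((seq_id, m.name, pos))
    return out


def _plant_into(
    background: list[str],
    plan: dict[str, int],
    motifs: dict[str, MotifDef],
    rng: np.random.Generator,
) -> list[tuple[str, int]]:
    """Write concrete motif instances into a mutable promoter sequence.

    Placement is non-overlapping, positions drawn at random; raises if the
    plan cannot be packed.
    """
    length = len(background)
    occupied: list[tuple[int, int]] = []
    planted: list[tuple[str, int]] = []
    for name, count in sorted(plan.items()):
        if name not in motifs:
            raise KeyError(f"motif {name!r} not in dictionary")
        pattern = motifs[name].pattern
        for _ in range(count):
            placed = False
            for _attempt in range(200):
                pos = int(rng.integers(0, length - len(pattern) + 1))
                if any(pos < e and pos + len(pattern) > s for s, e in occupied):
                    continue
                instance = "".join(
                    IUPAC[c][rng.integers(len(IUPAC[c]))] for c in pattern
                )
                background[pos : pos + len(pattern)] = list(instance)
                occupied.append((pos, pos + len(pattern)))
                planted.append((name, pos))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"cannot pack {count} x {name} into a {length}-nt promoter"
                )
    return planted


def plant_motifs(
    n_promoters: int,
    promoter_len: int,
    plan: dict[str, int],
    motifs: dict[str, MotifDef] | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], pd.DataFrame, pd.DataFrame]:
    """Promoter sequences with planted motif instances at recorded counts.

    Returns (promoters, truth table of planted counts/positions, table of
    chance background matches recorded at generation time).
    """
    motifs = motifs or load_motifs()
    rng = np.random.default_rng(seed)
    promoters: list[SequenceRecord] = []
    truth_rows: list[tuple[str, str, int]] = []
    background_rows: list[tuple[str, str, int]] = []
    for i in range(n_promoters):
        pid = f"promoter{i + 1:03d}"
        seq_list = list(_random_dna(promoter_len, rng))
        planted = _plant_into(seq_list, plan, motifs, rng)
        seq = "".join(seq_list)
        promoters.append(SequenceRecord(pid, seq, "dna"))
        truth_rows.extend((pid, name, pos) for name, pos in planted)
        background_rows.extend(_record_background(pid, seq, motifs, set(planted)))
    truth = pd.DataFrame(truth_rows, columns=["sequence_id", "motif", "start"])
    background = pd.DataFrame(
        background_rows, columns=["sequence_id", "motif", "start"]
    )
    return promoters, truth, background


@dataclass
class _GeneSpec:
    gene_type: str  # "I" or "II"
    clade: str
    length: int | None = None  # target protein length (aa)
    k_start: int | None = None  # aa position where the K domain starts


def _build_protein(
    spec: _GeneSpec,
    ancestor: dict[str, str],
    member_noise: float,
    rng: np.random.Generator,
) -> tuple[str, dict[str, tuple[int, int]]]:
    """One member protein from a clade ancestor, honouring length targets."""
    m_dom = _mutate_protein(ancestor["M"], member_noise, rng)
    i_reg = _mutate_protein(ancestor["I"], member_noise, rng)
    c_reg = _mutate_protein(ancestor["C"], member_noise, rng)
    if spec.gene_type == "I":
        if spec.length is not None:
            c_reg = _resize(c_reg, max(5, spec.length - M_END), rng)
        protein = "M" + m_dom + i_reg + c_reg
        return protein, {"M": (M_START, M_END)}
    k_dom = _mutate_protein(ancestor["K"], member_noise, rng)
    if spec.k_start is not None:
        if spec.k_start < M_END + 5:
            raise ValueError("k_start leaves no room for the I region")
        i_reg = _resize(i_reg, spec.k_start - M_END, rng)
    if spec.length is not None:
        c_len = spec.length - M_END - len(i_reg) - K_WIDTH
        if c_len < 1:
            raise ValueError(
                f"target length {spec.length} too short for the MIKC layout"
            )
        c_reg = _resize(c_reg, c_len, rng)
    protein = "M" + m_dom + i_reg + k_dom + c_reg
    k0 = M_END + len(i_reg)
    return protein, {"M": (M_START, M_END), "K": (k0, k0 + K_WIDTH)}


def gen_gene_family(
    n_genes: int,
    n_typeI: int = 0,
    intron_len_range: tuple[int, int] = (100, 400),
    seed: int = 0,
    n_introns_range: tuple[int, int] = (4, 7),
    flank: int = 2000,
    ancestor_noise: float = 0.05,
    member_noise: float = 0.03,
    clade_size: int = 4,
    gene_specs: list[dict] | None = None,
    motif_plan: dict[str, int] | None = DEFAULT_MOTIF_PLAN,
    promoter_len: int = 1500,
    references_per_clade: int = 2,
    long_intron_genes: int = 0,
) -> FamilyTruth:
    """Generate a planted MADS-like gene family.

    ``n_typeI`` genes lack the K domain (type I); the rest have the full
    M-I-K-C architecture. ``gene_specs`` optionally fixes per-gene protein
    length and K-domain start (used by the truncation panel).
    ``long_intron_genes`` gives that many leading type II genes one >=10 kb
    intron. Identical seeds yield byte-identical outputs.
    """
    if not 0 <= n_typeI <= n_genes:
        raise ValueError("need 0 <= n_typeI <= n_genes")
    if intron_len_range[0] > intron_len_range[1] or intron_len_range[0] < 1:
        raise ValueError("invalid intron length range")
    if n_introns_range[0] > n_introns_range[1] or n_introns_range[0] < 0:
        raise ValueError("invalid intron count range")
    rng = np.random.default_rng(seed)
    m_seed = load_seed_alignment("M")
    k_seed = load_seed_alignment("K")
    motifs = load_motifs() if motif_plan else {}

    n_typeII = n_genes - n_typeI
    specs: list[_GeneSpec] = []
    n_clades = max(1, math.ceil(n_typeII / clade_size)) if n_typeII else 0
    clade_names = [
        TYPE_II_CLADES[i % len(TYPE_II_CLADES)]
        + ("" if i < len(TYPE_II_CLADES) else f"-{i // len(TYPE_II_CLADES) + 1}")
        for i in range(n_clades)
    ]
    for i in range(n_typeII):
        specs.append(_GeneSpec("II", clade_names[i % n_clades]))
    for _ in range(n_typeI):
        specs.append(_GeneSpec("I", TYPE_I_CLADE))
    if gene_specs:
        if len(gene_specs) != n_genes:
            raise ValueError("gene_specs length must equal n_genes")
        for s, override in zip(specs, gene_specs):
            s.length = override.get("length", s.length)
            s.k_start = override.get("k_start", s.k_start)

    # one ancestor per clade; domain instances from distinct seed rows
    ancestors: dict[str, dict[str, str]] = {}
    for idx, clade in enumerate(clade_names + ([TYPE_I_CLADE] if n_typeI else [])):
        m_row = m_seed.records[idx % len(m_seed)].seq
        k_row = k_seed.records[idx % len(k_seed)].seq
        ancestors[clade] = {
            "M": _mutate_protein(m_row, ancestor_noise, rng),
            "K": _mutate_protein(k_row, ancestor_noise, rng),
            "I": _random_protein(int(rng.integers(25, 41)), rng),
            "C": _random_protein(int(rng.integers(30, 61)), rng),
        }

    scaffolds: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    transcripts: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    clade_labels: dict[str, str] = {}
    domain_spans: dict[str, dict[str, tuple[int, int]]] = {}
    truth_rows: list[tuple[str, str, int]] = []
    background_rows: list[tuple[str, str, int]] = []

    long_introns_left = long_intron_genes
    for i, spec in enumerate(specs):
        gid = f"g{i + 1:02d}"
        protein, spans = _build_protein(spec, ancestors[spec.clade], member_noise, rng)
        cds = _reverse_translate(protein, rng)
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        transcript = cds + stop

        n_introns = int(rng.integers(n_introns_range[0], n_introns_range[1] + 1))
        max_introns = max(0, len(transcript) // 40 - 1)
        n_introns = min(n_introns, max_introns)
        cuts = sorted(
            rng.choice(
                np.arange(20, len(transcript) - 20), size=n_introns, replace=False
            ).tolist()
        ) if n_introns else []
        exon_pieces = []
        prev = 0
        for c in cuts + [len(transcript)]:
            exon_pieces.append(transcript[prev:c])
            prev = c
        intron_seqs = [
            _random_dna(int(rng.integers(*intron_len_range) if not (
                long_introns_left and spec.gene_type == "II" and j == 0
            ) else rng.integers(10_000, 12_000)), rng)
            for j in range(n_introns)
        ]
        if intron_seqs and spec.gene_type == "II" and long_introns_left:
            long_introns_left -= 1

        flank5 = list(_random_dna(flank, rng))
        if motif_plan:
            promoter = flank5[-promoter_len:]
            planted = _plant_into(promoter, motif_plan, motifs, rng)
            flank5[-promoter_len:] = promoter
            pseq = "".join(promoter)
            truth_rows.extend((gid, name, pos) for name, pos in planted)
            background_rows.extend(
                _record_background(gid, pseq, motifs, set(planted))
            )
        flank3 = _random_dna(flank, rng)

        body_parts = []
        exon_intervals = []  # in layout (coding) orientation
        pos = flank
        for j, piece in enumerate(exon_pieces):
            body_parts.append(piece)
            exon_intervals.append((pos, pos + len(piece)))
            pos += len(piece)
            if j < len(intron_seqs):
                body_parts.append(intron_seqs[j])
                pos += len(intron_seqs[j])
        layout = "".join(flank5) + "".join(body_parts) + flank3

        strand = "+" if rng.random() < 0.5 else "-"
        scaf_id = f"scaf{i + 1:03d}"
        if strand == "+":
            scaffold_seq = layout
            exons = exon_intervals
        else:
            scaffold_seq = revcomp(layout)
            L = len(layout)
            exons = [(L - e, L - s) for s, e in exon_intervals]

        scaffolds.append(SequenceRecord(scaf_id, scaffold_seq, "dna"))
        gene = GeneModel(
            gene_id=gid,
            scaffold_id=scaf_id,
            strand=strand,
            exons=exons,
            has_M=True,
            has_K=spec.gene_type == "II",
            protein=protein,
        )
        assert gene.spliced(scaffold_seq) == transcript
        genes.append(gene)
        transcripts.append(SequenceRecord(gid, transcript, "dna"))
        proteins.append(SequenceRecord(gid, protein, "protein"))
        clade_labels[gid] = spec.clade
        domain_spans[gid] = spans

    reference_proteins: list[SequenceRecord] = []
    reference_labels: dict[str, str] = {}
    for clade in ancestors:
        anc = ancestors[clade]
        for r in range(references_per_clade):
            rid = f"REF_{clade.replace(' ', '_')}_{r + 1}"
            spec = _GeneSpec("I" if clade == TYPE_I_CLADE else "II", clade)
            prot, _ = _build_protein(spec, anc, member_noise, rng)
            reference_proteins.append(SequenceRecord(rid, prot, "protein"))
            reference_labels[rid] = clade

    return FamilyTruth(
        scaffolds=scaffolds,
        genes=genes,
        transcripts=transcripts,
        proteins=proteins,
        clade_labels=clade_labels,
        rng_seed=seed,
        domain_spans=domain_spans,
        reference_proteins=reference_proteins,
        reference_labels=reference_labels,
        promoter_truth=pd.DataFrame(
            truth_rows, columns=["sequence_id", "motif", "start"]
        ),
        promoter_background=pd.DataFrame(
            background_rows, columns=["sequence_id", "motif", "start"]
        ),
    )


@dataclass
class AnnotatedFamily:
    """The defective annotation emitted over a FamilyTruth."""

    genes: list[GeneModel]
    proteins: list[SequenceRecord]
    records: list[TruncationRecord]


def truncate_models(
    truth: FamilyTruth, records: list[TruncationRecord], seed: int = 0
) -> AnnotatedFamily:
    """Apply annotation defects and emit the defective gene set.

    lack_M removes the 5'-most codons through the M domain; lack_K removes
    codons from the K domain through the stop; corrupt_5prime/3prime point
    the first/last ``param`` transcript bases at unrelated flank sequence.
    The emitted protein is the in-frame translation for lack_* modes and the
    longest-ORF translation for corrupt_* modes (mimicking a gene predictor
    run on a wrong region).
    """
    from .orf_complete import find_orfs  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    by_id = {r.gene_id: r for r in records}
    for gid in by_id:
        truth.gene(gid)  # raises KeyError for unknown ids
    out_genes: list[GeneModel] = []
    out_proteins: list[SequenceRecord] = []
    for gene, transcript in zip(truth.genes, truth.transcripts):
        rec = by_id.get(gene.gene_id)
        if rec is None:
            new = GeneModel(
                gene.gene_id, gene.scaffold_id, gene.strand, list(gene.exons),
                has_M=gene.has_M, has_K=gene.has_K, protein=gene.protein,
            )
            out_genes.append(new)
            out_proteins.append(SequenceRecord(gene.gene_id, gene.protein, "protein"))
            continue
        spans = truth.domain_spans[gene.gene_id]
        t_len = len(transcript.seq)
        scaffold = truth.scaffold(gene.scaffold_id)
        if rec.mode == "lack_M":
            cut = 3 * spans["M"][1]
            exons = gene.transcript_to_genomic(cut, t_len)
            protein = translate(transcript.seq[cut:], to_stop=True)
        elif rec.mode == "lack_K":
            if "K" not in spans:
                raise ValueError(f"{gene.gene_id} has no K domain to remove")
            cut = 3 * spans["K"][0]
            exons = gene.transcript_to_genomic(0, cut)
            protein = translate(transcript.seq[:cut], to_stop=False)
        elif rec.mode == "corrupt_5prime":
            n_bp = int(rec.param)
            kept = gene.transcript_to_genomic(n_bp, t_len)
            gs, ge = gene.span
            if gene.strand == "+":
                lo = gs - 1600 - n_bp  # upstream of the promoter window
                junk = (lo, lo + n_bp)
            else:
                hi = ge + 1600 + n_bp
                junk = (hi - n_bp, hi)
            if junk[0] < 0 or junk[1] > len(scaffold.seq):
                raise ValueError("scaffold flank too short to plant a corrupt exon")
            exons = sorted(kept + [junk])
            bad = GeneModel(gene.gene_id, gene.scaffold_id, gene.strand, exons)
            emitted = bad.spliced(scaffold.seq)
            orfs = find_orfs(emitted, min_len_aa=10)
            protein = orfs[0].protein if orfs else translate(emitted, to_stop=True)
        elif rec.mode == "corrupt_3prime":
            n_bp = int(rec.param)
            kept = gene.transcript_to_genomic(0, t_len - n_bp)
            gs, ge = gene.span
            if gene.strand == "+":
                hi = ge + 1600 + n_bp
                junk = (hi - n_bp, hi)
            else:
                lo = gs - 1600 - n_bp
                junk = (lo, lo + n_bp)
            if junk[0] < 0 or junk[1] > len(scaffold.seq):
                raise ValueError("scaffold flank too short to plant a corrupt exon")
            exons = sorted(kept + [junk])
            bad = GeneModel(gene.gene_id, gene.scaffold_id, gene.strand, exons)
            emitted = bad.spliced(scaffold.seq)
            orfs = find_orfs(emitted, min_len_aa=10)
            protein = orfs[0].protein if orfs else translate(emitted, to_stop=True)
        else:  # pragma: no cover - validated in TruncationRecord
            raise ValueError(rec.mode)
        rec.original_len_aa = len(protein)
        rec.true_len_aa = len(gene.protein)
        if rec.mode.startswith("lack") and not rec.original_len_aa < rec.true_len_aa:
            raise AssertionError("truncation did not shorten the protein")
        new = GeneModel(
            gene.gene_id, gene.scaffold_id, gene.strand, exons,
            has_M=rec.mode != "lack_M",
            has_K=rec.mode != "lack_K" and "K" in spans,
            reason=rec.mode,
            protein=protein,
        )
        out_genes.append(new)
        out_proteins.append(SequenceRecord(gene.gene_id, protein, "protein"))
    return AnnotatedFamily(out_genes, out_proteins, records)


def table2_panel(seed: int = 0) -> tuple[FamilyTruth, list[TruncationRecord]]:
    """The bundled 17-gene truncation panel with its defect records."""
    gene_specs = [
        {"length": length, "k_start": param if mode == "lack_K" else None}
        for mode, length, param in TRUNCATION_PANEL
    ]
    truth = gen_gene_family(
        n_genes=len(TRUNCATION_PANEL),
        n_typeI=0,
        seed=seed,
        gene_specs=gene_specs,
        clade_size=4,
    )
    records = [
        TruncationRecord(
            gene_id=f"g{i + 1:02d}",
            mode=mode,
            param=param if mode.startswith("corrupt") else None,
        )
        for i, (mode, _length, param) in enumerate(TRUNCATION_PANEL)
    ]
    return truth, records


def sim_reads(
    transcripts: list[SequenceRecord],
    depth: float = 10.0,
    read_len: int = 100,
    err_rate: float = 0.0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Substitution-error short reads tiled evenly over each transcript.

    Per transcript the read count is ceil(depth * length / read_len); start
    positions are evenly spaced so both transcript ends are covered, strands
    are drawn uniformly, and substitution errors are i.i.d. at ``err_rate``.
    """
    if not 0 <= err_rate < 1:
        raise ValueError("err_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    for t in transcripts:
        L = len(t.seq)
        if read_len > L:
            raise ValueError(
                f"read_len {read_len} exceeds transcript {t.id} length {L}"
            )
        n = math.ceil(depth * L / read_len)
        starts = np.unique(
            np.round(np.linspace(0, L - read_len, n)).astype(int)
        ) if n > 1 else np.array([0])
        # keep the requested count even when rounding collapses positions
        while len(starts) < n:
            extra = rng.integers(0, L - read_len + 1, size=n - len(starts))
            starts = np.sort(np.concatenate([starts, extra]))
        for i, s in enumerate(starts.tolist()):
            seq = t.seq[s : s + read_len]
            if err_rate > 0:
                bases = list(seq)
                for j in range(len(bases)):
                    if rng.random() < err_rate:
                        alt = "ACGT".replace(bases[j], "") if bases[j] in "ACGT" else "ACGT"
                        bases[j] = alt[rng.integers(len(alt))]
                seq = "".join(bases)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SequenceRecord(f"{t.id}_r{i + 1:05d}", seq, "dna"))
    return reads


def gen_ct_table(
    true_folds: dict[tuple[str, str], float],
    base_ct: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    ref_gene: str = "NTB",
    calibrator: str = "leaf",
    n_replicates: int = 3,
    ref_ct: float = 20.0,
) -> pd.DataFrame:
    """Long-format Ct table generated from known fold changes.

    Ct(target, sample) = base_ct - log2(fold) + noise; the reference gene is
    constant (+ noise) in every sample; the calibrator sample has fold 1 by
    construction. A NaN fold marks a not-detected gene (NaN Ct values).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for key, f in true_folds.items():
        if not np.isnan(f) and f <= 0:
            raise ValueError(f"fold change must be > 0 (got {f} for {key})")
    rng = np.random.default_rng(seed)
    samples = sorted({s for s, _ in true_folds}, key=str)
    genes = sorted({g for _, g in true_folds})
    if calibrator not in samples:
        samples = [calibrator] + samples
    rows = []
    for sample in samples:
        for gene in genes + [ref_gene]:
            if gene == ref_gene:
                mu = ref_ct
            else:
                fold = true_folds.get((sample, gene), 1.0 if sample == calibrator else None)
                if fold is None:
                    continue
                mu = np.nan if np.isnan(fold) else base_ct - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                ct = np.nan if np.isnan(mu) else mu + noise
                rows.append((sample, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
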