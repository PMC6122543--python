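"""End-to-end pipeline stages over a simulated gene family.

Each stage reads and writes plain files (FASTA/FASTQ/GFF3/TSV/CSV) so the
CLI and the analysis scripts stay thin; the science lives in the sibling
modules. Every stage is deterministic given its seed, so a full pipeline
run is byte-reproducible.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .align import crop_to_conserved, progressive_align
from .cis_scan import extract_introns, extract_promoter, load_motifs, scan_motifs, summarize_categories
from .domain_scan import ProfileModel, build_profile, classify_gene, scan_protein
from .expression import ddct, hcluster
from .orf_complete import complete_model
from .phylo_classify import assign_clade, bootstrap_support, collapse_low_support
from .read_walk import WalkParams, build_read_index, walk
from .records import SequenceRecord, WalkResult
from .synthetic_data import (
    TRUNCATION_PANEL,
    TruncationRecord,
    gen_ct_table,
    gen_gene_family,
    load_seed_alignment,
    sim_reads,
    truncate_models,
)

SAMPLES = ("leaf", "F1", "F2", "F3", "F4")


def build_profiles() -> tuple[ProfileModel, ProfileModel]:
    """M- and K-domain profiles from the bundled seed alignments."""
    m = build_profile(load_seed_alignment("M"), label="M")
    k = build_profile(load_seed_alignment("K"), label="K")
    return m, k


def simulate(
    outdir: str | Path,
    n_genes: int = 42,
    n_typeI: int = 6,
    depth: float = 10.0,
    read_len: int = 100,
    err_rate: float = 0.0,
    seed: int = 0,
    n_defects: int = 17,
) -> dict[str, Path]:
    """Generate the full synthetic input set plus ground truth tables."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    truth = gen_gene_family(n_genes, n_typeI, seed=seed)

    n_typeII = n_genes - n_typeI
    modes = [m for m, _l, p in TRUNCATION_PANEL]
    params = [p for m, _l, p in TRUNCATION_PANEL]
    records = [
        TruncationRecord(
            gene_id=truth.genes[i].gene_id,
            mode=modes[i % len(modes)],
            param=params[i % len(params)] if modes[i % len(modes)].startswith("corrupt") else None,
        )
        for i in range(min(n_defects, n_typeII))
    ]
    annotated = truncate_models(truth, records, seed=seed + 1)
    reads = sim_reads(truth.transcripts, depth, read_len, err_rate, seed=seed + 2)

    io.write_fasta(truth.scaffolds, out / "scaffolds.fa")
    io.write_gff3(annotated.genes, out / "annotation.gff3")
    io.write_fasta(annotated.proteins, out / "annotated_proteins.fa")
    scaf = {s.id: s.seq for s in truth.scaffolds}
    io.write_fasta(
        [
            SequenceRecord(g.gene_id, g.spliced(scaf[g.scaffold_id]), "dna")
            for g in annotated.genes
        ],
        out / "annotated_cds.fa",
    )
    io.write_fastq(reads, out / "reads.fq")
    io.write_fasta(truth.reference_proteins, out / "references.fa")
    with open(out / "reference_labels.tsv", "w") as fh:
        for rid, label in sorted(truth.reference_labels.items()):
            fh.write(f"{rid}\t{label}\n")

    io.write_fasta(truth.proteins, out / "truth" / "true_proteins.fa")
    io.write_fasta(truth.transcripts, out / "truth" / "true_transcripts.fa")
    io.write_gff3(truth.genes, out / "truth" / "true_annotation.gff3")
    with open(out / "truth" / "clade_labels.tsv", "w") as fh:
        for gid, label in truth.clade_labels.items():
            fh.write(f"{gid}\t{label}\n")
    pd.DataFrame(
        [
            (r.gene_id, r.mode, r.param or "", r.original_len_aa, r.true_len_aa)
            for r in annotated.records
        ],
        columns=["gene_id", "mode", "param", "original_len_aa", "true_len_aa"],
    ).to_csv(out / "truth" / "truncation_records.csv", index=False)
    truth.promoter_truth.to_csv(out / "truth" / "promoter_truth.csv", index=False)
    truth.promoter_background.to_csv(
        out / "truth" / "promoter_background.csv", index=False
    )

    # planted expression: clade-level stage profiles with per-gene jitter
    rng = np.random.default_rng(seed + 3)
    clades = sorted(set(truth.clade_labels.values()))
    profile = {
        c: {s: float(rng.normal(0.0, 1.5)) for s in SAMPLES if s != "leaf"}
        for c in clades
    }
    folds: dict[tuple[str, str], float] = {}
    fold_rows = []
    for gid, clade in truth.clade_labels.items():
        for s in SAMPLES:
            if s == "leaf":
                f = 1.0
            else:
                f = float(2.0 ** (profile[clade][s] + rng.normal(0.0, 0.3)))
            folds[(s, gid)] = f
            fold_rows.append((s, gid, f))
    pd.DataFrame(fold_rows, columns=["sample", "gene", "fold"]).to_csv(
        out / "truth" / "true_folds.csv", index=False
    )
    ct = gen_ct_table(folds, noise_sd=0.2, seed=seed + 4)
    ct.to_csv(out / "ct_table.csv", index=False)
    return {"outdir": out}


def scan_stage(proteins_fa: str | Path, outdir: str | Path) -> pd.DataFrame:
    """Classify annotated proteins by M/K domain content."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    m_prof, k_prof = build_profiles()
    proteins = io.read_fasta(proteins_fa, alphabet="protein")
    hit_rows, class_rows = [], []
    for p in proteins:
        m_hits = scan_protein(m_prof, p)
        k_hits = scan_protein(k_prof, p)
        for h in m_hits + k_hits:
            hit_rows.append((h.sequence_id, h.start, h.end, round(h.score, 3), h.frame, h.domain))
        c = classify_gene(m_hits, k_hits)
        class_rows.append((p.id, c.gene_type, c.has_M, c.has_K))
    pd.DataFrame(
        hit_rows, columns=["sequence", "start", "end", "score", "frame", "domain"]
    ).to_csv(out / "domain_hits.tsv", sep="\t", index=False)
    classification = pd.DataFrame(
        class_rows, columns=["gene_id", "type", "has_M", "has_K"]
    )
    classification.to_csv(out / "classification.tsv", sep="\t", index=False)
    return classification


def walk_stage(
    seeds_fa: str | Path,
    reads_fq: str | Path,
    outdir: str | Path,
    params: WalkParams | None = None,
    sanitize: bool = True,
) -> dict[str, object]:
    """Walk every seed against the read index; write completed sequences."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or WalkParams()
    seeds = io.read_fasta(seeds_fa)
    reads = io.read_fastq(reads_fq)
    index = build_read_index(reads, k=params.k)
    results = {}
    completed, report_rows = [], []
    for s in seeds:
        r = walk(s, index, params, sanitize=sanitize)
        results[s.id] = r
        completed.append(SequenceRecord(s.id, r.final, "dna"))
        report_rows.append(
            (
                s.id,
                len(s.seq),
                len(r.final),
                r.bases_added_5,
                r.bases_added_3,
                r.seed_offset,
                len(r.sanitized_seed),
                r.termination.get("5", ""),
                r.termination.get("3", ""),
            )
        )
    io.write_fasta(completed, out / "completed.fa")
    pd.DataFrame(
        report_rows,
        columns=[
            "seed_id", "seed_len", "final_len", "added_5prime", "added_3prime",
            "seed_offset", "sanitized_len",
            "termination_5prime", "termination_3prime",
        ],
    ).to_csv(out / "walk_report.tsv", sep="\t", index=False)
    return results


def load_walk_results(walked_dir: str | Path) -> dict[str, WalkResult]:
    """Rehydrate walk results from a walk-stage output directory."""
    walked = Path(walked_dir)
    finals = {r.id: r.seq for r in io.read_fasta(walked / "completed.fa")}
    report = pd.read_csv(walked / "walk_report.tsv", sep="\t").fillna("")
    out: dict[str, WalkResult] = {}
    for row in report.itertuples():
        final = finals[row.seed_id]
        off, slen = int(row.seed_offset), int(row.sanitized_len)
        out[row.seed_id] = WalkResult(
            seed_id=row.seed_id,
            seed=final[off : off + slen],
            final=final,
            seed_offset=off,
            sanitized_seed=final[off : off + slen],
            termination={
                "5": str(row.termination_5prime),
                "3": str(row.termination_3prime),
            },
        )
    return out


def complete_stage(
    annotation_gff3: str | Path,
    annotated_proteins_fa: str | Path,
    walk_results: dict[str, WalkResult] | str | Path,
    outdir: str | Path,
) -> pd.DataFrame:
    """Turn walked transcripts into corrected models and the before/after report.

    ``walk_results`` is either the dict returned by :func:`walk_stage` or
    the path of a walk-stage output directory.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(walk_results, dict):
        walk_results = load_walk_results(walk_results)
    m_prof, k_prof = build_profiles()
    genes = io.read_gff3(annotation_gff3)
    proteins = {p.id: p.seq for p in io.read_fasta(annotated_proteins_fa, "protein")}
    rows, corrected_prot, corrected_cds = [], [], []
    for g in genes:
        g.protein = proteins.get(g.gene_id, "")
        rep = complete_model(g, walk_results[g.gene_id], m_prof, k_prof)
        rows.append(
            (
                rep.gene_id, rep.reason, rep.original_len_aa, rep.corrected_len_aa,
                rep.has_M_before, rep.has_K_before, rep.has_M_after, rep.has_K_after,
                rep.status,
            )
        )
        if rep.corrected_protein:
            corrected_prot.append(SequenceRecord(g.gene_id, rep.corrected_protein, "protein"))
            corrected_cds.append(SequenceRecord(g.gene_id, rep.corrected_cds, "dna"))
    io.write_fasta(corrected_prot, out / "corrected_proteins.fa")
    io.write_fasta(corrected_cds, out / "corrected_cds.fa")
    report = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "reason", "original_len_aa", "corrected_len_aa",
            "has_M_before", "has_K_before", "has_M_after", "has_K_after", "status",
        ],
    )
    report.to_csv(out / "orf_report.tsv", sep="\t", index=False)
    return report


def tree_stage(
    proteins_fa: str | Path,
    references_fa: str | Path,
    reference_labels_tsv: str | Path,
    outdir: str | Path,
    n_bootstrap: int = 100,
    collapse_threshold: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Family tree with bootstrap supports and reference-guided clade labels."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    family = io.read_fasta(proteins_fa, "protein")
    refs = io.read_fasta(references_fa, "protein")
    labels = {}
    with open(reference_labels_tsv) as fh:
        for line in fh:
            rid, label = line.rstrip("\n").split("\t")
            labels[rid] = label
    msa = progressive_align(family + refs)
    cropped = crop_to_conserved(msa, max_gap_fraction=0.5)
    tree = bootstrap_support(cropped, n_reps=n_bootstrap, seed=seed)
    collapsed = collapse_low_support(tree, threshold=collapse_threshold)
    with open(out / "family.nwk", "w") as fh:
        fh.write(tree.newick() + "\n")
    with open(out / "family_collapsed.nwk", "w") as fh:
        fh.write(collapsed.newick() + "\n")
    assignments = assign_clade(collapsed, labels)
    table = pd.DataFrame(
        [(a.query_id, a.clade, ";".join(a.supporting_references)) for a in assignments],
        columns=["gene_id", "clade", "supporting_references"],
    )
    table.to_csv(out / "clade_assignments.tsv", sep="\t", index=False)
    return table


def cis_stage(
    annotation_gff3: str | Path,
    scaffolds_fa: str | Path,
    outdir: str | Path,
    motifs_tsv: str | Path | None = None,
    promoter_len: int = 1500,
) -> pd.DataFrame:
    """Promoter + intron cis-element enumeration and category summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    motifs = load_motifs(str(motifs_tsv) if motifs_tsv else None)
    genes = io.read_gff3(annotation_gff3)
    scaffolds = {s.id: s for s in io.read_fasta(scaffolds_fa)}
    tables = []
    for g in genes:
        scaf = scaffolds[g.scaffold_id]
        promoter, _ = extract_promoter(g, scaf, length=promoter_len)
        tables.append(scan_motifs(promoter, motifs, region="promoter"))
        for intron in extract_introns(g, scaf):
            tables.append(scan_motifs(intron, motifs, region="intron"))
    hits = pd.concat(tables, ignore_index=True)
    hits.to_csv(out / "cis_hits.tsv", sep="\t", index=False)
    summary, per_gene = summarize_categories(hits, motifs)
    summary.to_csv(out / "cis_summary.csv", index=False)
    per_gene.to_csv(out / "cis_per_sequence_counts.csv")
    return summary


def expr_stage(
    ct_csv: str | Path,
    outdir: str | Path,
    ref_gene: str = "NTB",
    calibrator: str = "leaf",
) -> pd.DataFrame:
    """Relative expression (2^-ΔΔCt) and hierarchical clustering of genes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ct = pd.read_csv(ct_csv)
    rel = ddct(ct, ref_gene=ref_gene, calibrator=calibrator)
    rel.to_csv(out / "relative_expression.csv", index=False)
    ok = rel[rel["flag"] == "ok"]
    matrix = ok.pivot(index="gene", columns="sample", values="fold")
    log2m = np.log2(matrix)
    log2m.to_csv(out / "log2_fold_matrix.tsv", sep="\t")
    dendro = hcluster(log2m, distance="1-pearson", linkage="average")
    with open(out / "expression_dendrogram.nwk", "w") as fh:
        fh.write(dendro.newick() + "\n")
    if dendro.dropped:
        with open(out / "excluded_genes.txt", "w") as fh:
            fh.write("\n".join(dendro.dropped) + "\n")
    return rel


def run_pipeline(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 42,
    n_typeI: int = 6,
    depth: float = 10.0,
    read_len: int = 100,
    err_rate: float = 0.0,
    n_bootstrap: int = 100,
) -> dict[str, object]:
    """simulate -> scan -> walk -> complete -> tree -> cis -> expr."""
    out = Path(outdir)
    simulate(out, n_genes, n_typeI, depth, read_len, err_rate, seed)
    classification = scan_stage(out / "annotated_proteins.fa", out / "scan")
    walks = walk_stage(out / "annotated_cds.fa", out / "reads.fq", out / "walk")
    report = complete_stage(
        out / "annotation.gff3", out / "annotated_proteins.fa", walks, out / "complete"
    )
    assignments = tree_stage(
        out / "complete" / "corrected_proteins.fa",
        out / "references.fa",
        out / "reference_labels.tsv",
        out / "tree",
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
    cis = cis_stage(out / "annotation.gff3", out / "scaffolds.fa", out / "cis")
    rel = expr_stage(out / "ct_table.csv", out / "expr")
    return {
        "classification": classification,
        "orf_report": report,
        "clade_assignments": assignments,
        "cis_summary": cis,
        "relative_expression": rel,
    }
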