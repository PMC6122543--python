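# Methods

## Problem setting

Plant MADS-box transcription factors fall into two classes: type II (MIKC)
proteins with a MADS (M) DNA-binding domain followed by intervening (I),
keratin-like (K) and C-terminal regions, and type I proteins carrying the M
domain without K. On fragmented genome assemblies, annotated models of such
genes are frequently incomplete — missing the M or K domain, or carrying a
stretch of wrong sequence in the ORF — which corrupts both family censuses
and downstream phylogenetics. The pipeline identifies family members by
domain content, repairs defective models from short transcriptome reads,
and carries the corrected proteins through clade assignment, promoter
analysis and expression analysis.

## Domain profiles

Each domain is modeled as an ungapped per-column log-odds profile built
from a seed alignment: score(col, aa) = log2(((count + c) / (N + 20c)) /
b(aa)) with pseudocount c = 1, N residues observed in the column, and a
uniform background b = 0.05. Columns with ≥ 50% gaps are dropped. The hit
threshold defaults to 60% of the minimum seed-row self-score; both the
pseudocount and the threshold fraction are exposed. A window is a hit when
its summed score reaches the threshold; overlapping hits are pruned
greedily best-first. Six-frame scanning translates each frame, breaks
windows at stops, and reports DNA coordinates with a signed frame.

This is a deliberate simplification of profile HMMs: the two domains are
short and well conserved, the profile scorer is exactly checkable against a
per-window oracle, and presence/absence calls are all the pipeline needs.
The cost is that profiles cannot model insertions within a domain; a
domain split by a genuine indel would score as two partial windows.

## The read walk

Parameters (defaults): k-mer size k = 21, minimum overlap 31 nt, maximum
mismatch rate 5%, minimum column support 1 read, iteration cap 200, length
cap 20 kb. Reads are indexed on both strands; candidate placements are
seeded by shared k-mers and evaluated as ungapped alignments (transcript-
to-read alignments of same-gene reads are indel-free absent sequencing
indels, which the simulator does not produce). Extension is a per-column
strict-majority vote over read overhangs; a tie stops the extension at
that column. An end terminates when a round adds nothing; a tie reached
after progress is re-examined from the new terminus next round, where
deeper coverage usually resolves it. Minimum support 1 is required for
exact end recovery: the terminal base of a transcript is covered by
exactly one read under any layout, so demanding two provably stops short.
Raising support or overlap only ever shortens the result (verified as a
property test).

Seed sanitization (off by default, on in the pipeline) handles models whose
annotated sequence is wrong rather than merely truncated: all acceptable
reads are anchored to the whole seed, a position counts as supported only
when an accepted read agrees with its base, and the seed is trimmed to the
longest supported run before walking. Wrong prefixes/suffixes get no
agreeing coverage (spanning reads mismatch them) and are removed; the walk
then rebuilds the true sequence outward. The walk itself never edits
interior sequence.

Stop-on-tie rather than branch exploration is a conservative choice
matching the single-sequence-per-gene output contract; paralogous reads
that tie a column therefore truncate rather than chimerize a model.

## ORF completion

Walked sequences are spliced transcripts, so gene prediction reduces to ORF
selection: all ATG-initiated, stop-terminated ORFs on both strands are
enumerated, and the corrected model is the longest ORF that overlaps the
(sanitized) seed interval and contains an M-domain hit. The report records
original and corrected lengths and has_M/has_K flags before and after; a
walk that yields no qualifying ORF is recorded as `no_orf` with the
original model retained, never silently replaced.

## Phylogenetics

The family alignment is progressive: a neighbor-joining guide tree over
3-mer distances, then profile–profile Needleman–Wunsch merges (BLOSUM62,
linear gap −8) in postorder, output rows in input order. The alignment is
cropped to columns with ≤ 50% gaps — in practice the M domain and much of
K — and pairwise p-distances (share of differing sites over mutually
ungapped columns) feed classical NJ (Saitou–Nei Q criterion, standard
branch lengths, deterministic smallest-(i,j) tie-break). NJ is exact on
additive matrices, which the correctness tests exploit. Negative branch
lengths are retained and flagged rather than zeroed, because silently
clamping breaks additive-recovery checks.

Supports are Felsenstein column bootstraps (resampling columns of the
cropped alignment; default 1000 replicates, 100 in tests and the bundled
pipeline for speed — the support estimator is unchanged, only its Monte
Carlo error grows). Branches with support strictly below 50% are collapsed
into polytomies; an edge at exactly the threshold is retained. Clade
assignment gives each query the label of the smallest edge-delimited group
(after collapsing) that contains it and at least one labeled reference;
conflicting reference labels within that group yield "unresolved".
p-distance with no substitution-model correction is intentional: distances
here separate recent clades, not deep time, and the closed form is what
the oracles need.

## cis-elements

Promoters are the 1500 nt immediately 5′ of the translational start on the
coding strand (reverse-complemented for minus-strand genes; truncated
without error at scaffold edges). Introns are the exon complement within
the gene span, reported in coding orientation. Matching is exact per IUPAC
position over both strands; a palindromic pattern (equal to its own IUPAC
reverse complement, e.g. the CArG box CCW6GG) is counted once per position
with strand "±"; for non-palindromic patterns a position matching in either
orientation is one hit with the forward orientation preferred. Overlapping
matches all count. The bundled dictionary covers ~25 named elements across
nine categories (core promoter, protein binding, hormone, tissue-specific,
light, abiotic/biotic stress, circadian, cell cycle, other); its consensus
strings are conventional definitions and are user-replaceable via a TSV.

## Expression

ΔCt is computed per replicate as Ct(target) − Ct(reference), paired by
replicate index; ΔΔCt subtracts the calibrator-sample mean; fold change is
2^−ΔΔCt with amplification efficiency fixed at 2 (no Pfaffl correction).
The replicate SD of ΔCt is reported, and each sample is tested against the
calibrator with a pooled-variance two-sample t-test (flags at p ≤ 0.05 and
p ≤ 0.01; no multiple-testing correction is applied, by design). Genes
with missing Ct values are flagged (`not_detected` / `no_reference`) and
excluded from clustering with a log, not dropped silently. Clustering is
agglomerative average linkage on 1 − Pearson distance by default
(euclidean available) over the gene × sample log2 fold matrix; a constant
row is an explicit error under the correlation distance. scipy's linkage
implementation stands behind this operation (its tie handling is
deterministic, though not the lexicographic rule one might choose when
implementing from scratch); a brute-force agglomeration oracle checks it
on tie-free inputs.

## Synthetic data: what it emulates and what it does not

The generator plants a family with real clade structure: each clade
derives from an ancestor whose M (and K) instance comes from a distinct
row of the bundled seed alignments (5% ancestor noise), members mutate the
ancestor at 3%, and type I members omit the K block. CDSs are independent
random reverse-translations per member, so paralogs are similar in protein
space but divergent in nucleotide space — reads never cross-map between
paralogs at the 5% mismatch tolerance. Genes get 4–7 introns (100–400 nt;
an optional long-intron mode plants ≥ 10 kb introns), random strands, and
2-kb flanks whose promoter window carries planted motif instances at
recorded positions; chance background matches are recorded separately at
generation time with an independent position-wise matcher. Reads are tiled
with evenly spaced start positions (so both transcript ends are covered
deterministically), random strands, i.i.d. substitution errors, and
constant placeholder qualities (the pipeline ignores quality strings). Ct
tables follow Ct(target, sample) = base − log2(fold) + N(0, σ) with a
constant reference gene and independent triplicates.

The bundled seed alignments are synthetic fixtures (flagged `.synthetic.`
in their filenames): eight rows at 12% divergence from a random consensus,
57 columns (M) and 50 (K). They give the profiles the same
detect-what-you-planted geometry as real seed alignments, but carry no
biological signal.

Passing tests on these data therefore demonstrate algorithmic correctness
— exact recovery under the stated error model, correct bookkeeping,
deterministic behaviour — not robustness to features the simulator lacks:
sequencing indels, coverage biases, chimeric or paired-end reads,
alternative splicing, nucleotide-level paralog similarity, transposon
insertions in introns, or qPCR efficiency drift. The 17-gene defect panel
mirrors the defect *modes* of a real annotation-repair scenario (6 lack_K,
7 lack_M, 4 corrupted 5′ regions, with realistic protein lengths); pure
truncation means the emitted defective model is always shorter than the
truth, whereas real mis-annotations can also be spuriously long.

## Numerical and format choices

Coordinates are 0-based half-open everywhere in memory; GFF3 emission
converts to 1-based inclusive. Alignment DP uses a linear gap penalty so
rows vectorise exactly (affine gaps are not implemented); traceback
tie-break is diagonal > up > left. All randomness flows through
numpy `default_rng` seeds; every generator and stage is byte-deterministic
under a fixed seed, and the end-to-end CLI run is verified byte-identical
across repeated runs. Simulation sizes in the tests (50-transcript walk
panels, 100-replicate bootstraps, 1000-sequence scanner oracles) were
chosen as the package's own test conditions and run in well under a minute
each on one CPU.

## Known limitations

- The walk cannot bridge coverage gaps (no paired-end rescue) and stops at
  genuine paralog branch points instead of exploring them.
- Profiles are ungapped; a domain interrupted by an in-frame insertion
  scores as fragments.
- Local alignment reports non-overlapping target hits greedily; suboptimal
  overlapping alignments are not enumerated (no BLAST-style statistics or
  E-values).
- Clade labels depend entirely on the supplied reference vocabulary; the
  package ships none.
- ΔΔCt assumes perfect doubling per cycle; efficiency-corrected
  quantification is out of scope.
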