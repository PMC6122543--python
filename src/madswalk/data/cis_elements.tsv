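# Curated cis-regulatory element dictionary (name, IUPAC pattern, category).
# Consensus strings are conventional definitions for the named elements and
# are configuration data; users may supply their own dictionary TSV.
name	pattern	category
TATA-box	TATAWAW	core promoter
CAAT-box	CCAAT	core promoter
CArG	CCWWWWWWGG	protein binding
MBS	CAACTG	protein binding
CCAAT-box	CAACGG	protein binding
ABRE	ACGTGKC	hormone response
CGTCA-motif	CGTCA	hormone response
TGACG-motif	TGACG	hormone response
TCA-element	CCATCTTTTT	hormone response
Skn-1	GTCAT	tissue-specific
GCN4-motif	TGAGTCA	tissue-specific
CAT-box	GCCACT	tissue-specific
CCGTCC-box	CCGTCC	tissue-specific
G-box	CACGTG	light response
Sp1	GGGCGG	light response
TCT-motif	TCTTAC	light response
ARE	AAACCA	abiotic/biotic stress
AAGAA-motif	GAAAGAA	abiotic/biotic stress
LTR	CCGAAA	abiotic/biotic stress
HSE	AAAAAATTTC	abiotic/biotic stress
GC-motif	CCCCCG	abiotic/biotic stress
TC-rich_repeats	ATTTTCTTCA	abiotic/biotic stress
circadian	CAANNNNATC	circadian
MSA-like	TCCAACGG	cell cycle
O2-site	GATGAYRTGR	other
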