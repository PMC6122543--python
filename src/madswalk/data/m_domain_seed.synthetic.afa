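>Mseed01
NGAPTTYIIFYLHHCYHAQHECKRCKKMWQSQWVVQDWEGIQENGVVRAHITVPMEG
>Mseed02
NMAPTTYIIFYLHQPYHAQHECQKCKFMWYSQWVVQDLKWIQTCGVVRAHIIVPMEG
>Mseed03
KMAPTTYIIWYLPHPYHAQHEDPRCKFMMYSAWVVSDLEGCQENGVVRAHATVKMNG
>Mseed04
DMAPTTVIIFYLHHPYHAQHDCQRNKFMWYSRWVVQDLWGIQENGVVWAAITVPQEG
>Mseed05
NMAPTTYIHFYLGHMYHAQHECQYCKEMWMSQWVVQDLEGIQENGVVRAHITVPMEG
>Mseed06
NMAPTTYIISYLHHPYPAQHECQRCKFMWYSQWIVQDLEGIQENGVVRAHITVPMEG
>Mseed07
NMRPTTYIIFYLHHPYHAQQRCGECKDMWYSQWVVQDLLGIQHNGKVRAHITVPMEG
>Mseed08
NMAPTTTCIFYLHYPYHAQHECQRCKFMWYSKWVVMDNVQIQWNGCVRAHITVPMEG
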