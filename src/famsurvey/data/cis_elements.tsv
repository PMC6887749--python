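name	pattern	category
W-box	TTGAC	stress
ABRE	ACGTGGC	phytohormone
MBS	CAACTG	stress
LTR	CCGAAA	stress
TCA-element	CCATCTTTTT	phytohormone
CGTCA-motif	CGTCA	phytohormone
TGA-element	AACGAC	phytohormone
ARE	AAACCA	stress
ERE	ATTTCAAA	phytohormone
TATA-box	TATAWAW	other
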