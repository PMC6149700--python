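# Eight-enzyme panel for six-species Pyropia PCR-RFLP identification.
# Recognition patterns and cut offsets transcribed from REBASE;
# outside cutters normalised to the recognition-strand frame
# (BsrI ACTGG(1/-1) -> cut5=6, cut3=4).
# name	pattern	cut5	cut3
BglI	GCCNNNNNGGC	7	4
Tth111I	GACNNNGTC	4	5
AvaII	GGWCC	1	4
BsrI	ACTGG	6	4
BsaAI	YACGTR	3	3
HindIII	AAGCTT	1	5
SacII	CCGCGG	4	2
SphI	GCATGC	5	1
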