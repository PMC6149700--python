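# Published fragment sizes (bp) for restriction digests of the partial
# plastid rbcL (BglI column, nominal amplicon 1107 bp) and mitochondrial
# rps11-trnG region (other columns, nominal amplicon 1005 bp) in six
# Pyropia species.  Cells with no reported diagnostic cut are encoded as
# the uncut amplicon length.
species	BglI	Tth111I	AvaII	BsrI	BsaAI	HindIII	SacII	SphI
P. yezoensis	556	1005	1005	1005	1005	1005	1005	1005
P. seriata	1107	664,333	1005	119,844	1005	1005	1005	1005
P. dentata	1107	1005	271,732	119,844	1005	1005	1005	1005
P. suborbiculata	1107	1005	1005	600,401	1005	1005	1005	1005
P. haitanensis	1107	1005	1005	1005	510	1005	1005	1005
P. pseudolinearis	1107	1005	1005	1005	1005	174,825	788,211	397,602
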