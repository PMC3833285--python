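# Built-in restriction enzyme panel (REBASE conventions).
# name	recognition	cut_offset   (cut_offset: top-strand cut, 0-based from the
# 5' end of the recognition site; e.g. C^CGG -> offset 1, ^CATG -> offset 0)
MspI	CCGG	1
HpaII	CCGG	1
RsaI	GTAC	2
FatI	CATG	0
Kzo9I	GATC	0
AluI	AGCT	2
AluBI	AGCT	2
AspS9I	GGNCC	1
Bme18I	GGWCC	1
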