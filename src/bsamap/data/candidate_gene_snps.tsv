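chrom	pos	effect	codon_change
Chr6	2366479	Non-synonymous coding	aTc/aGc
Chr6	2366489	Synonymous coding	ctA/ctG
Chr6	2366498	Synonymous coding	tcT/tcA
Chr6	2366504	Synonymous coding	gaT/gaC
Chr6	2366529	Non-synonymous coding	Ggt/Agt
Chr6	2366539	Non-synonymous coding	gGa/gAa
Chr6	2366558	Synonymous coding	gaG/gaA
Chr6	2366614	Non-synonymous coding	aTc/aCc
Chr6	2366656	Non-synonymous coding	gAg/gGg
Chr6	2366669	Synonymous coding	gcC/gcT
Chr6	2366678	Synonymous coding	ttG/ttA
Chr6	2366686	Non-synonymous coding	aTc/aCc
Chr6	2366697	Non-synonymous coding	Ttc/Atc
Chr6	2366710	Non-synonymous coding	aAc/aCc
Chr6	2366725	Non-synonymous coding	aAt/aGt
Chr6	2366786	Synonymous coding	tcT/tcC
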