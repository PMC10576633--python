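variant_id	gene	protein_change	function_class
chr13:28592642:C/A	FLT3	p.D835Y	missense
chr4:55599436:T/C	KIT	p.D816V	missense
chr2:25457242:C/T	DNMT3A	p.R882H	missense
chr4:106196829:T/A	TET2	p.Y1245*	nonsense
chr17:7577121:G/A	TP53	p.R273C	missense
chr12:25398284:C/T	KRAS	p.G12D	missense
chr1:115258747:C/T	NRAS	p.G12D	missense
chr21:36252877:C/T	RUNX1	p.R201Q	missense
chr2:198266834:T/C	SF3B1	p.K700E	missense
chr20:31022441:A/G	ASXL1	p.I718V	missense
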