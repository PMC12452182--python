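class	family
SAM	SAM
SAM-IV	SAM
SAH	SAM
SAM_alpha	SAM
SAM-I-IV	SAM
SAM-III	SAM
SAM-SAH	SAM
SAM_V	SAM
SAM_VI	SAM
c-di-GMP-I	c-di-GMP
c-di-GMP-II	c-di-GMP
c-di-GMP-I-GGC	c-di-GMP
c-di-GMP-II-GAG	c-di-GMP
c-di-GMP-I-UAU	c-di-GMP
c-di-GMP-II-GCG	c-di-GMP
Glycine	Glycine
glycine-GGAnGA	Glycine
Cobalamin	Cobalamin
AdoCbl_riboswitch	Cobalamin
AdoCbl-variant	Cobalamin
Purine	Purine
2dG-I	Purine
PreQ1	PreQ1
PreQ1-II	PreQ1
PreQ1-III	PreQ1
Guanidine-I	Guanidine
Guanidine-II	Guanidine
Guanidine-III	Guanidine
Glutamine	Glutamine
Glutamine-II	Glutamine
M-box	Magnesium
Mg-sensor	Magnesium
T-box	T-box
TPP	TPP
FMN	FMN
Lysine	Lysine
yybP-ykoY	Manganese
Fluoride	Fluoride
glmS	glmS
ydaO-yuaA	c-di-AMP
ZMP-ZTP	ZMP-ZTP
THF	THF
Moco	Moco
NiCo	NiCo
raiA	raiA
c-AMP-GMP	c-AMP-GMP
yjdF	yjdF
Xanthine	Xanthine
nhaA-I	Sodium
PRPP	PRPP
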