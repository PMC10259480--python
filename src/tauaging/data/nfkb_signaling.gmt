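NFkB_signaling	curated Drosophila NFkB/Imd/Toll pathway mediators (62 genes)	PGRP-LE	imd	Tak1	key	Rel	eff	PGRP-LC	bsk	akirin	Jra	sick	Tab2	IKKbeta	Uev1A	ben	Dredd	Fadd	PGRP-LA	Diap2	Diap1	egr	Traf6	trbd	pirk	casp	PGRP-LB	PGRP-LF	dnr1	scny	RYBP	PGRP-SC1a	PGRP-SC1b	PGRP-SC2	CYLD	POSH	spirit	spheroide	spz	PGRP-SA	PGRP-SD	pll	Myd88	dl	Gprk2	Deaf1	Tl	psh	grass	modSP	Dif	mop	tub	cact	nec	Pli	18w	Toll-4	Tehao	Toll-6	Toll-7	Tollo	Toll-9
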