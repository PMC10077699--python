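gene_id	gene	MM	GS
ENSSSCG00000039103	ADIPOQ	0.874557699	0.858025625
ENSSSCG00000001844	PLIN1	0.855238258	0.785834744
ENSSSCG00000027404	UNC93A	0.864469943	0.688918599
ENSSSCG00000025822	SFRP1	0.867467057	0.671675851
ENSSSCG00000034786	HACD2	0.864057374	0.645773129
ENSSSCG00000026850	SNCG	0.801110493	0.572908619
ENSSSCG00000006245	SDR16C5	0.838140788	0.569356922
ENSSSCG00000011579	PPARG	0.823399895	0.542931625
ENSSSCG00000011451	ITIH3	0.840818259	0.506913162
ENSSSCG00000010478	FFAR4	0.953347586	0.485423388
ENSSSCG00000015135	SORL1	0.88145227	0.479634802
ENSSSCG00000012138	ACE2	0.815256029	0.246877132
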