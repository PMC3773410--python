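sirna_id	gene	antisense	off_target_gene	shared_seed_mirna
s35278	WNK3	AAAUACUGACAAACGUGAGGC	ZEB1/TCF8	hsa-miR-200b
s30875	STRADB	AAAUACUGAUAUCCAAUGGGC	ZEB1/TCF8	hsa-miR-200b
SI00606011	MAPK4	UAAUGCUGAUCAACGAUCCUU	BACH1	hsa-miR-155
SI00606011	MAPK4	UAAUGCUGAUCAACGAUCCUU	TP53INP1	hsa-miR-155
s35278	WNK3	AAAUACUGACAAACGUGAGGC	RERE	hsa-miR-429
s30979	PLXNA3	AAAGUGCUUCCAUUGAUGAUG	CCND2	hsa-miR-302b
s30979	PLXNA3	AAAGUGCUUCCAUUGAUGAUG	MBNL2	hsa-miR-302d
s30979	PLXNA3	AAAGUGCUUCCAUUGAUGAUG	VEGF	hsa-miR-372
s30979	PLXNA3	AAAGUGCUUCCAUUGAUGAUG	APP	hsa-miR-520c-3p
SI00288344	TYRO3	UUGGCACUAAAGGUCACCGUU	MITF	hsa-miR-96
SI04435592	ITPKB	UUGGUCCAUAGUCUCCCUCUG	KCNQ1	hsa-miR-133a
SI03649674	TNK1	UAAUGCUCCAGGAUGCGCCAG	MEIS1	hsa-miR-155
SI00127918	PACSIN1	UUGGUCCCUCAGAUGGGCCUG	PITX3	hsa-miR-133b
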