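est_id	mirna_name	homolog_name	mature_seq_raw	msl	psl	mfe_dg	mfe_kcal	gc_percent	mfei
medp_camac_20101112|9453	cac-miR-5653	ath-miR5653	GTTGAGTTTGAGTTGAGTTG	20	205	-100	-102.7	35.12	-1.389
medp_camac_20101112|7558	cac-miR-5780d	gma-miR5780d	TGTTTTGAGTTTCTG-TAAAT	21	210	-80.8	-83.96	32.86	-1.171
medp_camac_20101112|10526	cac-miR-3440-3p	aly-miR3440-3p	CGGTTCTCTCTGACCATATCCA	22	141	-74.1	-75.88	45.39	-1.158
medp_camac_20101112|33501	cac-miR-8157-3p	ssa-miR-8157-3p	CTCTGTGCATTCTGCTGTGCT	21	220	-67.7	-72.58	52.27	-0.589
medp_camac_20101112|6119	cac-miR-6903-5p	mmu-miR-6903-5p	TGGTAGAGT-CTGCTTTTCCCA	22	220	-61.3	-64.88	40.45	-0.689
medp_camac_20101112|44664	cac-miR-7398f-5p	mdo-miR-7398f-5p	ATT-CCACATCTCTTCTACACT	22	220	-60.4	-64.34	44.09	-0.623
medp_camac_20101112|9293	cac-miR-156e-3p	bdi-miR156e-3p	GACAGAGAGAGAAGTGGAGC	20	183	-58.5	-61.48	42.08	-0.760
medp_camac_20101112|29	cac-miR-5532	osa-miR5532	ATGGAATATATGACAAAGGTG	21	220	-57.4	-61.99	39.09	-0.667
medp_camac_20101112|6065	cac-miR-4723-3p	hsa-miR-4723-3p	TTTGGGGAGGAG--AGAGAGGG	22	217	-56.3	-61.33	45.16	-0.574
medp_camac_20101112|447	cac-miR-5049-3p	bdi-miR5049-3p	TAATATGGAATCGGAGGAAGT	21	220	-53.3	-57.51	39.55	-0.613
medp_camac_20101112|3541	cac-miR-5291c	mtr-miR5291c	TTTGATGGATGGCATTG-ATGGA	23	221	-53.2	-57.84	41.63	-0.578
medp_camac_20101112|4893	cac-miR-548d-3p	mml-miR-548d-3p	GCAGAAAGAAATTGTGGTGTTTT	23	222	-53.1	-58.01	37.39	-0.640
medp_camac_20101112|18253	cac-miR-29c-5p	ssa-miR-29c-5p	CTGTTTTCTTTTGGCTGTTT	20	219	-52.2	-56.62	42.47	-0.561
medp_camac_20101112|10789	cac-miR-7009-3p	mmu-miR-7009-3p	GCAGGGAGAGGGGATAAAGA	20	219	-51.4	-55.09	36.99	-0.635
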