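strain	construct	rate_e5	sd_e5
Wild Type	5ORIΔ-ΔR	210	30
Wild Type	0ORIΔ-ΔR	3	2
Wild Type	5ORIΔ	9	3
Wild Type	ΔL-6ORIΔ	240	40
sml1Δ	5ORIΔ-ΔR	160	50
sml1Δ	0ORIΔ-ΔR	18	3
sml1Δ	5ORIΔ	6	2
sml1Δ	ΔL-6ORIΔ	130	30
rad9 (ofm14)	5ORIΔ-ΔR	1500	100
rad9 (ofm14)	0ORIΔ-ΔR	19	4
rad9 (ofm14)	5ORIΔ	39	11
rad9 (ofm14)	ΔL-6ORIΔ	ND	ND
rad9Δ	5ORIΔ-ΔR	2100	400
rad9Δ	0ORIΔ-ΔR	32	6
rad9Δ	5ORIΔ	30	8
rad9Δ	ΔL-6ORIΔ	9600	1000
rad17Δ	5ORIΔ-ΔR	1100	100
rad17Δ	0ORIΔ-ΔR	12	3
rad17Δ	5ORIΔ	ND	ND
rad17Δ	ΔL-6ORIΔ	ND	ND
rad24Δ	5ORIΔ-ΔR	980	180
rad24Δ	0ORIΔ-ΔR	12	3
rad24Δ	5ORIΔ	24	5
rad24Δ	ΔL-6ORIΔ	1500	300
mec1Δ sml1Δ	5ORIΔ-ΔR	1400	200
mec1Δ sml1Δ	0ORIΔ-ΔR	33	7
mec1Δ sml1Δ	5ORIΔ	260	40
mec1Δ sml1Δ	ΔL-6ORIΔ	610	100
mrc1Δ	5ORIΔ-ΔR	1200	200
mrc1Δ	0ORIΔ-ΔR	150	20
mrc1Δ	5ORIΔ	530	100
mrc1Δ	ΔL-6ORIΔ	460	100
chk1Δ	5ORIΔ-ΔR	410	50
chk1Δ	0ORIΔ-ΔR	9	2
chk1Δ	5ORIΔ	N.D.	N.D.
chk1Δ	ΔL-6ORIΔ	1100	200
rad53Δ sml1Δ	5ORIΔ-ΔR	490	90
rad53Δ sml1Δ	0ORIΔ-ΔR	67	11
rad53Δ sml1Δ	5ORIΔ	N.D.	N.D.
rad53Δ sml1Δ	ΔL-6ORIΔ	1200	200
rad53Δ chk1Δ sml1Δ	5ORIΔ-ΔR	880	140
rad53Δ chk1Δ sml1Δ	0ORIΔ-ΔR	39	7
rad53Δ chk1Δ sml1Δ	5ORIΔ	N.D.	N.D.
rad53Δ chk1Δ sml1Δ	ΔL-6ORIΔ	9000	1000
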