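chromosome	FS	FL	Micro	FU	FE	Color	FM	Perimeter	WT	WallThick	SLF	HI	BW	LI	LP	SCY	LY	BN	LB	Gossypol	Protein	Oil	HP	EPP	LargenumFS	NOFuzFib	SW	SI	SM	FBNum	FBNode	Pubescence	NFFB	HNFFB	LeafMorph	OP	Nematode	VW	Fusarium	Xcm	Chlorophyll	CIR	CT
c1	5	8	11	1	5	3	0	0	0	0	0	0	1	0	0	1	3	0	0	0	0	1	0	0	0	0	0	0	0	0	0	1	1	0	2	2	1	0	0	0	0	0	0
c2	3	0	6	5	6	0	0	0	0	0	0	2	1	0	0	2	0	1	0	0	2	0	0	0	0	0	0	0	1	0	0	0	0	0	1	1	0	0	1	0	2	0	0
c3	5	16	11	1	2	1	1	0	0	1	0	0	0	0	1	1	1	0	0	1	3	1	1	0	0	0	0	1	0	0	0	0	0	0	1	0	2	0	0	0	0	0	0
c4	2	7	7	3	1	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	2	0	0	0	0	0	0
c5	6	4	16	4	2	2	1	0	0	1	0	0	2	1	2	0	1	0	0	0	3	1	0	0	0	0	0	0	0	1	0	0	1	0	0	0	7	6	0	1	0	0	0
c6	1	6	12	3	3	8	0	0	0	0	0	0	0	0	0	1	1	0	0	0	2	0	0	1	0	0	0	0	0	0	0	2	1	0	3	1	0	0	0	0	0	0	1
c7	9	7	4	3	5	2	0	0	0	0	0	0	0	1	3	1	2	0	0	0	0	0	0	0	0	0	1	1	0	0	0	0	0	0	0	0	13	2	0	0	0	0	0
c8	2	5	3	3	1	9	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0
c9	2	5	9	3	5	6	1	0	0	1	0	0	0	1	1	3	1	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0	0	0	2	0	4	1	0	0	0	0	0
c10	1	4	8	2	4	1	1	1	1	0	0	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0
c11	5	1	2	0	0	3	0	0	0	0	0	0	1	2	3	1	0	1	0	0	0	1	0	0	0	0	1	0	0	1	0	0	1	0	0	0	17	0	0	0	0	0	0
c12	7	9	11	10	7	0	1	0	0	0	0	0	1	2	2	2	1	0	0	0	2	2	0	0	1	2	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0
c13	1	3	4	1	3	0	0	0	0	0	0	0	0	0	0	1	2	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
c14	9	8	13	5	8	4	2	1	1	0	0	1	4	2	1	3	3	1	0	0	1	0	1	0	0	0	0	3	0	1	0	0	0	0	0	0	8	0	0	1	1	1	0
c15	3	4	13	5	9	2	0	0	0	0	0	0	1	0	1	1	1	0	0	0	2	1	0	1	0	0	0	0	0	0	1	0	0	0	6	0	4	0	1	0	0	1	0
c16	10	2	10	4	2	1	1	0	0	0	0	0	1	0	2	1	1	0	0	0	1	1	0	0	0	0	1	0	0	1	2	0	0	0	0	0	0	16	0	0	0	0	0
c17	0	1	7	7	4	2	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	2	1	4	0	0	0	0	0	0	1	0
c18	6	6	9	4	4	4	1	0	0	1	1	2	3	0	0	3	2	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	1	0	0	0	0	0	0
c19	2	9	10	2	12	3	0	0	0	0	0	0	0	0	0	0	0	0	0	2	3	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	6	3	0	0	0	0	0
c20	2	4	5	4	6	0	0	0	1	0	0	0	0	0	0	1	1	0	0	0	2	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	3	0	0	0	0	0	0
c21	5	6	9	3	4	2	0	0	0	0	0	0	1	0	0	0	0	1	0	0	2	3	0	0	0	0	0	0	0	0	1	0	0	0	0	0	3	2	0	0	0	0	0
c22	1	0	3	4	2	2	0	0	0	0	1	0	3	1	0	0	1	0	0	1	1	0	0	0	0	0	0	1	0	0	0	0	0	0	1	0	1	2	0	0	0	0	0
c23	13	10	6	1	8	4	0	0	0	0	0	0	1	0	3	0	0	0	1	0	0	0	0	0	0	0	0	1	0	0	0	1	0	0	0	0	2	26	0	0	0	0	0
c24	26	5	17	6	9	0	1	0	0	0	0	0	1	0	0	1	1	0	0	0	2	1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
c25	4	7	20	2	3	11	1	0	0	0	0	0	2	1	0	2	0	0	1	0	2	0	0	0	0	0	0	0	0	0	1	2	0	0	1	1	0	0	0	0	0	1	0
c26	2	14	8	5	3	1	0	0	0	0	0	0	2	2	3	3	1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	2	0	0	0	0	0
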