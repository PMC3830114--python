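name	chromosome	trait	start_cM	end_cM	n_qtl
c1-FL-Hotspot-1	c1	FL	66	86	5
c2-FE-Hotspot-1	c2	FE	30	43	4
c3-FL-Hotspot-2	c3	FL	0	20	7
c3-FL-Hotspot-3	c3	FL	43	55	5
c3-Micronaire-Hotspot-1	c3	Micro	23	43	5
c4-FL-Hotspot-4	c4	FL	46	58	5
c4-Micronaire-Hotspot-2	c4	Micro	34	55	4
c5-Micronaire-Hotspot-3	c5	Micro	0	20	5
c5-Nematode-Hotspot-1	c5	Nematode	27	47	6
c6-color-Hotspot-1	c6	Color	8	17	6
c6-Micronaire-Hotspot-4	c6	Micro	0	24	4
c7-FL-Hotspot-5	c7	FL	0	18	4
c7-FS-Hotspot-1	c7	FS	0	27	5
c7-Nematode-Hotspot-2	c7	Nematode	0	22	9
c8-color-Hotspot-2	c8	Color	20	39	7
c10-Micronaire-Hotspot-5	c10	Micro	0	20	4
c11-Nematode-Hotspot-3	c11	Nematode	0	20	14
c12-FL-Hotspot-6	c12	FL	72	91	6
c12-FU-Hotspot-1	c12	FU	23	34	5
c12-Micronaire-Hotspot-6	c12	Micro	0	16	4
c12-Micronaire-Hotspot-7	c12	Micro	23	34	4
c14-Micronaire-Hotspot-8	c14	Micro	99	118	5
c14-Nematode-Hotspot-4	c14	Nematode	0	15	8
c15-FE-Hotspot-2	c15	FE	17	39	5
c15-Leaf-Hotspot-1	c15	LeafMorph	17	39	6
c15-Micronaire-Hotspot-9	c15	Micro	23	49	10
c16-Micronaire-Hotspot-10	c16	Micro	0	23	8
c16-VW-Hotspot-1	c16	VW	0	23	5
c16-VW-Hotspot-2	c16	VW	30	50	7
c16-VW-Hotspot-3	c16	VW	51	64	4
c17-FU-Hotspot-2	c17	FU	63	78	4
c17-Micronaire-Hotspot-11	c17	Micro	11	27	5
c18-Micronaire-Hotspot-12	c18	Micro	28	43	5
c19-FE-Hotspot-3	c19	FE	124	144	4
c19-Micronaire-Hotspot-13	c19	Micro	0	25	4
c21-Micronaire-Hotspot-14	c21	Micro	60	81	4
c23-FE-Hotspot-4	c23	FE	0	22	4
c23-FS-Hotspot-2	c23	FS	77	85	6
c23-VW-Hotspot-4	c23	VW	0	21	13
c23-VW-Hotspot-5	c23	VW	26	46	9
c24-FS-Hotspot-3	c24	FS	31	51	16
c24-Micronaire-Hotspot-15	c24	Micro	0	19	4
c24-Micronaire-Hotspot-16	c24	Micro	29	35	4
c24-Micronaire-Hotspot-17	c24	Micro	92	110	4
c25-color-Hotspot-3	c25	Color	21	40	4
c25-color-Hotspot-4	c25	Color	55	75	7
c25-Micronaire-Hotspot-18	c25	Micro	0	21	10
c25-Micronaire-Hotspot-19	c25	Micro	33	65	4
c26-FL-Hotspot-7	c26	FL	0	22	4
c26-FL-Hotspot-8	c26	FL	45	65	6
c26-Micronaire-Hotspot-20	c26	Micro	28	45	6
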