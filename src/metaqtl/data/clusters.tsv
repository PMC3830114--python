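name	chromosome	start_cM	end_cM	n_qtl
c1-cluster-1	c1	14	34	9
c1-cluster-2	c1	58	82	10
c1-cluster-3	c1	95	126	7
c2-cluster-1	c2	0	14	5
c2-cluster-2	c2	32	52	13
c2-cluster-3	c2	82	105	5
c3-cluster-1	c3	0	20	15
c3-cluster-2	c3	23	48	23
c4-cluster-1	c4	0	8	7
c4-cluster-2	c4	46	66	10
c5-cluster-1	c5	0	20	15
c5-cluster-2	c5	22	42	16
c5-cluster-3	c5	59	79	5
c5-cluster-4	c5	84	104	14
c6-cluster-1	c6	0	17	19
c6-cluster-2	c6	24	37	6
c6-cluster-3	c6	53	67	10
c7-cluster-1	c7	0	25	32
c7-cluster-2	c7	43	59	9
c7-cluster-3	c7	72	91	5
c8-cluster-1	c8	0	20	6
c8-cluster-2	c8	25	39	9
c8-cluster-3	c8	107	144	5
c9-cluster-1	c9	0	20	16
c9-cluster-2	c9	29	54	14
c10-cluster-1	c10	0	20	13
c10-cluster-2	c10	79	112	12
c11-cluster-1	c11	0	20	26
c12-cluster-1	c12	0	16	11
c12-cluster-2	c12	18	38	19
c12-cluster-3	c12	67	85	10
c13-cluster-1	c13	0	17	6
c13-cluster-2	c13	29	44	6
c14-cluster-1	c14	0	20	30
c14-cluster-2	c14	52	66	10
c14-cluster-3	c14	82	91	7
c14-cluster-4	c14	99	122	16
c15-cluster-1	c15	0	17	8
c15-cluster-2	c15	20	44	24
c15-cluster-3	c15	60	68	10
c16-cluster-1	c16	0	23	28
c16-cluster-2	c16	30	40	9
c16-cluster-3	c16	50	70	16
c17-cluster-1	c17	5	23	12
c17-cluster-2	c17	53	78	13
c18-cluster-1	c18	0	19	15
c18-cluster-2	c18	28	43	9
c18-cluster-3	c18	53	65	7
c18-cluster-4	c18	76	93	8
c19-cluster-1	c19	0	20	14
c19-cluster-2	c19	32	52	14
c19-cluster-3	c19	62	82	5
c19-cluster-4	c19	97	117	5
c19-cluster-5	c19	124	144	12
c20-cluster-1	c20	0	20	7
c20-cluster-2	c20	25	45	13
c20-cluster-3	c20	117	137	5
c21-cluster-1	c21	12	32	6
c21-cluster-2	c21	48	64	12
c21-cluster-3	c21	70	87	8
c21-cluster-4	c21	96	104	5
c22-cluster-1	c22	0	22	19
c23-cluster-1	c23	0	22	26
c23-cluster-2	c23	25	35	10
c23-cluster-3	c23	40	70	10
c23-cluster-4	c23	76	87	11
c23-cluster-5	c23	102	119	7
c24-cluster-1	c24	0	17	13
c24-cluster-2	c24	17	19	6
c24-cluster-3	c24	35	45	17
c24-cluster-4	c24	56	66	5
c25-cluster-1	c25	0	21	21
c25-cluster-2	c25	40	62	13
c25-cluster-3	c25	73	89	17
c26-cluster-1	c26	0	22	14
c26-cluster-2	c26	33	51	19
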