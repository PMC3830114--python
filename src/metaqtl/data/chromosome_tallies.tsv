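chromosome	n_clusters	n_hotspots
c1	3	1
c2	3	1
c3	2	3
c4	2	2
c5	4	2
c6	3	2
c7	3	3
c8	3	1
c9	2	0
c10	2	1
c11	1	1
c12	3	4
c13	2	0
c14	4	2
c15	3	3
c16	3	4
c17	2	2
c18	4	1
c19	5	2
c20	3	0
c21	4	1
c22	1	0
c23	5	4
c24	4	4
c25	3	4
c26	2	3
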