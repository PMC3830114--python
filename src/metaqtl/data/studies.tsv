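author	journal	year	n_qtl	population	trait_type
An C et al	Euphytica	2010	26	F2	Yield
Chee P et al	Theor Appl Genet	2005	17	BC3F2	Fiber
Chen H et al	Theor Appl Genet	2009	20	RIL	Fiber
Draye X et al	Theor Appl Genet	2005	36	BC3F2	Fiber
Feng J et al	Sci China Series C: Life Sciences	2009	41	F2:3	Resistance
Guo Y et al	Euphytica	2008	5	F2	Morphological
Gutierrez OA et al	Theor Appl Genet	2010	12	RIL	Resistance
Gutierrez OA et al	Theor Appl Genet	2011	3	BCP1/2	Resistance
Jiang C et al	Theor Appl Genet	2000	16	F2	Morpholigical
Jiang CX et al	Proc. Natl. Acad. Sci. USA	1998	7	F2	Fiber
Lacape JM et al	BMC Plant Biology	2010	233	RIL	Fiber
Lacape JM et al	Crop Science	2005	61	BC1,2,BC2S1	Fiber
Li C et al	Euphytica	2012	7	F2:3	Morpholigical
Liu HY et al	Euphytica	2012	10	RIL	Yield
Liu R et al	Mol Breed	2012	26	RIL	Yield
Mei M et al	Theor Appl Genet	2004	3	F2	Fiber
Paterson AH et al	Theor Appl Genet	2003	24	F2/F3	Fiber
Qin H et al	Theor Appl Genet	2008	20	4WC	Yield and Fiber
Rong J et al	Theor Appl Genet	2005	5	F2	Yield
Saranga Y et al	Plant Cell Environ	2004	35	F2/F3	Yield
Shen X et al	Mol Breed	2005	28	F2 & F2:3	Fiber
Shen X et al	Crop Sci	2006	1	RIL	Yield
Shen X et al	Theor Appl Genet	2006	13	F2	Resistance
Shen X et al	Theor Appl Genet	2010	1	F2	Resistance
Sun FD et al	Mol Breed	2012	39	RIL	Fiber
Waghmare VN et al	Theor Appl Genet	2005	9	F2	Morpholigical
Wang B et al	Euphytica	2006	24	RIL	Fiber
Wang C et al	PLoS ONE	2012	45	RIL	Resistance
Wang F et al	Mol Breed	2013	21	F2/F2:3	Fiber
Wang HM et al	Journal Integr Plant Biol	2008	4	F2:3	Resistance
Wang P et al	Theor Appl Genet	2012	33	CSIL	Fiber
Wang P et al	Theor Appl Genet	2009	2	F2:3	Resistance
Wright RJ et al	J Hered	1999	6	B2/B3b6/B3	Morpholigical
Wright RJ et al	Genetics	1998	2	B2/B3b6/B3	Resistance
Wu Jixiang et al	Euphytica	2009	56	RIL	Fiber
Yang C et al	Plant Sci	2008	18	BC1S2	Resistance
Yu J et al	Euphytica	2012	41	BIL	Seed
Yu J et al	Euphytica	2013	103	F2:F2:3:TC	Fiber
Yu J et al	Theor Appl Genet	2013	67	BIL	Fiber and Yield
Zhang K et al	Mol Breed	2012	60	F1:2,1:3	Fiber
Zhang Z et al	Theor Appl Genet	2011	30	BC3F1	Fiber
Zhang ZS et al	Mol Breed	2009	13	RIL	Fiber
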