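# VTE susceptibility SNP panel (Thai case-control study); 38 variants, 26 genes.
# literature_or is the published per-allele odds ratio used as the default PRS weight.
gene	rsid	effect_allele	reference_allele	literature_or	category
PROC	rs146922325	T	C	6.91	established
THBD	rs16984852	A	C	2.80	established
F2	rs1799963	A	G	1.88	established
F2	rs191945074	T	C	1.86	established
ABO	rs8176719	C	-	1.85	established
ABO	rs8176743	T	C	1.76	established
FGG	rs2066865	A	G	1.56	established
PAI-1	rs2227631	A	G	1.55	established
APOH	rs8178847	T	C	1.55	established
NOS3	rs1799983	T	G	1.41	established
ABO	rs2519093	T	C	1.40	established
ABO	rs9411377	A	C	1.36	established
ABO	rs687289	A	G	1.34	established
F11	rs2036914	T	C	1.32	established
MTHFR	rs1801133	T	C	1.30	established
F11	rs2289252	T	C	1.26	established
ABO	rs8176749	T	C	1.23	established
F11	rs4253417	C	T	1.22	established
SERPINC1	rs2227589	T	C	1.20	established
HIVEP1	rs169713	C	T	1.20	established
TSPAN15	rs78707713	T	C	1.20	established
FGG	rs2066864	A	G	1.20	established
KNG1	rs710446	G	A	1.19	established
F2	rs3136516	G	A	1.19	established
PROS1	rs6795524	G	A	1.19	established
CYP4V2	rs13146272	A	C	1.17	established
VWF	rs1063856	C	T	1.16	established
GP6	rs1613662	G	A	1.15	established
F5	rs4524	C	T	0.88	established
SERPINC1	rs2227624	A	T	0.99	novel
PDIA3	rs139974673	T	C	0.98	novel
PPP1R3B	rs34290760	C	G	0.96	novel
SYK	rs10993706	A	G	0.93	novel
TGFB2	rs57615042	A	G	0.89	novel
MTOR	rs12097293	A	G	0.77	novel
KNG1	rs5030062	A	C	0.63	novel
ZFPM1	rs55823018	T	C	0.31	novel
XXYLT1	rs56324901	A	G	0.20	novel
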