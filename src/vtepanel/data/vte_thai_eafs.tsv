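# Observed effect-allele frequencies in the Thai case-control cohort
# (122 VTE patients / 87 healthy controls); defaults for the synthetic cohort generator.
rsid	eaf_case	eaf_control
rs146922325	0.16	0.09
rs16984852	0.01	0.00
rs1799963	0.00	0.00
rs191945074	0.09	0.08
rs8176719	0.46	0.40
rs8176743	0.26	0.17
rs2066865	0.52	0.36
rs2227631	0.42	0.42
rs8178847	0.02	0.05
rs1799983	0.14	0.14
rs2519093	0.24	0.21
rs9411377	0.00	0.00
rs687289	0.63	0.55
rs2036914	0.19	0.24
rs1801133	0.09	0.11
rs2289252	0.55	0.48
rs8176749	0.24	0.18
rs4253417	0.54	0.43
rs2227589	0.33	0.37
rs169713	0.28	0.19
rs78707713	0.97	0.95
rs2066864	0.80	0.74
rs710446	0.36	0.39
rs3136516	0.86	0.82
rs6795524	0.04	0.03
rs13146272	0.54	0.56
rs1063856	0.07	0.08
rs1613662	0.09	0.07
rs4524	0.09	0.22
rs2227624	0.00	0.00
rs139974673	1.00	1.00
rs34290760	0.99	0.99
rs10993706	0.23	0.17
rs57615042	0.69	0.78
rs12097293	0.93	0.91
rs5030062	0.63	0.61
rs55823018	0.58	0.57
rs56324901	0.45	0.48
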