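CpG_site	Gene	Mean_control	Mean_drinker	P_drinking	Mean_baseline	Mean_followup	P_exercise
cg00510787	C6orf96	0.2395	0.1636	7.59E-06	0.2267	0.3120	4.66E-06
cg00542846	APP	0.2209	0.1363	5.71E-09	0.1540	0.2131	3.67E-06
cg06270401	DYRK4	0.4840	0.4200	8.05E-06	0.4549	0.5179	1.37E-05
cg06415153	PITPNM2	0.5131	0.4328	1.37E-11	0.4302	0.5058	1.73E-07
cg07031532	OAZ2	0.0883	0.1587	4.00E-08	0.1454	0.0848	2.07E-06
cg12286890	XCL2	0.6152	0.7205	2.74E-09	0.6534	0.5369	8.58E-12
cg12671744	FAAH	0.2281	0.2919	2.33E-06	0.2737	0.2076	1.63E-07
cg14760714	RPUSD2	0.2151	0.1421	4.09E-09	0.1482	0.2088	4.37E-07
cg15364618	CIDEB	0.1907	0.2983	1.27E-07	0.2916	0.2500	6.93E-06
cg15679651	MAP4K1	0.3130	0.2544	2.15E-07	0.3477	0.4097	1.14E-05
cg17091851	LOC348174	0.4846	0.5437	5.66E-06	0.5238	0.4697	9.25E-08
cg18241160	CDC2L2	0.5656	0.3396	2.38E-12	0.3923	0.5310	1.10E-06
cg24648715	TCEAL3	0.3423	0.2492	1.65E-13	0.2696	0.3173	1.23E-09
cg24792360	FUCA1	0.4656	0.5297	1.00E-07	0.5060	0.4716	3.03E-07
cg26825412	SOX18	0.6743	0.6061	1.45E-11	0.6602	0.7093	1.56E-06
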