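# Differentially expressed miRNAs curated from the recurrent pregnancy loss literature,
# as printed (verbatim, including the duplicated hsa-miR-30d-5p row and negative
# log-scale fold values for four down-regulated entries). p_value "<0.001" entries kept as text.
name	state	sequence	fold_change	p_value
hsa-miR-146a-5p	UP	UGAGAACUGAAUUCCAUGGGUU	4.45436783	0.0009
hsa-miR-125a-5p	UP	UCCCUGAGACCCUUUAACCUGUGA	2.79	<0.001
hsa-miR-155-5p	UP	UUAAUGCUAAUCGUGAUAGGGGUU	3.96	<0.001
hsa-miR-221-3p	UP	AGCUACAUUGUCUGCUGGGUUUC	7.409	0.0070
hsa-miR-146b-5p	UP	UGAGAACUGAAUUCCAUAGGCUG	5.108	0.0087
hsa-miR-320b	UP	AAAAGCUGGGUUGAGAGGGCAA	2.637	0.0022
hsa-miR-133a-3p	UP	UUUGGUCCCCUUCAACCAGCUG	0.009684	<0.001
hsa-miR-101-3p	UP	UACAGUACUGUGAUAACUGAA	3.614	0.0193
hsa-miR-223-3p	UP	UGUCAGUUUGUCAAAUACCCCA	5.7	<0.001
hsa-miR-92a-3p	UP	UAUUGCACUUGUCCCGGCCUGU	2.662	0.0308
hsa-miR-148b-3p	UP	UCAGUGCAUCACAGAACUUUGU	4.595	0.0434
hsa-miR-30d-5p	UP	UGUAAACAUCCCCGACUGGAAG	4.361	0.0285
hsa-miR-23b-3p	UP	AUCACAUUGCCAGGGAUUACCAC	3.430	0.0210
hsa-miR-423-3p	UP	AGCUCGGUCUGAGGCCCCUCAGU	2.01	0.0332
hsa-miR-145-5p	UP	GUCCAGUUUUCCCAGGAAUCCCU	0.722968	0.5116
hsa-miR-16-5p	UP	UAGCAGCACGUAAAUAUUGGCG	0.879078	0.3559
hsa-miR-181a-5p	UP	AACAUUCAACGCUGUCGGUGAGU	2.854288	0.0925
hsa-miR-424-5p	UP	CAGCAGCAAUUCAUGUUUUGAA	0.127032	0.8565
hsa-miR-30d-5p	UP	UGUAAACAUCCCCGACUGGAAG	0.604136	0.1879
hsa-miR-143-3p	UP	UGAGAUGAAGCACUGUAGCUC	1.336424	0.2162
hsa-miR-27b-3p	UP	UUCACAGUGGCUAAGUUCUGC	1.052276	0.4425
hsa-miR-17-5p	Down	CAAAGUGCUUACAGUGCAGGUAG	0.35	0.0020
hsa-miR-19b-3p	Down	UGUGCAAAUCCAUGCAAAACUGA	0.34	<0.001
hsa-miR-559	Down	UAAAGUAAAUAUGCACCAAAA	0.390	0.0150
hsa-miR-365a-3p	Down	UAAUGCCCCUAAAAAUCCUUAU	0.321	0.0318
hsa-miR-1182	Down	GAGGGUCUUGGGAGGGAUGUGAC	0.238	0.0186
hsa-miR-4284	Down	GGGCUCACAUCACCCCAU	0.428	0.0079
hsa-miR-4264	Down	ACUCAGUCAUGGUCAUU	0.113	0.0013
hsa-miR-4474-5p	Down	UUAGUCUCAUGAUCAGACACA	0.196	0.0399
hsa-miR-22-5p	Down	AGUUCUUCAGUGGCAAGCUUUA	0.337	0.0172
hsa-miR-372-5p	Down	CCUCAAAUGUGGAGCACUAUUCU	0.22803727	0.0021
hsa-miR-451a	Down	AAACCGUUACCAUUACUGAGUU	-1.31401	0.0592
hsa-miR-21-5p	Down	UAGCUUAUCAGACUGAUGUUGA	-1.45161	0.4086
hsa-miR-149-5p	Down	UCUGGCUCCGUGUCUUCACUCCC	-1.530395	0.1853
hsa-miR-181b-5p	Down	AACAUUCAUUGCUGUCGGUGGGU	-2.329242	0.0434
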