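# Signed edges of the narrated RPL TF-miRNA loop network.
# miRNA targeting is repressive; TF->miRNA transcriptional regulation is activating unless
# the narrative implies repression (NFKB1 represses miR-21-5p in the double-negative switch).
source	target	interaction_type	sign	evidence
hsa-miR-92a-3p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-16-5p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-155-5p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-146a-5p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-21-5p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-146b-5p	NFKB1	mirna_target	repression	curated: six miRNAs target NFKB1
hsa-miR-21-5p	STAT3	mirna_target	repression	curated: miR-21-5p targets its regulators
hsa-miR-21-5p	E2F1	mirna_target	repression	curated: REL/miR-21-5p cascade targets
hsa-miR-21-5p	MMP2	mirna_target	repression	curated: miR-17-5p and miR-21-5p target MMP2
hsa-miR-21-5p	VEGFA	mirna_target	repression	curated: REL/miR-21-5p cascade targets
hsa-miR-17-5p	MMP2	mirna_target	repression	curated: miR-17-5p and miR-21-5p target MMP2
hsa-miR-17-5p	VEGFA	mirna_target	repression	curated: E2F1/NFKB1-regulated miR-17-5p targets
hsa-miR-17-5p	IL8	mirna_target	repression	curated: E2F1/NFKB1-regulated miR-17-5p targets
hsa-miR-17-5p	E2F1	mirna_target	repression	curated: E2F1/NFKB1-regulated miR-17-5p targets
NFKB1	hsa-miR-21-5p	tf_mirna	repression	curated: NFKB1/miR-21-5p double-negative switch
NFKB1	hsa-miR-155-5p	tf_mirna	activation	curated: NFKB1/miR-155-5p oscillating loop
NFKB1	hsa-miR-146a-5p	tf_mirna	activation	curated: NFKB1/miR-146a-5p oscillating loop
NFKB1	hsa-miR-17-5p	tf_mirna	activation	curated: miR-17-5p regulated by E2F1 and NFKB1
STAT3	hsa-miR-21-5p	tf_mirna	activation	curated: STAT3-dependent activation of miR-21-5p
STAT5	hsa-miR-17-5p	tf_mirna	activation	curated: STAT5 regulates miR-17-5p
E2F1	hsa-miR-17-5p	tf_mirna	activation	curated: miR-17-5p regulated by E2F1 and NFKB1
REL	hsa-miR-21-5p	tf_mirna	activation	curated: REL regulates miR-21-5p
ESR1	hsa-miR-21-5p	tf_mirna	activation	curated: ESR1 induces miR-21-5p transcription
ESR1	NFKB1	tf_gene	activation	curated: ESR1 and miR-21-5p jointly regulate NFKB1
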