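# Nodes of the narrated RPL TF-miRNA loop network.
# miRNA expression states come from the curated miRNA table; TF/target states are not narrated.
id	node_class	expression_state
NFKB1	TF	unknown
STAT3	TF	unknown
STAT5	TF	unknown
E2F1	TF	unknown
REL	TF	unknown
ESR1	TF	unknown
hsa-miR-21-5p	miRNA	down
hsa-miR-155-5p	miRNA	up
hsa-miR-146a-5p	miRNA	up
hsa-miR-146b-5p	miRNA	up
hsa-miR-92a-3p	miRNA	up
hsa-miR-16-5p	miRNA	up
hsa-miR-17-5p	miRNA	down
MMP2	target_gene	unknown
VEGFA	target_gene	unknown
IL8	target_gene	unknown
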