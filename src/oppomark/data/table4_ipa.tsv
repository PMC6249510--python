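# Static fixture: canonical-pathway enrichment of the opposite-direction
# marker genes, produced by a proprietary pathway tool. Shipped for
# documentation only; this package does not compute pathway enrichment.
Canonical_pathway	Molecules	P_value
Anandamide degradation	FAAH	8.14E-04
Reelin signaling in neurons	MAP4K1, APP	2.24E-03
Wnt/beta-catenin	SOX18, MAP4K1	7.41E-03
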