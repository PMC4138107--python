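gene_id	reason
AAEL011434	dual-specificity MAPK phosphatase ortholog; not a classical PTP
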