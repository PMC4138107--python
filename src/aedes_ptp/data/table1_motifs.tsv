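accession	domain_index	presence	m1_seq	m1_status	m8_seq	m8_status	m9_seq	m9_status	m10_seq	m10_status	verdict
AAEL001046	1	DEGENERATE		ABSENT		ABSENT		ABSENT		ABSENT	INACTIVE
AAEL001046	2	DEGENERATE		ABSENT		ABSENT		ABSENT		ABSENT	INACTIVE
AAEL001919-PA	1	WELL_FORMED		ABSENT	YTTWPDFGIP	ACTIVE	PIIHCSAGIGRSGT	ACTIVE	IQTVDQLYF	ACTIVE	ACTIVE
AAEL001919-PB	1	WELL_FORMED		ABSENT	YTTWPDFGIP	ACTIVE	PIIHCSAGIGRSGT	ACTIVE	IQTVDQLYF	ACTIVE	ACTIVE
AAEL003108	1	WELL_FORMED	NLNKNRY	ACTIVE	YLAWPDHGVP	ACTIVE	PIIHCSAGIGRTG	ACTIVE	VQNVSQYRF	ACTIVE	ACTIVE
AAEL005492	1	WELL_FORMED	NLAKNRY	ACTIVE	FTSWPDYGVP	ACTIVE	PMVVHCSAGIGRT	ACTIVE	IQMPDQYVF	ACTIVE	ACTIVE
AAEL008528-PA	1	DEGENERATE		ABSENT		ABSENT		ABSENT		ABSENT	INACTIVE
AAEL008528-PA	2	WELL_FORMED	NESKHKR	INACTIVE	FQVWPDHGVP	ACTIVE	PICVHCSAGIGRT	ACTIVE	VQTEAQYKF	ACTIVE	ACTIVE
AAEL008528-PB	1	DEGENERATE		ABSENT		ABSENT		ABSENT		ABSENT	INACTIVE
AAEL008528-PB	2	WELL_FORMED	NESKHKR	INACTIVE	FQVWPDHGVP	ACTIVE	PICVHCSAGIGRT	ACTIVE	VQTEAQYKF	ACTIVE	ACTIVE
AAEL010234	1	WELL_FORMED	NKARNF	ACTIVE	YNEWGDQNCP	INACTIVE	PPVLIHCNEGGGRT	INACTIVE	TPSLAQYKF	INACTIVE	INACTIVE
AAEL010914	1	WELL_FORMED	KNRSID	INACTIVE	LWPKQSA	INACTIVE	NCLNGSDRSC	INACTIVE	DPNHMQL	INACTIVE	INACTIVE
AAEL011434	1	WELL_FORMED	QSKNRY	ACTIVE	FPDWPDHRSP	ACTIVE	PIIHCSAGIGRTG	ACTIVE	VQNSEQYEL	ACTIVE	ACTIVE
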