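motif_id	name	role	active_pattern	offset	tolerance	template
1	KNRY loop	active_site	[KR].{0,2}R.?[YF]	-170	50	NLNKNRY
2	beta-sheet core 2	core	DFWQMVW	-150	20	DFWQMVW
3	beta-sheet core 3	core	KCAQYWP	-130	20	KCAQYWP
4	core loop 4	core	NTRVIMV	-105	20	NTRVIMV
5	core loop 5	core	EYGDFKV	-85	20	EYGDFKV
6	core strand 6	core	GPIEVID	-65	15	GPIEVID
7	pre-WPD core 7	core	RQESLAV	-50	12	RQESLAV
8	WPD loop	active_site	WPD	-42	18	YLAWPDHGVP
9	P-loop/HCX5R	active_site	HCSAG[IVLM]GR	-4	8	PIIHCSAGIGRTG
10	Q loop	active_site	.Q...Q...	50	20	VQNVSQYRF
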