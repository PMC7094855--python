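gene	pattern	FC6	FC12	FC24	area
WG01	DDD	0.0625	0.0625	0.0625	tie
WG02	D-U	0.5	1	2	A
WG03	DU-	0.5	2	1	B
WG04	-UD	1	2	0.5	C
WG05	U-D	2	1	0.5	D
WG06	UD-	2	0.5	1	E
WG07	-DU	1	0.5	2	F
WG08	DDD	0.015625	0.0078125	0.00390625	D
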