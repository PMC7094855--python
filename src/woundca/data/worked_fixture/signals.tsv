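gene	t0_r1	t0_r2	t0_r3	t0_r4	t6_r1	t6_r2	t6_r3	t6_r4	t12_r1	t12_r2	t12_r3	t12_r4	t24_r1	t24_r2	t24_r3	t24_r4
WG01	2.0	8.0	2.0	8.0	2.0	8.0	2.0	8.0	2.0	8.0	2.0	8.0	2.0	8.0	2.0	8.0
WG02	32.0	32.0	32.0	32.0	256.0	256.0	256.0	256.0	512.0	512.0	512.0	512.0	1024.0	1024.0	1024.0	1024.0
WG03	32.0	32.0	32.0	32.0	256.0	256.0	256.0	256.0	1024.0	1024.0	1024.0	1024.0	512.0	512.0	512.0	512.0
WG04	32.0	32.0	32.0	32.0	512.0	512.0	512.0	512.0	1024.0	1024.0	1024.0	1024.0	256.0	256.0	256.0	256.0
WG05	32.0	32.0	32.0	32.0	1024.0	1024.0	1024.0	1024.0	512.0	512.0	512.0	512.0	256.0	256.0	256.0	256.0
WG06	32.0	32.0	32.0	32.0	1024.0	1024.0	1024.0	1024.0	256.0	256.0	256.0	256.0	512.0	512.0	512.0	512.0
WG07	32.0	32.0	32.0	32.0	512.0	512.0	512.0	512.0	256.0	256.0	256.0	256.0	1024.0	1024.0	1024.0	1024.0
WG08	64.0	64.0	64.0	64.0	16.0	16.0	16.0	16.0	8.0	8.0	8.0	8.0	4.0	4.0	4.0	4.0
WG09	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0	16.0
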