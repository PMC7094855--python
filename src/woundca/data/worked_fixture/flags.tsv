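gene	t0_r1	t0_r2	t0_r3	t0_r4	t6_r1	t6_r2	t6_r3	t6_r4	t12_r1	t12_r2	t12_r3	t12_r4	t24_r1	t24_r2	t24_r3	t24_r4
WG01	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG02	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG03	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG04	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG05	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG06	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG07	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG08	Dt	Dt	Dt	Dt	Dt	NDt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt
WG09	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Dt	Cm	Dt	Dt	Dt	Dt	Dt
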