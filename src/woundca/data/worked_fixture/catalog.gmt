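WT001	early responders	WG02	WG03	WG04	WG05
WT002	late responders	WG05	WG06	WG07	WG08
WT003	flat	WG01	WG08
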