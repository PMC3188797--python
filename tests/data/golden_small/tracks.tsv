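mark_act	EEMB	probe	tracks/mark_act.bedgraph
mark_rep	EEMB	probe	tracks/mark_rep.bedgraph
polii	EEMB	read	tracks/polii.bedgraph
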