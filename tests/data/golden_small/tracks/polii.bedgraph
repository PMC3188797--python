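chrI	3500	3600
chrI	5000	5100
chrI	5000	5100
chrI	7500	7600
chrI	7500	7600
chrI	7500	7600
chrI	11500	11600
chrI	13000	13100
chrI	13000	13100
chrI	15500	15600
chrI	15500	15600
chrI	15500	15600
chrI	19500	19600
chrI	925	1025
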