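transcript_id	EEMB
t00	5
t01	3
t02	8
t03	1
t04	9
t05	2
t06	7
t07	0
t08	6
t09	4
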