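{
 "designed_read_overlap": {
  "bin": "TSS:d1",
  "transcript": "t00",
  "value": 0.25
 },
 "rpkm_EEMB": [
  5.0,
  3.0,
  8.0,
  1.0,
  9.0,
  2.0,
  7.0,
  0.0,
  6.0,
  4.0
 ],
 "spearman_mark_act_TSSu1": -0.10303030303030303
}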