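# Test-chemical descriptors.
MXC:
  name: methoxychlor
  log_kow: 5.08
BaP:
  name: benzo[a]pyrene
  log_kow: 5.99
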