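{
  "PGC": ["NANOS3", "SOX17", "TFAP2C", "PRDM1", "NANOG"]
}
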