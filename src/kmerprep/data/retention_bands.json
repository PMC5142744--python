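{
  "quality_filter": [0.95, 1.0],
  "abundance_trim": [0.85, 0.96],
  "digital_normalization": [0.6, 0.78]
}
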