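# Dissociation constants reported in nM; converted to pKd.
label_unit: Kd_nM
columns:
  label: Kd_nM
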