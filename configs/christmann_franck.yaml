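# Compendium already standardized to pAct by its curators; passed through.
label_unit: pAct
columns:
  label: pAct
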