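# Single-dose kinase panel reporting percent activity of the inhibited kinase;
# bridged to percent inhibition (100 - activity), then converted to pIC50
# under the Hill-slope-1 model at the 0.5 uM screening dose.
label_unit: percent_activity
columns:
  label: percent_activity
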