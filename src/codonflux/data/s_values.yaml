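# Selective constraints per wobble pairing kind (0 = perfect coupling)
# and per-(codon:anticodon) overrides. Edit to explore alternatives.
s_values:
  "A34:U3": 0.0
  "G34:C3": 0.0
  "U34:A3": 0.0
  "C34:G3": 0.0
  "G34:U3": 0.41
  "I34:C3": 0.28
  "I34:A3": 0.9999
  "U34:G3": 0.68
  "L34:A3": 0.89
overrides:
  "CGA:ACG": 0.9172
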