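# Therapists with lower salaries: nurse 150 DKK/h, physiotherapist 120 DKK/h.
name: lower_salaries
overrides:
  nurse_hourly: 150
  physiotherapist_hourly: 120
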