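# Maximum of 12 patients per course: only the per-patient divisor changes.
name: twelve_patients_per_course
overrides:
  patients_per_course: 12
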