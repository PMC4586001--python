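# One standard-education course: identical group training and education,
# no interviews, no team evaluation, no expert patient.
arm: standard
nurse:
  training_h: 36
  education_h: 8
physiotherapist:
  training_h: 36
  education_h: 4
expert: {}
expert_transport_time_h: 0
expert_transport_cost_total: 0
patients_per_course: 10
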