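# One learning-and-coping course (8 weeks, 10 patients on average):
# group sessions plus individual clarifying interviews, weekly team
# evaluations and an expert patient acting as lay educator.
arm: lc
nurse:
  training_h: 36     # 3 x 1.5 h/week x 8 weeks
  education_h: 8     # 1 x ~1 h/week (planned 1.5 h shared across roles)
  interview_h: 10    # initial + final clarifying interviews
  team_eval_h: 8     # weekly team evaluation, 1 h
physiotherapist:
  training_h: 36
  education_h: 4
  interview_h: 10
  team_eval_h: 8
expert:
  training_h: 12
  education_h: 12
  team_eval_h: 8
expert_transport_time_h: 16
expert_transport_cost_total: 2304   # hospital-paid, per-course average
patients_per_course: 10
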