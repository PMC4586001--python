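# Exclude the value of patients' own (informal) time from the societal total.
name: exclude_patient_time
exclusions: [patient_time]
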