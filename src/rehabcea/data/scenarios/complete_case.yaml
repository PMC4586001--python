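# Complete-response analysis: patients with all three utility measurements observed.
name: complete_case
imputation: complete_case
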