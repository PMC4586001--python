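# Sensitivity analysis of the imputation procedure: last observation carried forward.
name: locf_imputation
imputation: locf
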