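# Exclude the load factor on staff formal hours.
name: no_load_factor
overrides:
  load_factor: 1.0
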