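# Approximate Danish consumer price index, normalised to 2013 = 100, for
# inflating costs to the common price year. All shipped unit costs are
# already in 2013 prices, so these entries exist for inputs priced earlier.
index:
  2009: 91.9
  2010: 94.0
  2011: 96.6
  2012: 98.9
  2013: 100.0
  2014: 100.6
target_year: 2013
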