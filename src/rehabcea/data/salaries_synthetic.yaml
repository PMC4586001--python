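# SYNTHETIC national-average-style salary table (DKK/hour, 2013 price level),
# gender x 5-year age band, gross and net hourly wages, for valuing time by
# the opportunity-cost method. The published source prints only four example
# cells (male/female 60-64); this table reproduces those exactly and fills
# the remaining bands with a plausible synthetic age profile. Ages above the
# top band clamp to the top band.
entries:
  male:
    15: {gross: 95,  net: 85}
    20: {gross: 120, net: 106}
    25: {gross: 140, net: 123}
    30: {gross: 152, net: 133}
    35: {gross: 158, net: 139}
    40: {gross: 162, net: 142}
    45: {gross: 165, net: 145}
    50: {gross: 166, net: 146}
    55: {gross: 165, net: 145}
    60: {gross: 164, net: 144}
    65: {gross: 150, net: 132}
    70: {gross: 140, net: 123}
    75: {gross: 135, net: 118}
    80: {gross: 130, net: 114}
  female:
    15: {gross: 90,  net: 75}
    20: {gross: 110, net: 91}
    25: {gross: 125, net: 103}
    30: {gross: 130, net: 108}
    35: {gross: 133, net: 110}
    40: {gross: 135, net: 112}
    45: {gross: 136, net: 113}
    50: {gross: 136, net: 113}
    55: {gross: 135, net: 112}
    60: {gross: 134, net: 111}
    65: {gross: 124, net: 103}
    70: {gross: 116, net: 96}
    75: {gross: 112, net: 93}
    80: {gross: 108, net: 89}
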