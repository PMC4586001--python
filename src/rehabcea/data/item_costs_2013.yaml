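# Unit costs for costing group-based cardiac rehabilitation education,
# common price year 2013, DKK.
items:
  nurse_hourly: 197            # gross wage of the nurse delivering sessions
  physiotherapist_hourly: 160  # gross wage of the physiotherapist
  expert_patient_hourly: 108   # flat pensioner net wage for the lay educator
  patient_transport_per_km: 3.82   # government tariff, private car
  expert_transport_per_way: 49     # hospital-paid tariff per one-way trip
  km_per_way: 10               # assumed distance per one-way patient trip
  transport_minutes_per_way: 20    # assumed travel time per one-way trip
load_factor: 1.5      # staff formal hours -> paid hours (non-productive time)
overhead_rate: 0.21   # hospital capital / indirect cost rate
price_year: 2013
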