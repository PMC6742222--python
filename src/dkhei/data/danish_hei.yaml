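components:
- name: fruit_veg
  direction: adequacy
  zero_point: 0.0
  full_point: 600.0
  basis: grams
  period: day
- name: dietary_fibre
  direction: adequacy
  zero_point: 0.0
  full_point: 30.0
  basis: grams
  period: day
- name: fish
  direction: adequacy
  zero_point: 0.0
  full_point: 350.0
  basis: grams
  period: week
- name: red_meat
  direction: moderation
  zero_point: 500.0
  full_point: 200.0
  basis: grams
  period: week
- name: sfa
  direction: moderation
  zero_point: 10.0
  full_point: 0.0
  basis: energy_percent
  period: day
  energy_factor: 37.0
- name: sodium
  direction: moderation
  zero_point: 2.4
  full_point: 1.6
  basis: grams
  period: day
- name: ssb
  direction: moderation
  zero_point: 500.0
  full_point: 0.0
  basis: grams
  period: week
- name: added_sugar
  direction: moderation
  zero_point: 10.0
  full_point: 0.0
  basis: energy_percent
  period: day
  energy_factor: 17.0
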