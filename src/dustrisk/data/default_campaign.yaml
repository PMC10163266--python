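elements:
  Fe:
    gm: 35000
    gsd: 1.4
  Ca:
    gm: 50000
    gsd: 1.4
  Al:
    gm: 60000
    gsd: 1.4
  K:
    gm: 18000
    gsd: 1.4
  Mg:
    gm: 15000
    gsd: 1.4
  Na:
    gm: 10000
    gsd: 1.5
  Ti:
    gm: 3000
    gsd: 1.5
  Mn:
    gm: 600
    gsd: 1.6
  Ba:
    gm: 400
    gsd: 1.6
  Sr:
    gm: 300
    gsd: 1.6
  V:
    gm: 70
    gsd: 1.7
  Zn:
    gm: 80
    gsd: 1.8
  Cr:
    gm: 80
    gsd: 1.8
  Ni:
    gm: 40
    gsd: 1.8
  Cu:
    gm: 30
    gsd: 1.8
  Pb:
    gm: 20
    gsd: 1.9
  Co:
    gm: 12
    gsd: 1.8
  As:
    gm: 8
    gsd: 2.0
  Mo:
    gm: 1.5
    gsd: 2.0
  Cd:
    gm: 0.3
    gsd: 2.0
sites:
  D1:
    city: Jiroft
    offset: 1.1
  D2:
    city: Jiroft
    offset: 1.05
  D3:
    city: Jiroft
    offset: 1.0
  D4:
    city: Roodbar Jonoob
    offset: 1.05
  D5:
    city: Roodbar Jonoob
    offset: 0.95
  D6:
    city: Ghaleh Ganj
    offset: 0.9
  D7:
    city: Ghaleh Ganj
    offset: 0.95
  D8:
    city: Kahnooj
    offset: 0.8
  D9:
    city: Kahnooj
    offset: 1.0
  D10:
    city: Iranshahr
    offset: 1.0
  D11:
    city: Iranshahr
    offset: 1.3
pm:
  gm_pm25: 40.0
  gsd_pm25: 1.6
  gm_pm10: 55.0
  gsd_pm10: 1.6
  event_prob: 0.2
  event_magnitude: 4.0
  n_days: 150
  start: '2021-04-01'
n_samples: 1
seed: 0
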