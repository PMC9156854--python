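# Noble crayfish -- DEB parameters at T_ref = 293.15 K (20 C).
species: astacus_astacus
common_name: noble crayfish
family: Astacidae
primary:
  pAm: 192.025
  v: 0.02944
  kappa: 0.9305
  pM: 60.42
  EG: 4422.0
  EHh: 1.053
  EHb: 2.435
  EHp: 5844.0
  ha: 1.679e-08
  t0: 43.28
  deltaM: 0.2449
  deltaMC: 0.5451
  deltaMh: 0.1607
male:
  pAm: 232.52
  EHp: 3982.0
temperature:
  TA: 8000.0
  TAH: 21000.0
  TAL: 18000.0
  TH: 295.15
  TLcrit: 280.15
  Tref: 293.15
  Ttyp: 285.15
auxiliary:
  kJ: 0.002
  kapR: 0.95
  kapX: 0.8
  Fm: 6.5
  sG: 0.0
composition:
  dV: 1.0
  wE: 23.9
  muE: 93500.0
reproduction:
  clutches_per_year: 1.0
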