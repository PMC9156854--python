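# Signal crayfish -- DEB parameters at T_ref = 293.15 K (20 C).
species: pacifastacus_leniusculus
common_name: signal crayfish
family: Astacidae
primary:
  pAm: 253.508
  v: 0.03783
  kappa: 0.9319
  pM: 74.92
  EG: 4374.0
  EHh: 1.963
  EHb: 2.042
  EHp: 8042.0
  ha: 8.963e-09
  t0: 30.94
  deltaM: 0.2513
  deltaMC: 0.4948
  deltaMh: null
male:
  pAm: 326.242
  EHp: 2976.0
temperature:
  TA: 8000.0
  TAH: 21000.0
  TAL: 18000.0
  TH: 301.15
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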