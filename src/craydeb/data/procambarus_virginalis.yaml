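# Marbled crayfish -- DEB parameters at T_ref = 293.15 K (20 C).
# Obligately parthenogenetic: no male parameter overlay exists.
species: procambarus_virginalis
common_name: marbled crayfish
family: Cambaridae
primary:
  pAm: 158.437
  v: 0.05713
  kappa: 0.7051
  pM: 47.8
  EG: 4490.0
  EHh: 0.077
  EHb: 6.709
  EHp: 1735.0
  ha: 1.119e-07
  t0: 22.89
  deltaM: 0.2451
  deltaMC: 0.5493
  deltaMh: 0.1
male: null
temperature:
  TA: 8000.0
  TAH: 21000.0
  TAL: 18000.0
  TH: 305.15
  TLcrit: 288.15
  Tref: 293.15
  Ttyp: 293.15
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
  clutches_per_year: 5.0
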