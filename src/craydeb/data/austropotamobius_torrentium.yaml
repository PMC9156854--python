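# Stone crayfish -- DEB parameters at T_ref = 293.15 K (20 C).
# Rates in J/d units; lengths in cm; maturities in J.
species: austropotamobius_torrentium
common_name: stone crayfish
family: Astacidae
primary:
  pAm: 69.3065      # {p_Am}, max surface-specific assimilation rate, J/d/cm^2
  v: 0.04252        # energy conductance, cm/d
  kappa: 0.9606     # allocation fraction to soma
  pM: 22.56         # [p_M], volume-specific somatic maintenance, J/d/cm^3
  EG: 4443.0        # [E_G], specific cost of structure, J/cm^3
  EHh: 1.261        # maturity at hatching, J
  EHb: 2.031        # maturity at birth, J
  EHp: 757.2        # maturity at puberty, J
  ha: 1.018e-08     # Weibull ageing acceleration, 1/d^2
  t0: 63.56         # time at start of development, d
  deltaM: 0.3132    # shape coefficient, total length
  deltaMC: 0.5553   # shape coefficient, carapace length
  deltaMh: null     # shape coefficient at hatching (not available)
male:
  pAm: 84.1479
  EHp: 3614.0
temperature:
  TA: 8000.0        # Arrhenius temperature, K
  TAH: 21000.0      # Arrhenius temperature, high boundary, K
  TAL: 18000.0      # Arrhenius temperature, low boundary, K
  TH: 294.15        # upper boundary of tolerance range, K (21 C)
  TLcrit: 280.15    # lower boundary of tolerance range, K (7 C)
  Tref: 293.15      # reference temperature, K (20 C)
  Ttyp: 284.15      # typical field temperature, K (11 C)
auxiliary:
  kJ: 0.002         # maturity maintenance rate coefficient, 1/d
  kapR: 0.95        # reproduction efficiency
  kapX: 0.8         # digestion (assimilation) efficiency
  Fm: 6.5           # {F_m}, max specific searching rate, l/d/cm^2
  sG: 0.0           # Gompertz stress coefficient
composition:
  dV: 1.0           # wet structural density, g/cm^3
  wE: 23.9          # molar weight of reserve, g/mol
  muE: 93500.0      # effective chemical potential of reserve, J/mol
reproduction:
  clutches_per_year: 0.5   # one clutch every second year
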