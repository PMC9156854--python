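{
 "austropotamobius_torrentium": {
  "species": "austropotamobius_torrentium",
  "common_name": "stone crayfish",
  "family": "Astacidae",
  "primary": {
   "pAm": 69.3065,
   "v": 0.04252,
   "kappa": 0.9606,
   "pM": 22.56,
   "EG": 4443.0,
   "EHh": 1.261,
   "EHb": 2.031,
   "EHp": 757.2,
   "ha": 1.018e-08,
   "t0": 63.56,
   "deltaM": 0.3132,
   "deltaMC": 0.5553,
   "deltaMh": null
  },
  "male": {
   "pAm": 84.1479,
   "EHp": 3614.0
  },
  "temperature": {
   "TA": 8000.0,
   "TAH": 21000.0,
   "TAL": 18000.0,
   "TH": 294.15,
   "TLcrit": 280.15,
   "Tref": 293.15,
   "Ttyp": 284.15
  },
  "auxiliary": {
   "kJ": 0.002,
   "kapR": 0.95,
   "kapX": 0.8,
   "Fm": 6.5,
   "sG": 0.0
  },
  "composition": {
   "dV": 1.0,
   "wE": 23.9,
   "muE": 93500.0
  },
  "reproduction": {
   "clutches_per_year": 0.5
  }
 },
 "astacus_astacus": {
  "species": "astacus_astacus",
  "common_name": "noble crayfish",
  "family": "Astacidae",
  "primary": {
   "pAm": 192.025,
   "v": 0.02944,
   "kappa": 0.9305,
   "pM": 60.42,
   "EG": 4422.0,
   "EHh": 1.053,
   "EHb": 2.435,
   "EHp": 5844.0,
   "ha": 1.679e-08,
   "t0": 43.28,
   "deltaM": 0.2449,
   "deltaMC": 0.5451,
   "deltaMh": 0.1607
  },
  "male": {
   "pAm": 232.52,
   "EHp": 3982.0
  },
  "temperature": {
   "TA": 8000.0,
   "TAH": 21000.0,
   "TAL": 18000.0,
   "TH": 295.15,
   "TLcrit": 280.15,
   "Tref": 293.15,
   "Ttyp": 285.15
  },
  "auxiliary": {
   "kJ": 0.002,
   "kapR": 0.95,
   "kapX": 0.8,
   "Fm": 6.5,
   "sG": 0.0
  },
  "composition": {
   "dV": 1.0,
   "wE": 23.9,
   "muE": 93500.0
  },
  "reproduction": {
   "clutches_per_year": 1.0
  }
 },
 "pacifastacus_leniusculus": {
  "species": "pacifastacus_leniusculus",
  "common_name": "signal crayfish",
  "family": "Astacidae",
  "primary": {
   "pAm": 253.508,
   "v": 0.03783,
   "kappa": 0.9319,
   "pM": 74.92,
   "EG": 4374.0,
   "EHh": 1.963,
   "EHb": 2.042,
   "EHp": 8042.0,
   "ha": 8.963e-09,
   "t0": 30.94,
   "deltaM": 0.2513,
   "deltaMC": 0.4948,
   "deltaMh": null
  },
  "male": {
   "pAm": 326.242,
   "EHp": 2976.0
  },
  "temperature": {
   "TA": 8000.0,
   "TAH": 21000.0,
   "TAL": 18000.0,
   "TH": 301.15,
   "TLcrit": 280.15,
   "Tref": 293.15,
   "Ttyp": 285.15
  },
  "auxiliary": {
   "kJ": 0.002,
   "kapR": 0.95,
   "kapX": 0.8,
   "Fm": 6.5,
   "sG": 0.0
  },
  "composition": {
   "dV": 1.0,
   "wE": 23.9,
   "muE": 93500.0
  },
  "reproduction": {
   "clutches_per_year": 1.0
  }
 },
 "procambarus_virginalis": {
  "species": "procambarus_virginalis",
  "common_name": "marbled crayfish",
  "family": "Cambaridae",
  "primary": {
   "pAm": 158.437,
   "v": 0.05713,
   "kappa": 0.7051,
   "pM": 47.8,
   "EG": 4490.0,
   "EHh": 0.077,
   "EHb": 6.709,
   "EHp": 1735.0,
   "ha": 1.119e-07,
   "t0": 22.89,
   "deltaM": 0.2451,
   "deltaMC": 0.5493,
   "deltaMh": 0.1
  },
  "male": null,
  "temperature": {
   "TA": 8000.0,
   "TAH": 21000.0,
   "TAL": 18000.0,
   "TH": 305.15,
   "TLcrit": 288.15,
   "Tref": 293.15,
   "Ttyp": 293.15
  },
  "auxiliary": {
   "kJ": 0.002,
   "kapR": 0.95,
   "kapX": 0.8,
   "Fm": 6.5,
   "sG": 0.0
  },
  "composition": {
   "dV": 1.0,
   "wE": 23.9,
   "muE": 93500.0
  },
  "reproduction": {
   "clutches_per_year": 5.0
  }
 }
}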