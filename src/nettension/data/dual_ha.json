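{
 "description": "Representative dual hysteresis+adaptation solution (base variant) from a warm-started product-objective adaptive-walk search.",
 "params": {
  "ke_MYC": 0.0213023178,
  "d_MYC": 0.997719728,
  "k_CDm": 1.1047298,
  "k_CDs": 17.3023957,
  "d_CD": 3.5604431,
  "k_E2Fm": 22.9954182,
  "k_auto": 36.7401995,
  "k_tl": 98.0128234,
  "d_E2Fm": 3.37549151,
  "d_E2Fp": 2.58045238,
  "k_Adeg": 1.63369669,
  "k_RB": 0.0312513334,
  "d_RB": 0.0600303662,
  "k_phD": 0.05,
  "K_phD": 0.068858265,
  "k_phE": 1167.71296,
  "K_phE": 1.29259103,
  "k_deph": 1.25678598,
  "d_RP": 4.46201889,
  "k_CE": 0.126950473,
  "d_CE": 5.61597028,
  "k_A": 10.0,
  "d_A": 0.066346151,
  "k_X": 0.00570157524,
  "K_XM": 0.216608457,
  "d_X": 0.0894244486,
  "K_S": 1.07322943,
  "K_M": 0.0773435145,
  "K_P": 1.83602733,
  "K_RB": 0.001,
  "K_X": 0.0802089001
 }
}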