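{
 "description": "Representative dual hysteresis+biphasic solution (base variant) from a product-objective adaptive-walk search, at physiological concentrations.",
 "params": {
  "ke_MYC": 0.0103922411,
  "d_MYC": 0.007,
  "k_CDm": 0.0320692499,
  "k_CDs": 0.003,
  "d_CD": 9.7819192,
  "k_E2Fm": 8.89661403,
  "k_auto": 0.927681085,
  "k_tl": 4.204462,
  "d_E2Fm": 2.91291761,
  "d_E2Fp": 6.29249902,
  "k_Adeg": 0.00196839092,
  "k_RB": 0.00646431753,
  "d_RB": 0.0290576332,
  "k_phD": 0.05,
  "K_phD": 30.0,
  "k_phE": 0.934193838,
  "K_phE": 0.0350903263,
  "k_deph": 30.0,
  "d_RP": 0.647123676,
  "k_CE": 0.289205064,
  "d_CE": 0.053957861,
  "k_A": 0.00287380348,
  "d_A": 3.70995499,
  "k_X": 0.131434949,
  "K_XM": 1000.0,
  "d_X": 0.00503098476,
  "K_S": 2.56994595,
  "K_M": 1.22257068,
  "K_P": 0.134041481,
  "K_RB": 0.16259518,
  "K_X": 0.005
 }
}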