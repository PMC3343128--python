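{
 "description": "Reference temporal-adaptation parameter set (base variant), selected from an adaptive-walk adaptation archive at physiological concentrations.",
 "params": {
  "ke_MYC": 1.33498078,
  "d_MYC": 0.0134230886,
  "k_CDm": 0.824329345,
  "k_CDs": 0.0135137749,
  "d_CD": 64.2130901,
  "k_E2Fm": 0.0335555459,
  "k_auto": 0.147987027,
  "k_tl": 2.96129015,
  "d_E2Fm": 0.255155275,
  "d_E2Fp": 0.112548217,
  "k_Adeg": 0.305768857,
  "k_RB": 1.77301553,
  "d_RB": 1.11289582,
  "k_phD": 500.0,
  "K_phD": 0.175220785,
  "k_phE": 490.636309,
  "K_phE": 24.5577822,
  "k_deph": 0.0263398659,
  "d_RP": 50.0,
  "k_CE": 11.1133125,
  "d_CE": 1.07327594,
  "k_A": 2.3709136,
  "d_A": 0.00251337168,
  "k_X": 0.00912958614,
  "K_XM": 18.8507353,
  "d_X": 0.0159657016,
  "K_S": 6.07064952,
  "K_M": 0.212231998,
  "K_P": 99.8892712,
  "K_RB": 0.704744191,
  "K_X": 0.005
 }
}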