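{
 "description": "Reference bistable (hysteresis) parameter set for the base RB-E2F model; produced by manual tuning and verified by the bidirectional serum sweep. Also the centre of the default 4-decade search ranges.",
 "params": {
  "ke_MYC": 1.0,
  "d_MYC": 0.7,
  "k_CDm": 1.0,
  "k_CDs": 0.3,
  "d_CD": 1.5,
  "k_E2Fm": 0.3,
  "k_auto": 2.0,
  "k_tl": 2.0,
  "d_E2Fm": 1.0,
  "d_E2Fp": 1.0,
  "k_Adeg": 0.05,
  "k_RB": 0.18,
  "d_RB": 0.06,
  "k_phD": 5.0,
  "K_phD": 0.3,
  "k_phE": 30.0,
  "K_phE": 0.3,
  "k_deph": 0.3,
  "d_RP": 0.5,
  "k_CE": 1.5,
  "d_CE": 1.0,
  "k_A": 0.1,
  "d_A": 0.1,
  "k_X": 0.2,
  "K_XM": 10.0,
  "d_X": 0.1,
  "K_S": 2.0,
  "K_M": 1.0,
  "K_P": 2.0,
  "K_RB": 0.1,
  "K_X": 0.5
 },
 "reference_values": {
  "P_24h_at_10pct_serum": 2.1858686668368796,
  "note": "E2F protein (uM) 24 h after a step to 10% serum from the quiescent state; integrated at rtol 1e-10, atol 1e-12."
 }
}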