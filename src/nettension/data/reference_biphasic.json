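{
 "description": "Reference biphasic parameter set (base variant), selected from an adaptive-walk biphasic archive for a well-interior dose-response peak at physiological concentrations.",
 "params": {
  "ke_MYC": 0.40994268,
  "d_MYC": 0.116845471,
  "k_CDm": 0.0499513205,
  "k_CDs": 0.553760402,
  "d_CD": 29.55364,
  "k_E2Fm": 30.0,
  "k_auto": 0.12348189,
  "k_tl": 20.275643,
  "d_E2Fm": 0.0382367708,
  "d_E2Fp": 21.4936251,
  "k_Adeg": 0.305945138,
  "k_RB": 0.0618654608,
  "d_RB": 0.00256893993,
  "k_phD": 1.19024616,
  "K_phD": 0.00738473842,
  "k_phE": 108.07975,
  "K_phE": 0.003,
  "k_deph": 0.0279555816,
  "d_RP": 0.0230855952,
  "k_CE": 0.465147453,
  "d_CE": 47.3596327,
  "k_A": 0.0140277419,
  "d_A": 2.71466586,
  "k_X": 0.886882986,
  "K_XM": 196.445673,
  "d_X": 0.0148901658,
  "K_S": 2.56665646,
  "K_M": 1.23696268,
  "K_P": 0.038597388,
  "K_RB": 0.0104443081,
  "K_X": 15.9371647
 }
}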