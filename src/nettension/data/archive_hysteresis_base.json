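{
  "task": "hysteresis",
  "variant": "base",
  "param_names": [
    "ke_MYC",
    "d_MYC",
    "k_CDm",
    "k_CDs",
    "d_CD",
    "k_E2Fm",
    "k_auto",
    "k_tl",
    "d_E2Fm",
    "d_E2Fp",
    "k_Adeg",
    "k_RB",
    "d_RB",
    "k_phD",
    "K_phD",
    "k_phE",
    "K_phE",
    "k_deph",
    "d_RP",
    "k_CE",
    "d_CE",
    "k_A",
    "d_A",
    "k_X",
    "K_XM",
    "d_X",
    "K_S",
    "K_M",
    "K_P",
    "K_RB",
    "K_X"
  ],
  "n_iterations": 100,
  "meta": {
    "seed": 2024,
    "stall_limit": 100,
    "mode": "product",
    "warm_start": null,
    "n_stalled": 17
  },
  "version": "0.1.0"
}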