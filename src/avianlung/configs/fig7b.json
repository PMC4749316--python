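{
  "P_atm": 1033.6,
  "R_trachea": 1.0,
  "R_EPPB": 8.0,
  "R_P": 2.5,
  "R1_insp": 3.0,
  "R2_exp": 3.0,
  "R2_insp": 3.0,
  "R1_exp": 60.0,
  "gamma": 1.0,
  "C_tot": 450.0,
  "V1_res": 105.6,
  "V2_res": 103.6,
  "P_c": 1033.6,
  "P_amp": 0.5,
  "T": 3.0
}
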