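# Parameter set 3 (calibrated; see docs/methods.md)
plasticity:
  tau_T: 10.0
  theta_u_T: -60.0
  m_T: 1.7
  tau_N_alpha: 10.0
  tau_N_beta: 150.0
  theta_u_N: -31.0
  m_N_alpha: 2.0
  m_N_beta: 10.0
  theta_N: 0.75
  tau_Z_a: 1.0
  tau_Z_b: 15.0
  m_Z: 6.0
  tau_G_a: 2.0
  tau_G_b: 50.0
  m_G: 10.0
  theta_u_C: -72.0
  theta_C_minus: 15.0
  theta_C_plus: 35.0
  m_K_alpha: 1.5
  tau_K_beta: 15.0
  m_K_beta: 1.7
  s_K_beta: 10.0
  tau_K_gamma: 20.0
  a_pre_ltd: 0.00214
  a_pre_ltp: 0.01348
  a_post_ltd: 0.01832
  a_post_ltp: 0.362
  eta: 0.025
  w_pre_init: 0.5
  w_post_init: 2.0
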