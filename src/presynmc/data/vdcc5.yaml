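# Voltage-dependent calcium channel (P/Q-type), five-state chain
# C0 <-> C1 <-> C2 <-> C3 <-> O.
#
# Forward (alpha) rates grow with depolarization, backward (beta) rates grow
# with repolarization:
#   alpha_i(V) = alpha0_i * exp(+V / v_alpha_i)
#   beta_i(V)  = beta0_i  * exp(-V / v_beta_i)
# alpha0/beta0 in 1/s, v_* in mV.
#
# Source: Bischofberger & Jonas (2002) calyx-type VDCC gating model, as used
# in the MCell presynaptic reconstructions of Nadkarni et al. (2010) and
# Bartol et al. (2015).
version: 1
scheme: vdcc5
steps:
  - {alpha0: 4040.0,  v_alpha: 49.14, beta0: 2880.0, v_beta: 49.14}
  - {alpha0: 6700.0,  v_alpha: 42.08, beta0: 6300.0, v_beta: 42.08}
  - {alpha0: 4390.0,  v_alpha: 55.31, beta0: 8160.0, v_beta: 55.31}
  - {alpha0: 17330.0, v_alpha: 26.55, beta0: 1840.0, v_beta: 26.55}
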