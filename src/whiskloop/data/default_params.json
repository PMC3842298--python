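{
 "plant": {
  "dt_ms": 0.5,
  "theta_rest_deg": 70.0,
  "inertia": 6.0,
  "damping": 9.5,
  "stiffness": 1.0,
  "eps_contact_deg": 2.0,
  "rest_theta_tol_deg": 0.5,
  "rest_omega_tol": 0.005
 },
 "cpg": {
  "Int": {
   "phase_start_ms": 31.0,
   "cycle_duration_ms": 5.0,
   "cycles_num": 10,
   "silence_duration_ms": 100.0
  },
  "ExtP": {
   "phase_start_ms": 0.0,
   "cycle_duration_ms": 5.0,
   "cycles_num": 8,
   "silence_duration_ms": 110.0
  },
  "ExtR": {
   "phase_start_ms": 95.0,
   "cycle_duration_ms": 5.0,
   "cycles_num": 11,
   "silence_duration_ms": 95.0
  }
 },
 "neuron": {
  "SN2": {
   "threshold": 1.0,
   "rrp_threshold": 1.5,
   "t_relay_ms": 1.0,
   "arp_ms": 2.0,
   "rrp_ms": 4.0,
   "tau_accum_ms": 10.0
  },
  "MN": {
   "threshold": 1.0,
   "rrp_threshold": 2.0,
   "t_relay_ms": 1.0,
   "arp_ms": 3.0,
   "rrp_ms": 15.0,
   "tau_accum_ms": 10.0
  }
 },
 "population": {
  "sn1_per_whisker": {
   "D": 28,
   "W": 73,
   "C": 33,
   "P": 28
  },
  "sn2_pool": 10,
  "mn_pool": 10,
  "sn2_fan_in_fraction": 0.5
 },
 "muscle": {
  "intrinsic": {
   "dca_volley": 1.0,
   "tau_ca_ms": 15.0,
   "ca0": 0.7,
   "ca_sat": 0.25,
   "ca_max": 4.0,
   "a_max": 12.1,
   "tau_act_ms": 23.0,
   "tau_deact_ms": 4.0,
   "trigger_frac": 0.7,
   "hold_ms": 5.2,
   "share_caudal": 0.75,
   "share_rostral": 0.25
  },
  "pseudo_intrinsic": {
   "dca_volley": 1.0,
   "tau_ca_ms": 15.0,
   "ca0": 0.7,
   "ca_sat": 0.25,
   "ca_max": 4.0,
   "a_max": 12.1,
   "tau_act_ms": 23.0,
   "tau_deact_ms": 4.0,
   "trigger_frac": 0.7,
   "hold_ms": 5.2
  },
  "extP_superficial": {
   "dca_volley": 1.0,
   "tau_ca_ms": 10.0,
   "ca0": 0.6,
   "ca_sat": 0.5,
   "ca_max": 2.5,
   "a_max": 4.5,
   "tau_act_ms": 6.0,
   "tau_deact_ms": 14.0,
   "trigger_frac": 0.7,
   "hold_ms": 6.5
  },
  "extR_superficial": {
   "dca_volley": 2.2,
   "tau_ca_ms": 12.0,
   "ca0": 0.6,
   "ca_sat": 0.3,
   "ca_max": 2.0,
   "a_max": 5.6,
   "tau_act_ms": 2.5,
   "tau_deact_ms": 6.0,
   "trigger_frac": 0.7,
   "hold_ms": 10.0
  },
  "extR_deep": {
   "dca_volley": 2.2,
   "tau_ca_ms": 12.0,
   "ca0": 0.6,
   "ca_sat": 0.3,
   "ca_max": 2.0,
   "a_max": 1.6,
   "tau_act_ms": 2.5,
   "tau_deact_ms": 6.0,
   "trigger_frac": 0.7,
   "hold_ms": 10.0
  }
 },
 "sensory": {
  "p_period_ms": 6.0,
  "pressure_latency_slope_ms": 19.0,
  "pressure_latency_intercept_ms": 4.5,
  "w_period_mean_ms": 10.0,
  "w_period_jitter_ms": 1.0,
  "sn1_relay_ms": 1.0
 },
 "synapses": {
  "sn1_to_sn2_volley_gain": 2.2,
  "cpg_to_mn": {
   "CPG_ONLY": 2.4,
   "CPG_PLUS_SENSORY": 0.7,
   "SENSORY_ONLY": 0.0
  },
  "sn2w_to_mn": {
   "CPG_ONLY": 0.0,
   "CPG_PLUS_SENSORY": 0.056,
   "SENSORY_ONLY": 0.12
  },
  "mn_threshold": {
   "CPG_ONLY": [
    1.0,
    2.0
   ],
   "CPG_PLUS_SENSORY": [
    1.0,
    1.3
   ],
   "SENSORY_ONLY": [
    1.0,
    2.0
   ]
  },
  "sn2p_to_extr_mn": 0.15,
  "sn2c_to_extr_mn": 0.06,
  "sn2p_inhib_weight": 3.0,
  "sn2c_inhib_weight": 0.2,
  "veto_direct_ms": 8.0,
  "veto_indirect_ms": 25.0
 },
 "init_kick": {
  "volleys": 2,
  "interval_ms": 5.0,
  "weight": 2.4
 }
}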