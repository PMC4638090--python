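# Default three-arm trial design, calibrated to the reported operating
# characteristics of the multicenter ICU enteral-nutrition study the
# pipeline analyzes (arm glucose means/SDs, exposure-time distributions,
# per-exposure infection hazards, mortality).  These are CALIBRATION
# TARGETS for the synthetic generator, not mechanistic ground truth: real
# arm differences arise from formula composition in vivo, the simulator
# encodes them directly as variability/set-point parameters.
#
# Arms: A = new-generation diabetes-specific high-protein formula,
#       B = standard high-protein formula, C = control diabetes-specific.
n_centers: 9
block_size: 6
horizon_days: 28
sampling_interval_h: [1.0, 4.0]      # uniform, capillary checks
interruption_days: [3, 7, 14, 21, 28]
interruption_len_h: 8.0
protocol:
  max_rate: 2.0   # the consensus scale as operated was gentle
arms:
  A:
    n_patients: 52
    setpoint_mgdl: 155.0             # latent operating level before insulin
    between_sd_mgdl: 18.0            # patient-to-patient set-point spread
    within_sd_mgdl: 40.0             # stationary within-patient fluctuation
    reversion_per_h: 0.25            # mean-reversion rate of the latent process
    noise_sd_mgdl: 5.0               # glucometer measurement noise
    insulin_sensitivity: 6.0         # mg/dL steady-state drop per IU/h
    hazard_tracheobronchitis_per_1000vd: 15.2
    hazard_vap_per_1000vd: 17.4
    hazard_catheter_bsi_per_100icud: 0.15
    hazard_primary_bsi_per_100icud: 0.40
    hazard_uti_per_100icud: 0.13
    vent_days_lognorm: [1.9459, 0.80]   # [mu, sigma]; median 7 d
    icu_days_lognorm: [2.5649, 0.60]    # median 13 d
    en_days_lognorm: [2.1972, 0.60]     # median 9 d  (mean ~10.8)
    mortality_28d: 0.211
    mortality_6mo: 0.307
  B:
    n_patients: 53
    setpoint_mgdl: 162.0
    between_sd_mgdl: 20.0
    within_sd_mgdl: 60.0
    reversion_per_h: 0.25
    noise_sd_mgdl: 5.0
    insulin_sensitivity: 6.0
    hazard_tracheobronchitis_per_1000vd: 25.5
    hazard_vap_per_1000vd: 25.5
    hazard_catheter_bsi_per_100icud: 0.15
    hazard_primary_bsi_per_100icud: 0.15
    hazard_uti_per_100icud: 0.13
    vent_days_lognorm: [1.7918, 0.85]   # median 6 d
    icu_days_lognorm: [2.4849, 0.75]    # median 12 d
    en_days_lognorm: [2.0149, 0.60]     # median 7.5 d (mean ~9.0)
    mortality_28d: 0.189
    mortality_6mo: 0.377
  C:
    n_patients: 52
    setpoint_mgdl: 157.0
    between_sd_mgdl: 12.0
    within_sd_mgdl: 40.0
    reversion_per_h: 0.25
    noise_sd_mgdl: 5.0
    insulin_sensitivity: 6.0
    hazard_tracheobronchitis_per_1000vd: 16.5
    hazard_vap_per_1000vd: 14.2
    hazard_catheter_bsi_per_100icud: 0.30
    hazard_primary_bsi_per_100icud: 0.40
    hazard_uti_per_100icud: 0.13
    vent_days_lognorm: [1.7918, 0.85]   # median 6 d
    icu_days_lognorm: [2.4423, 0.65]    # median 11.5 d
    en_days_lognorm: [2.1163, 0.60]     # median 8.3 d (mean ~9.9)
    mortality_28d: 0.250
    mortality_6mo: 0.346
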