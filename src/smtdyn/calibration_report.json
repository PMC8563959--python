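{
  "params": {
    "c_bottom_steady_mm": 1719.1,
    "k_aom_mm_yr": 33.677,
    "c_bottom_weak_mm": 400.0,
    "c_step_increasing_mm": 400.0,
    "z_front_increasing_m": 4.3,
    "front_rise_m_yr": 0.10625,
    "c_step_transitional_mm": 16.55,
    "z_front_transitional_m": 4.5,
    "porosity": 0.7,
    "dz_m": 0.01
  },
  "targets": [
    {
      "target": "steady_smt_m",
      "value": 1.0,
      "achieved": 0.9994808948291325,
      "rel_error": -0.0005191051708675065,
      "calibrated": true
    },
    {
      "target": "steady_peak_nmol_cm3_d",
      "value": 10.0,
      "achieved": 10.015990602263543,
      "rel_error": 0.0015990602263542542,
      "calibrated": true
    },
    {
      "target": "steady_flux_mol_m2_yr",
      "value": 1.3,
      "achieved": 0.22147976149245271,
      "rel_error": -0.8296309526981134,
      "calibrated": false
    },
    {
      "target": "steady_late_shoal_cm_yr",
      "value": 0.007,
      "achieved": 0.0037731639427906268,
      "rel_error": -0.46097657960133903,
      "calibrated": false
    },
    {
      "target": "increasing_shoal_cm_yr",
      "value": 10.0,
      "achieved": 9.993200291877754,
      "rel_error": -0.0006799708122246173,
      "calibrated": true
    },
    {
      "target": "increasing_peak_nmol_cm3_d",
      "value": 200.0,
      "achieved": 118.67126300437839,
      "rel_error": -0.40664368497810804,
      "calibrated": false
    },
    {
      "target": "transitional_shoal_cm_yr",
      "value": 0.4,
      "achieved": 0.40013337964325,
      "rel_error": 0.0003334491081249946,
      "calibrated": true
    }
  ],
  "protocol": {
    "t_spinup_yr": 40000.0,
    "steady_window_yr": [
      30000.0,
      40000.0
    ],
    "increasing_post_yr": 25.0,
    "increasing_window_yr": [
      15.0,
      25.0
    ],
    "transitional_post_yr": 150.0,
    "transitional_window_yr": [
      50.0,
      150.0
    ]
  }
}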