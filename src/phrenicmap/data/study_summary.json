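{
  "_note": "Published summary statistics of the reference clinical pace-mapping cohort (45 patients, 1033 endocardial pacing sites; capture-threshold category vs shortest 3D distance to the CT-delineated right phrenic nerve). These printed values are the calibration targets and the comparison baseline for the reproduction pipeline.",
  "n_patients": 45,
  "n_sites": 1033,
  "sites_per_patient_mean": 23,
  "sites_per_patient_sd": 16.4,
  "n_la_sites": 872,
  "n_svc_ra_sites": 161,
  "n_capture_sites": 725,
  "n_la_sites_within_3mm": 34,
  "n_la_sites_within_10mm": 302,
  "categories": [
    {"label": "<=10 mA", "n": 74, "mean_mm": 7.5, "sd_mm": 3.0, "min_mm": 1.0},
    {"label": ">10-<=20 mA", "n": 319, "mean_mm": 8.6, "sd_mm": 4.5, "min_mm": 2.0},
    {"label": ">20-<=30 mA", "n": 135, "mean_mm": 11.5, "sd_mm": 3.7, "min_mm": 4.1},
    {"label": ">30-<=50 mA", "n": 197, "mean_mm": 16.5, "sd_mm": 4.5, "min_mm": 5.7},
    {"label": "non-capture at 50 mA", "n": 308, "mean_mm": 19.2, "sd_mm": 6.5, "min_mm": 9.4}
  ],
  "distance_cutoff_mm": 10.0,
  "auc": 0.846,
  "auc_ci": [0.821, 0.870],
  "spearman_rho": 0.692,
  "table2": {
    ">10 mA": {"sensitivity": 0.968, "specificity": 0.150},
    ">20 mA": {"sensitivity": 0.808, "specificity": 0.775},
    ">30 mA": {"sensitivity": 0.680, "specificity": 0.916},
    ">50 mA (no capture)": {"sensitivity": 0.424, "specificity": 0.976}
  }
}
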