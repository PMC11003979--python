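# Synthetic study calibration: F98 rat spinal-cord-glioma BNCT experiment.
# Group survival parameters, organ boron anchors and uptake means/SDs are
# the published group-level summaries of the study this package models.
seed: 17
model: F98

groups:
  - {label: untreated, n: 8, survival_mean_days: 14.8, survival_sd_days: 1.1}
  - {label: neutron-only, n: 6, survival_mean_days: 15.5, survival_sd_days: 0.5}
  - {label: BNCT, n: 8, survival_mean_days: 32.5, survival_sd_days: 2.6}
  - {label: sham-untreated, n: 4, horizon_days: 37}
  - {label: sham-neutron-only, n: 4, horizon_days: 37}
  - {label: sham-BNCT, n: 4, horizon_days: 37}
  - {label: normal, n: 3, horizon_days: 37}

uptake:
  - {cell_line: F98, exposure_conc: 5, mean: 19.0, sd: 3.2, replicates: 3}
  - {cell_line: F98, exposure_conc: 10, mean: 42.3, sd: 2.6, replicates: 3}
  - {cell_line: F98, exposure_conc: 20, mean: 61.0, sd: 2.9, replicates: 3}
  - {cell_line: 9L, exposure_conc: 5, mean: 21.0, sd: 1.3, replicates: 3}
  - {cell_line: 9L, exposure_conc: 10, mean: 33.1, sd: 1.6, replicates: 3}
  - {cell_line: 9L, exposure_conc: 20, mean: 45.0, sd: 4.5, replicates: 3}

organs:
  - {tissue: tumor, conc_at_2p5h: 26.6, conc_at_24h: 3.0, cv: 0.22}
  - {tissue: spinal cord, conc_at_2p5h: 5.3, conc_at_24h: 0.8, cv: 0.25}
  - {tissue: brain, conc_at_2p5h: 5.5, conc_at_24h: 1.1, cv: 0.09}
  - {tissue: blood, conc_at_2p5h: 6.7, conc_at_24h: 1.1, cv: 0.10}

times_h: [2.5, 6, 24]
n_per_time: {2.5: 8, 6: 4, 24: 4}

bbb: {plateau: 21, decline_onset_frac: 0.5, euthanasia_threshold: 5}

pipeline:
  reference_group: untreated
  irradiation_start_day: 7
  dosimetry:
    neutron_field:
      flux: 9.4e8          # n/cm^2/s at the irradiation position
      duration_s: 1200     # 20 min
      d_h: 0.28            # measured hydrogen-recoil dose, Gy
      d_gamma: 0.65        # measured photon dose, Gy
    nitrogen_wt_pct: 3.5
    weights: {cbe_tumor: 3.8, cbe_normal: 1.35, rbe_n: 3.0, rbe_h: 3.0}
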