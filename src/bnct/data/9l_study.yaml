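# Synthetic study calibration: 9L rat gliosarcoma spinal-cord model.
# Only the in vitro uptake and in vivo biodistribution arms were carried
# through for this model; the survival groups are the untreated
# implantation cohorts.
seed: 17
model: 9L

groups:
  - {label: untreated, n: 7, survival_mean_days: 19.6, survival_sd_days: 1.6}
  - {label: untreated-high-burden, n: 13, survival_mean_days: 10.2, survival_sd_days: 1.0}

uptake:
  - {cell_line: 9L, exposure_conc: 5, mean: 21.0, sd: 1.3, replicates: 3}
  - {cell_line: 9L, exposure_conc: 10, mean: 33.1, sd: 1.6, replicates: 3}
  - {cell_line: 9L, exposure_conc: 20, mean: 45.0, sd: 4.5, replicates: 3}

organs:
  - {tissue: tumor, conc_at_2p5h: 15.3, conc_at_24h: 6.0, cv: 0.29}
  - {tissue: spinal cord, conc_at_2p5h: 4.2, conc_at_24h: 2.0, cv: 0.14}
  - {tissue: brain, conc_at_2p5h: 5.0, conc_at_24h: 1.8, cv: 0.14}
  - {tissue: blood, conc_at_2p5h: 5.9, conc_at_24h: 1.9, cv: 0.08}

times_h: [2.5, 6, 24]
n_per_time: {2.5: 6, 6: 5, 24: 4}

bbb: {plateau: 21, decline_onset_frac: 0.5, euthanasia_threshold: 5}

pipeline:
  reference_group: untreated
  irradiation_start_day: 0
  dosimetry:
    neutron_field:
      flux: 9.4e8
      duration_s: 1200
      d_h: 0.28
      d_gamma: 0.65
    nitrogen_wt_pct: 3.5
    weights: {cbe_tumor: 3.8, cbe_normal: 1.35, rbe_n: 3.0, rbe_h: 3.0}
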