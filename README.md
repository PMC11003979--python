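# bnct

Analysis toolkit for preclinical boron neutron capture therapy (BNCT)
studies in the rat spinal-cord-glioma setting: mixed-field dosimetry with
CBE/RBE photon-equivalent weighting, boron biodistribution and cellular
uptake analysis with irradiation-time selection, and survival + locomotor
efficacy statistics — plus a calibrated synthetic-study generator so the
whole pipeline can be exercised end-to-end without animal data.

## Who this is for

Radiobiologists and biostatisticians analysing small-animal BNCT
experiments: ICP-AES boron measurements of cell lysates and organ samples,
neutron irradiation cohorts scored for survival and hind-limb locomotion
(Basso–Beattie–Bresnahan scale), and the dose bookkeeping that connects
them.

## The model

The absorbed dose of a thermal-neutron irradiation decomposes as

    D = D_B + D_N + D_H + D_γ

with the boron and nitrogen capture terms linear in thermal fluence Φ
(n/cm²) through kerma coefficients,

    D_B = 7.43×10⁻¹⁴ Gy·cm²/(μg ¹⁰B/g) × c_B × Φ
    D_N = 6.78×10⁻¹⁴ Gy·cm²/wt% × w_N × Φ,

while the hydrogen-recoil and photon terms D_H, D_γ are measured
per-irradiation calibration inputs. The photon-equivalent dose weights
each term by its biological effectiveness relative to photons:

    D_eq = D_B·CBE + D_N·RBE_N + D_H·RBE_H + D_γ

with CBE = 3.8 (BPA in spinal-cord tumour), 1.35 (normal spinal cord) and
RBE_N = RBE_H = 3.0. When only total absorbed doses are tabulated, D_B is
recovered by subtracting the boron-free ("neutron only") background.

Efficacy uses the Kaplan–Meier product-limit estimator, two-group log-rank
tests, and the percent increase in life span on group medians,

    %ILS = (MST_treated − MST_untreated) × 100 / MST_untreated,

with BBB locomotor trajectories compared by one-way MANOVA (Wilks' Λ) on
the per-day score vectors, dead animals scoring 0.

## Worked example

Generate the packaged F98 spinal-cord-glioma study calibration and run
every stage:

```
bnct all --config f98_study --seed 7 --outdir out/
```

`out/table3.tsv` (survival analysis of the synthetic irradiation cohort):

```
group	n	mean	sd	median	ci_lo	ci_hi	pct_ILS	p_vs_reference
untreated	8	14.9	1.0	15.0	14.0	16.0	-	-
BNCT	8	31.5	3.3	31.0	27.0	34.0	106.7	< 0.0001
neutron-only	6	15.5	0.5	16.0	15.0	16.0	6.7	0.3452
...
```

The boron-treated irradiation group roughly doubles median survival over
the untreated cohort (%ILS ≈ 107 here; the cohort is only n = 8 per group,
so the point estimate scatters around the calibrated 116.7), the log-rank
test rejects decisively, and neutron irradiation alone adds nothing
significant. `out/table2.tsv` holds the organ boron time course with
tumour-to-normal ratios (T/SC ≈ 5, T/Bl ≈ 4 at 2.5 h), `out/irradiation_time.txt`
the selected irradiation time (2.5 h), `out/table4.tsv` the dose
decomposition, and `out/km_curves.csv` / `out/bbb_group_means.csv` the
survival-curve points and locomotor group means.

The same analyses are available as library functions
(`bnct.dosimetry`, `bnct.biodistribution`, `bnct.efficacy`) and as
per-stage subcommands (`bnct synth | uptake | biodist | dose | efficacy`).

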