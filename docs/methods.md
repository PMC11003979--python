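# Methods

## Dose model

The absorbed dose of a thermal-neutron irradiation is modelled as the sum
of four components. The boron and nitrogen capture terms are kerma-based
and exactly linear in both concentration and thermal fluence:
D_B = 7.43×10⁻¹⁴ Gy·cm² per (μg ¹⁰B/g) and D_N = 6.78×10⁻¹⁴ Gy·cm² per
weight-% nitrogen, each multiplied by the thermal-neutron fluence in
n/cm². The hydrogen-recoil term D_H (elastic scattering of epithermal and
fast neutrons on ¹H) and the photon term D_γ depend on the beam spectrum
and photon contamination, which a fluence-only model cannot predict; they
are therefore *measured inputs*, supplied per irradiation in the config,
never computed. Photon-equivalent weighting multiplies D_B by the
compound biological effectiveness (CBE; defaults 3.8 for spinal-cord
tumour and 1.35 for normal cord with BPA) and D_N, D_H by RBE = 3.0; D_γ
carries weight exactly 1.

Two deliberate modelling decisions:

* **Fluence is always explicit.** The nominal free-field fluence of the
  reference irradiation (9.4×10⁸ n/cm²/s × 1200 s = 1.128×10¹² n/cm²)
  underestimates the boron doses implied by the published dose table
  (back-solving gives ≈ 2.3–2.5×10¹² n/cm² thermal fluence at the target);
  the thermal component at depth was evidently larger than the quoted
  free-field figure and was not reported. The module therefore never
  equates total flux × time with thermal fluence silently — callers pass
  the fluence they mean.
* **Background subtraction.** Published tables report only totals, so
  `equivalent_via_background` recovers D_B as (boron-loaded total −
  boron-free background) and adds the CBE-weighted result to the
  background photon-equivalent dose. Reconstructed values agree with the
  tabulated photon-equivalent doses within 0.3 Gy-Eq, the rounding slack
  of inputs printed at one decimal.
* **Nitrogen content** defaults to 3.5 weight %, a standard soft-tissue
  figure, configurable per tissue — the kerma coefficient is published
  but the tissue nitrogen fraction is not.

Report rendering rounds half-up to one decimal (matching typeset tables);
all internal computation is full precision.

## Biodistribution and uptake

Cellular uptake is normalised to μg ¹⁰B per 10⁹ cells from the lysate
boron mass and cell count. Level and cell-line comparisons use two-sided
two-sample t-tests — pooled-variance Student's t by default (the studies
this emulates use equal n = 3 designs), Welch by flag. Washout
(retention-arm) records are summarised but excluded from comparisons.

Organ measurements are summarised per (tissue, time) as arithmetic mean
and n−1 SD. Ratios T/SC, T/Bl, Bl/SC are computed from raw means; a
"table mode" reproduces printed tables by rounding means half-up to one
decimal before dividing and rounding again. A small number of printed
ratio cells cannot be recovered this way because they were computed from
unrounded source data; `compare_printed_ratios` flags these as
reconstruction mismatches rather than failing.

Irradiation-time selection formalises the stated decision inputs as a
lexicographic maximisation: absolute tumour boron first, then T/SC, then
T/Bl, ties broken by the earliest time. On the published time courses of
both tumour models this selects 2.5 h.

## Survival and locomotion

Kaplan–Meier estimation, the two-group log-rank test and median-CI
construction delegate to `lifelines`. The median is the smallest t with
S(t) ≤ 0.5; for an even, fully observed split this is the
second-smallest central time, not the midpoint interpolation some
commercial packages print (the difference is at most one inter-event gap
and is immaterial at the tolerances used here). The 95% CI inverts the
pointwise confidence band of S(t) at 0.5 (Brookmeyer–Crowley, log
transform) — the standard small-cohort choice; printed CIs from other
software are not expected to match exactly. %ILS is computed on medians
and rounded half-up to one decimal for reporting. p-values below 10⁻⁴
are rendered "< 0.0001", full precision retained internally.

BBB trajectories are aligned on a common day grid starting at the
irradiation day; an animal that died or was euthanised (endpoint: death
or BBB ≤ 5) scores 0 on every later day. Group comparison is a one-way
MANOVA on the per-day score vectors, Wilks' Λ with Rao's F. Days without
within-group variance carry no error information and are dropped; if the
remaining grid exceeds what the error degrees of freedom support — or the
error matrix is rank-deficient because trajectories are highly collinear —
the grid is thinned evenly until the error matrix is invertible, and the
result is flagged. Two degenerate cases statsmodels cannot form are
computed exactly from the H/E cross-product matrices: a single response
day (Wilks reduces to the one-way ANOVA F) and identical group means
(Λ = 1, F = 0, p = 1).

## Synthetic-study generator

The generator's defaults are the published group-level summaries of the
rat spinal-cord-glioma study it emulates (`bnct.reference`,
`bnct/data/f98_study.yaml`, `9l_study.yaml`); individual-animal data were
never published, so the generative forms are the simplest families
matching those summaries:

* **Survival**: Normal(mean, SD) rounded to whole days, floored at 1, all
  events observed — the simplest family matching both the printed mean and
  SD at these scales. Sham-operated and normal groups survive to the
  37-day observation horizon, censored.
* **Organ clearance**: mono-exponential, mean(t) = c(2.5 h)·exp(−k(t−2.5)),
  with k fitted through the 2.5 h and 24 h anchors and a constant CV
  across animals, truncated at zero. Three sampled times cannot identify
  a two-compartment model. Note the consequence: the interpolated 6 h
  mean for the F98 tumour (≈18.6 μg/g) sits above the published 6 h mean
  (16.3), so the generator reproduces its calibration anchors, not every
  intermediate printed value.
* **BBB trajectories**: plateau at 21 until a configurable onset fraction
  (default 0.5) of the survival time, then a linear integer decline
  reaching the euthanasia threshold (5) on the death day. The only
  contracts are monotone non-increase after onset and endpoint
  consistency; real locomotor decline is noisier and can plateau
  mid-scale. Trajectories are deterministic given the survival draw, so
  within-group BBB variance comes entirely from survival-time variation —
  adequate for exercising the group comparison, but flatter than real
  repeated-measures noise.

Randomness: one master seed, with each generator drawing from a named
sub-stream (SeedSequence of the seed and a CRC32 of the stream name), so
adding a generator never perturbs existing outputs and identical seeds
reproduce datasets byte-for-byte.

What passing the recovery checks shows: at n = 500/group the calibrated
medians are recovered within a day, log-rank separation between the
treated and untreated calibrations is essentially certain, and organ
means match the clearance model within sampling error. It does not show
that real cohorts of n = 8 would yield the published p-values or CIs —
those depend on unpublished individual data.

## Pipeline

Stages run in study order (uptake → biodistribution → timing → dosimetry
→ efficacy), fail loudly with the stage name, and write TSV/CSV reports
plus a JSON manifest (package version, config hash, input SHA-256s,
per-stage status). All report numbers are deterministic functions of the
inputs and seed; the manifest's timestamps are the only non-reproducible
bytes. Default problem sizes (the packaged study: 37 animals, 18 uptake
records, 64 organ measurements; recovery checks at n = 500 and 200
log-rank replicates) keep a full run and the whole test suite under a
minute on one core.

## Known limitations

* No neutron/photon transport: fluence at depth, beam spectra and
  shielding are out of scope; D_H and D_γ must come from calibration.
* No dose→survival link: group survival parameters are free inputs; the
  generator cannot predict efficacy from dose.
* CI and median conventions may differ from commercial statistics
  packages at the second decimal; comparisons should use the documented
  definitions above.
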