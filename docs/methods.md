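# Methods

## The measurement model

### Transwell mass balance and apparent permeability

A filter insert with growth area *A* (default 1.13 cm²) separates an apical
donor compartment (*V_D* = 0.5 ml) dosed with radiotracer from a basal
receiver well (*V_R* = 1.5 ml). Passive flux follows the two-compartment
balance

    dA_R/dt =  Papp·A·(C_D − C_R),   dA_D/dt = −Papp·A·(C_D − C_R)

with amounts in dpm and concentrations *C* = *A*/*V*. The insert is moved to
a fresh receiver well at each scheduled time (default 5, 15, 30 min), so the
receiver restarts tracer-free while the donor carries over. Within one
interval the ODE is linear and the simulator uses its closed form

    A_R(t) = T · V_R/(V_D+V_R) · (1 − e^(−PS·(1/V_D+1/V_R)·t)),

*T* being the donor amount entering the interval; this is exact to machine
precision (validated against fine-step `solve_ivp` integration to 1×10⁻⁶
relative; in-interval mass conservation holds to 1×10⁻⁹).

The analysis inverts the sink approximation of the same model: interval
cleared volume `max(M_R − background, 0)/C_D`, cumulative volumes regressed
on time by OLS with a free intercept (the intercept absorbs dead volume; a
through-origin mode exists), slope in μl/min converted to the PS product in
cm³/s, and `Papp = PS/A`.

**Donor-concentration convention.** The bench protocol measures the donor
only at the end of the run, so the generator reports the end-of-run donor
concentration and the analysis uses the measured *C_D* as given. This
matters at the level of accuracy we validate: at a sucrose-scale Papp the
donor loses ≈2.4% of its tracer over 30 min, which alone would bias the
fitted slope −1.65%; dividing by the slightly depleted end-of-run *C_D*
cancels most of it, leaving +0.8%. A `donor_sampling="start"` option
reports the t = 0 concentration instead for sensitivity analyses. The
noiseless recovery tolerance of 1% in the tests reflects the end-sampling
convention; it is not achievable with start-sampling at this Papp and
schedule.

### Counting statistics

Scintillation counts are Poisson on a fixed counting window (default 1 min,
so dpm and counts coincide numerically). Counting efficiency multiplies
true dpm and instrument background adds before counting; both cancel in
every downstream ratio provided they are applied consistently, which the
round-trip tests check. The window and the donor-aliquot volume (100 μl)
are modelling choices exposed as parameters, since source protocols rarely
report them. Inter-insert permeability variability is lognormal with a
mean-preserving parameterisation (σ² = ln(1+CV²)), keeping Papp positive
and the batch mean unbiased.

### TEER

`TEER = (R_raw − R_blank)·A`. Negative corrected values are flagged
degenerate, never clamped — they indicate a measurement problem worth
seeing. The QC gate is strict on both sides (`TEER > 500 Ω·cm²`,
`Papp < 8×10⁻⁶ cm/s`); boundary values fail. The generator draws TEER from
a normal distribution truncated at zero (equivalently raw ≥ blank); at the
batch conditions used here (mean 789, sd 171.7 — the reported SEM of 18 at
n = 91) truncation is a 4.6 σ event and negligible.

### Distribution volumes and the efflux factor

Per channel, `V_d = (dpm_cells − bg) / ((dpm_aliquot − bg)/V_aliquot)`
normalised per mg protein. Background is a per-plate scalar per channel.
The substrate `V_d` minus the extracellular-marker `V_d` removes
non-specific binding and residual medium; negative corrected values are
flagged, not clamped. The efflux statistic is the ratio of group means
(inhibitor/control); with multiplicative noise at 5% and n = 6 per group
its bias is O(CV²/n) ≈ 0.1%, verified by a 500-seed simulation. Dual-label
spillover between the ³H and ¹⁴C channels is assumed already unmixed by the
counter.

### Relative-standard-curve qPCR

Per gene, OLS of Ct on log₁₀(quantity) over a tenfold dilution ladder
(default 5 points); amplification efficiency `10^(−1/slope) − 1`; technical
replicates aggregated by **mean Ct** before inversion (standard practice;
averaging quantities instead would bias high under Ct noise because the
inversion is convex). Undetected wells propagate as missing with warnings —
no Ct-40 imputation. Plate validity requires the no-template, extraction
and RT negatives undetected or above a configurable Ct floor (default 38).
The 2-fold significance rule is applied symmetrically (≥2 or ≤0.5), with a
1×10⁻⁹ relative tolerance at the boundary so that an exactly-2-fold change
is not lost to float round-off.

A calibration property pins the noise behaviour: with 0.15-Ct replicate
noise, triplicates and 6 samples per group, a programmed 2-fold change is
recovered within [1.7, 2.3] in ≥95% of 500 seeded plates (measured ≈99%).
With a single sample per group the same interval would hold only ~79% of
the time — group replication, not the triplicates, carries the precision.

### Log P screen

The passive line is OLS of Papp on calculated Log P over reference
compounds only (log₁₀-Papp fitting is available for wide dynamic ranges).
`residual_scale` is the residual standard error (ddof = 2); an exact fit is
snapped to zero scale. Classification: residual beyond
`max(k·residual_scale, 0.1·|predicted|)` above the line → carrier-mediated
uptake; below → efflux/active removal; else passive. Defaults `k = 2` and
the 10% floor are explicit configuration, since "clear outlier" is
otherwise a judgement call. Glutamate is classified by sign like every
other compound; its known mixed uptake/efflux biology is an annotation, not
a third class.

## The synthetic-data generators

The generators emulate the *statistical* structure of each assay — mass
balance, counting noise, replicate structure, standard curves, programmed
effect sizes — and are first-class tested code. Defaults are the study
conditions: TEER 789 ± 171.7 Ω·cm² over 91 inserts against a 120 Ω blank;
sucrose Papp 6.07×10⁻⁶ cm/s with the 0.15 μCi/ml, 643 mCi/mmol tracer;
colchicine/sucrose dual labels at 1.0 and 0.045 μCi/ml with a 1.34 efflux
factor over a 20 μl/mg control Vd and 5 μl/mg non-specific space; 5-point
curves, triplicates and a −3.3219 Ct/decade slope for qPCR; four passive
calibrators (sucrose, naloxone, propranolol, diazepam) and six transporter
substrates for the screen. Where the source assays report no value
(protein per well 0.1 mg; aliquot 50 μl; Ct intercept 25; screen line
slope 4×10⁻⁶ cm/s per Log P unit anchored so sucrose sits near its
measured Papp) realistic values were fixed once and documented here.

The default screen generator keeps reference noise at 1×10⁻⁷ cm/s — small
against the classifier's 10%-of-prediction floor — because with only four
reference compounds the fitted residual scale has 2 degrees of freedom and
its upper tail would otherwise blur programmed offsets; the floor is then
the operative margin and programmed ≥3-margin offsets are recovered with
100% accuracy across seeds. Noisy-reference behaviour is exercised
separately with a deterministic four-point fixture whose scatter yields
R² ≈ 0.96. What passing recovery tests shows is that the *arithmetic and
inference* are right under the modelled noise; they cannot certify
biological realism (no cell-to-cell heterogeneity beyond lognormal Papp,
no channel crosstalk, no plate-position effects, no pipetting drift).

## Problem sizes and determinism

Validation suites use 100-insert permeability batches, 91-insert TEER
batches, 200–500-seed replications for coverage/bias properties — sizes at
which every Monte-Carlo margin computed analytically (binomial coverage,
ratio-estimator bias) has comfortable slack, while the whole suite runs in
seconds. Every generator draws from `numpy.random.default_rng(seed)`; one
root seed (plus fixed offsets per stage in the pipeline) reproduces all
outputs byte-identically, which the pipeline test asserts.

## Known limitations

- Apical-to-basal flux only; no efflux-ratio (B→A/A→B) or
  unstirred-water-layer correction.
- `C_D` held constant within the regression; for compounds much more
  permeable than sucrose the ~1% depletion bias grows and a shorter
  schedule or explicit depletion correction would be needed.
- No ³H/¹⁴C spillover deconvolution, no BCA calibration fitting (protein
  mass is an input), no enzyme kinetics for ALP.
- Hypothesis testing (t-test/ANOVA) is intentionally out of scope; the
  pipeline reports descriptive summaries and effect ratios only.
- Calculated Log P values are inputs; no estimator is bundled.
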