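# Methods

This note documents the models behind each pipeline stage, what the
synthetic-data generators do and do not emulate, the numerical choices, and
the known limitations.

## Plate screen

**Model.** Each imaged cell contributes a surface-channel intensity, a
total-channel intensity, and their ratio; wells are summarized by the mean
of each per-cell quantity. The trafficking ratio is deliberately the *mean
of per-cell ratios*, not the ratio of well means — the two differ under
cell-to-cell heterogeneity, and the per-cell form is what a single-cell
imaging assay measures. Cells with zero total signal are dropped from the
ratio mean and tallied.

**Robust z.** Compound wells are scored per plate and metric as
`z = (x − x̃)/(1.4826·m)`, with median x̃ and MAD m taken over the plate's
*compound wells only*. Controls are excluded from the reference: when most
compounds are inactive, sample-based normalization is standard, and control
wells would otherwise bias location and scale. The constant 1.4826 makes
the score agree with a classical z-score under normality, so the null flag
rate at |z| > 3 is ≈ 2·(1−Φ(3)) ≈ 0.27% per metric. A plate whose MAD is
zero on some metric is flagged degenerate: the z-scores are undefined (NaN,
never silently zero) and the plate fails QC.

**Hit rule.** |z| strictly greater than 3 on at least one of the three
metrics, and not toxic. Toxicity is operationalized as cell-count robust
z < −3: the screen's observable for a toxic compound is a depleted well,
not an intensity change. Boundary values (|z| = 3 exactly) are not hits.

**QC.** Z′ is computed on the total-protein metric by default (the largest
assay window between the wild-type and the trafficking-deficient control
line); thresholds default to Z′ ≥ 0.5, negative-control %CV ≤ 20, median
cell count ≥ 50, and an optional focus-score floor. The focus score is
treated as an opaque imager-provided numeric.

## Funnel

Confirmation requires the *same metric to cross the threshold in the same
direction* in ≥ k of n replicates (defaults k = 2, n = 3). The count alone
would let a compound that raises surface signal in one replicate and
lowers it in another "confirm"; direction consistency excludes that.
Missing replicates count as failures — the denominator stays n. The
counter-screen retains a compound only if the unrelated-protein line shows
|z| ≤ 3 on every metric (same threshold and strictness as hit calling, for
symmetry); compounds without counter-screen data are carried forward
explicitly flagged `untested`. Stage accounting enforces monotone counts
and gives every compound exactly one disposition per stage.

## Flow trafficking

**Model.** Two antibodies label the same epitope in two channels: the
surface pool is stained before permeabilization, the internal pool after.
With background-subtracted channel statistics `S_corr` and `I_corr` and a
brightness factor `b` (surface-channel signal per epitope ÷
internal-channel signal per epitope), total protein in surface-channel
units is `S_corr + b·I_corr` and the trafficking efficiency is

    TE = S_corr / (S_corr + b·I_corr)  ∈ [0, 1].

TE is invariant to any common gain and is the natural "surface fraction of
total" statistic. Because the surface antibody occupies surface epitopes
before permeabilization, the internal stain sees only the internal pool —
total is a sum, not a double count.

**Processing order.** Spillover is estimated from single-color controls
(median off-channel over on-channel signal after subtracting the unstained
control's medians); compensation solves `observed = true·S` per event;
gating keeps events whose reporter exceeds the 99th percentile of a
reporter-negative control; per-sample statistics are medians by default
(robust to the log-normal tail; means are available by configuration);
the background-staining control (unexpressing cells stained with both
antibodies) is compensated identically and its statistics subtracted.
The background control is reporter-negative by construction, so it is the
one sample the reporter gate is not applied to. Negative corrected signals
are clipped to zero and counted. `b` comes from configuration or is
calibrated from a fully-permeabilized dual-stain control in which both
antibodies see the same pool, making the median per-event channel ratio an
estimate of `b`. Treated values are expressed as percent of the
same-replicate vehicle, so staining-batch factors cancel.

## Dose-response

Fits run on log10 concentration with a log-parameterized EC50 (positive by
construction), Levenberg–Marquardt from a 3×3 multi-start grid (EC50 at the
quartiles of the tested range; Hill slopes 0.7/1.5/3), optionally with
either asymptote fixed. Flat data raise an explicit "unidentifiable EC50"
error rather than returning an arbitrary fit, as does an EC50 landing more
than two decades outside the tested range. The EC50 CI is a seeded
case-resampling bootstrap (500 draws, percentile interval). A caveat
documented here because it matters when interpreting synthetic-recovery
runs: at 8 log-spaced concentrations (1–100 μM), 4 replicates, and 5%
multiplicative noise, the Cramér–Rao bound puts the EC50 sampling SD at
≈ 2.3–2.6 μM for these curve shapes, so single-dataset EC50 estimates
scatter by a few μM around truth regardless of estimator; the bootstrap
CIs reflect exactly this width.

## Mechanism assays

* **Chase:** `y = 100·e^(−kt)`. The amplitude is fixed at 100 because the
  inputs are percent-remaining values normalized to t = 0; with 3–4
  timepoints a free amplitude would trade off against k. Non-decreasing
  inputs return a flagged zero-rate result (infinite half-life) instead of
  a spurious fit.
* **CETSA:** a two-plateau falling logistic in temperature; T_agg is the
  inflection, constrained to the measured range. Monotone-increasing
  input is rejected as mis-oriented. T_agg is fitted per replicate and
  compared across conditions downstream.
* **qPCR:** classic ΔΔCt with efficiency 2.0 (configurable in (1, 2]);
  technical replicates are averaged on the Ct scale before differencing.
* **Viability:** percent live cells from trypan-blue counts.

## Patch clamp

**Analysis.** Only cells with Rseal ≥ 0.1 GΩ (inclusive) and
Rseries < 10 MΩ (strict) are analyzed; blocker-insensitive cells (whose
subtracted current at +60 mV stays below a 100 pA floor) are excluded.
Nonspecific components are removed by pointwise subtraction of the
after-blocker trace. Peak current is read at the 1,990 ms sample of the
2,000 ms step (nearest sample; a ±window mean is available) and divided by
Cm — normalization happens after subtraction. Tail amplitude is the
extremum within the first 50 ms of the −30 mV segment minus the
post-deactivation baseline (mean of the last quarter of the tail). Each
test potential is corrected as `V_corr = V_cmd − I·Rseries` using the
*pre-blocker total* current at the same 1,990 ms sample: the drop across
the series resistance is produced by the whole current, not only its
blocker-sensitive component. The normalized G–V is fit with
`G/Gmax = scale/(1 + exp((V½ − V)/k))`; the free scale absorbs the
normalize-to-maximum convention (the largest measured point need not sit
on the saturated plateau).

**Generator.** The specific current follows Boltzmann steady-state
activation with first-order kinetics (τ_act = 500 ms, τ_deact = 150 ms,
reversal −85 mV, Gmax 10 nS, V½ +20 mV, k 13 mV — typical slow
delayed-rectifier values for the channel/subunit complex); the seal leak
(1/Rseal) sits across the pipette-bath seal and follows the command
potential, so it cancels exactly in blocker subtraction. The membrane
potential under the uncompensated series resistance is solved
self-consistently at the 1,990 ms analysis sample, which makes the planted
Boltzmann exactly recoverable from noiseless tails at the corrected
potentials. Capacitive transients and deactivation kinetics are not
modeled; tails decay fully at −30 mV.

**Known bias.** With trace noise, picking the tail extremum over a short
window is a max statistic and slightly inflates small tails, flattening
the fitted slope k by ~5–10% at 8 pA RMS noise; V½ is essentially
unbiased (median error < 2 mV in the recovery suite).

## Synthetic-data generators

The generators define the study conditions; their defaults are the assay's
operating points (384-well plates with 16 negative- and 16
positive-control wells in columns 1–2; ~120 Poisson-distributed cells per
well; 35% cell-level CV; 8% plate effects; 2,500 events per flow sample
across 8 paired replicates; 8 log-spaced concentrations 1–100 μM with 4
replicates at 5% noise; 0/3/6/9 h chase timepoints at 8% noise; −80..+60 mV
steps in 10 mV increments). Cell- and event-level intensities are
log-normal around their means (fluorescence is positively skewed and
multiplicative); plate and staining-batch effects are single
multiplicative factors per plate/replicate and channel. Planted screen
effects can be specified as multiplicative factors or in MAD units of the
expected null well-mean spread (the per-cell ratio divides two independent
channels, so its conversion carries a √2). Toxicity is a reduced expected
cell count. All streams derive from one seed via stable per-plate /
per-sample substreams, so outputs are byte-identical given a seed and
single units can be regenerated in isolation.

One generator decision deserves emphasis: the flow effect preset for the
hit compound at 10 μM plants surface ×1.2331 and total ×1.1036 (internal
pool multiplier derived from the vehicle composition), giving a
trafficking-efficiency ratio of ×1.1174 by the TE identity
`TE ratio = surface ratio / total ratio`. A triple in which all three
effects are free parameters cannot be realized by any per-event generative
model, because TE is determined by the other two; the preset is the
consistent triple that minimizes the worst-case relative deviation from
the characterized effect sizes on the percent-increase scale.

**What the generators do not emulate:** microscope images and
segmentation (the pipeline starts from per-cell feature tables), spatial
plate artifacts (edge effects, gradients — the robust z is plate-global),
flow doublets and scatter geometry, debris, instrument drift within a run,
compound autofluorescence, and channel-specific saturation. Passing the
recovery suites therefore shows the estimators are correct under the
stated noise model, not that they are robust to every artifact of real
instruments.

## Problem sizes in the test and analysis runs

The suites use deliberately desk-scale sizes chosen to keep statistical
power while staying fast: null-calibration runs use 12 plates (≈ 12,700
well-metric trials, ~34 expected null flags), recall runs plant 60 effects
of 5–10 MAD across 4 plates, flow recovery uses the full 2,500 × 8 design,
ephys recovery uses 16–20 cells at a 5 ms sample interval (1,990 ms falls
on the grid at any tested dt). The analysis drivers print the planted
truth next to every recovered value.

## Limitations

* The robust z assumes a mostly inactive library; plates dominated by
  active compounds would need control-based normalization.
* No spatial plate-effect correction (B-score/LOESS) is implemented.
* Compensation assumes a linear, time-invariant spillover; no
  autofluorescence spreading model.
* The 4PL bootstrap CI is percentile-based and can undercover near the
  edges of the tested concentration range.
* Ephys analysis does not model leak beyond blocker subtraction and does
  not correct liquid-junction potentials; deactivation kinetics are out of
  scope.
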