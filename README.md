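# traffickit

Analysis pipeline for a high-content screen for correctors of KCNQ1
trafficking, the voltage-gated potassium channel whose loss of function
causes type 1 long QT syndrome. Most disease-associated KCNQ1 variants fail
to reach the plasma membrane; a small molecule that restores surface
trafficking is a candidate therapeutic strategy. This package implements
the full quantitative chain such a campaign needs, together with
synthetic-data generators that stand in for the raw instrument outputs so
every stage has a recoverable planted truth:

* **Plate screen** (`traffickit.plate`) — per-cell feature tables from a
  384-well imaging assay are aggregated to well means of three metrics
  (cell-surface signal, total signal, and the per-cell trafficking ratio
  surface/total), scored plate-by-plate with the median-based robust z-score

  `z_i = (x_i − median(x)) / (1.4826 · MAD(x))`

  over each plate's compound wells, and called as hits at |z| > 3 on any
  metric, excluding toxic wells (cell-count z < −3). Plate QC covers the
  Z′ factor `1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|`, negative-control %CV,
  cell counts, and focus score.
* **Funnel** (`traffickit.funnel`) — confirmation in ≥ 2 of 3 biological
  replicates (same metric, same direction), counter-screen exclusion of
  compounds that also move an unrelated membrane protein, and auditable
  stage accounting with hit rates.
* **Flow trafficking** (`traffickit.flow`) — spillover estimation from
  single-color controls, compensation, reporter gating, background
  subtraction, and brightness correction yield the trafficking efficiency
  `TE = S_corr / (S_corr + b·I_corr)`, the surface fraction of
  channel-corrected total protein, normalized to vehicle within replicate.
* **Dose-response** (`traffickit.doseresponse`) — four-parameter logistic
  fits `y = bottom + (top − bottom)/(1 + (EC50/c)^hill)` with optional fixed
  asymptotes and a seeded case-resampling bootstrap for the EC50 CI.
* **Mechanism assays** (`traffickit.assays`) — cycloheximide-chase
  half-life (`y = 100·e^(−kt)`, t½ = ln2/k), CETSA melt curves (T_agg at the
  inflection), ΔΔCt qPCR fold change, and trypan-blue viability.
* **Patch clamp** (`traffickit.ephys`) — QC (Rseal ≥ 0.1 GΩ,
  Rseries < 10 MΩ), blocker subtraction to isolate I_Ks, capacitance-
  normalized peak current density at 1,990 ms, tail-current G–V at −30 mV
  with per-potential series-resistance correction `V_corr = V_cmd −
  I·Rseries`, and Boltzmann activation fits
  `G/Gmax = 1/(1 + exp((V½ − V)/k))`.
* **Generators** (`traffickit.simulate`) — every input family above, with
  named presets pinning the characterized values (EC50s of 12.8 / 11.3 /
  15.4 μM, a ~7 h half-life, the 10 μM flow effect triple) as ground truth.

## Worked example

The numbered drivers under `analysis/` run each stage on generated data and
write tables under `results/`. For example:

```
$ python analysis/02_flow_trafficking.py --seed 1
8 paired replicates x 2500 events
vehicle trafficking efficiency: 0.350 (truth 0.350)
cell-surface              +23.0% vs vehicle (sd 1.8; planted +23.3%)
total protein             +10.3% vs vehicle (sd 1.0; planted +10.4%)
trafficking efficiency    +11.5% vs vehicle (sd 1.0; planted +11.7%)
```

The pipeline recovers the planted treated-versus-vehicle effects — a 23%
increase in cell-surface protein, 10% in total protein, 12% in trafficking
efficiency — from raw, spillover-contaminated, background-laden event data.
Likewise:

```
$ python analysis/01_screen_and_funnel.py --seed 1
plates passing QC: 3/3 (median z' = 0.76)
primary hits: 16 of 1055 compounds (1.5% hit rate)
         stage  input_count  output_count  pct_of_library
primary_screen         1055            16             1.5
  confirmation           16             4             0.4
counter_screen            4             4             0.4
planted modulators recovered through the funnel: 4/4
```

All four planted trafficking modulators survive the funnel while the
primary screen's false positives (null wells beyond |z| = 3) are removed at
the replicate-confirmation stage.

```
$ python analysis/03_dose_response.py --seed 1
vu0494372-surface          EC50 =  12.2 uM (95% CI 9.7-15.0; truth 12.8)
vu0494372-total            EC50 =  11.3 uM (95% CI 8.2-14.5; truth 11.3)
vu0494372-trafficking      EC50 =  14.4 uM (95% CI 11.6-17.0; truth 15.4)
```

See `docs/methods.md` for the models, the generator's assumptions, and
numerical choices.

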