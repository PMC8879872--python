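# Methods

## Model structure

The model tracks one treated lung lesion from the first radiotherapy
fraction (t = 0) to its follow-up CT (t = `followup_days`). States:
proliferating volume `x1` (mm³), necrotic volume `x2` (mm³), a
radiotherapy dose compartment `x5` and its effect-site compartment
`xe5`. Two further branch pairs (antiangiogenic `x3/xe3`, immunotherapy
`x4/xe4`) are kept structurally for combined-therapy studies but are
driven by zero inputs here, so they remain identically zero.

```
x1' = (a − n) x1 − E·x1
x2' = n·x1 + E·x1 − λw·x2
x5' = −c_r x5 + u_r(t)·k_gy
xe5' = −c_r xe5 + E_tr·x5
```

Growth of the proliferating compartment is exponential at the net rate
`a − n`; the treatment-driven kill `E·x1` converts proliferating into
necrotic tissue, which is cleared at the washout rate `λw`. The forcing
`u_r(t)` delivers each fraction as a rectangular dose-rate pulse of
width 0.1 day starting at the beginning of its treatment day, with
height `fraction dose / width` — a finite dose rate keeps the system
non-stiff and makes the delivered-dose integral exactly equal to the
prescribed total dose. The integrator splits the time axis at pulse
edges so the adaptive Runge–Kutta scheme (rtol 1e-8, atol 1e-8, maximum
step `width/5` inside pulses) always sees a smooth right-hand side.

The kill rate combines tumour burden and effect-site dose level through
an interaction index and a Hill sigmoid:

```
U_nr = xe5 / C50r
U_nt = (x1 + x2) / C50t          (absolute mode, default)
     = (100·(x1+x2)/V0) / C50t   (relative mode)
I    = U_nt + U_nr + σ·U_nr·U_nt
E    = Emax · I^γ / (1 + I^γ)
```

`γ` ("patient response") sets the steepness of the sigmoid and is the
only parameter fitted per lesion; `σ = 8` expresses the synergy between
accumulated burden and the radiation effect and is held constant
throughout (single-modality treatment). The reported volume compared
with CT measurements is by default the active volume
`δV = total − necrotic = x1`; the total `x1 + x2` is available as an
option.

## Parameter defaults

| parameter | default | units | role |
|---|---|---|---|
| `a` | 0.693 | 1/day | proliferating growth rate |
| `n` | 0.10 | 1/day | spontaneous necrosis rate |
| `cr` | 3 / treatment duration | 1/day | clearance of dose and effect-site compartments (per lesion) |
| `etr` | = `cr` | 1/day | effect-site transfer; equality gives the effect compartment unit steady-state gain |
| `c50r` | 20 | Gy/day | half-effect effect-site dose rate |
| `c50t` | 50 | mm³ (absolute) or % (relative) | half-effect tumour burden |
| `emax_rate` | 1.10 | 1/day | maximal kill rate (see below) |
| `sigma` | 8 | – | burden–dose synergy |
| `gamma` | fitted per lesion | – | response steepness, bounds [1e-3, 1] |
| `washout` | 1.0 | 1/day | necrotic clearance λw |
| `gy_to_conc` | 1 | – | Gy → model concentration units |

Treatment duration is the span from first to last fraction day,
inclusive, read off each lesion's day list.

### The kill-rate closure

The literature coefficient set quotes a maximal radiotherapy effect of
50% together with growth/necrosis rates of 0.693/0.10 per day, but
never states the kill term explicitly. Reading the maximal effect as a
rate of 0.5/day caps the kill below the net growth rate
`a − n = 0.593`/day, under which no lesion could ever shrink and the
observed post-treatment regressions (up to complete disappearance)
would be unreproducible. We therefore treat the maximal kill rate
`Emax` as a model constant to be fixed once against the cohort's
qualitative behaviour, and we anchor it at the low end of the response
range: at the smallest reported γ (0.043) the therapy-free balance point
of growth against the burden-driven kill,

```
x1* = (C50t / (1 + (n + (a−n))/λw)) · ((a−n)/(Emax−(a−n)))^(1/γ)
```

should sit at the cohort's median baseline volume (≈1.2 cm³), i.e.
lesions at the bottom of the response range neither progress nor regress
— the reported stable-disease behaviour. With `λw = 1`/day this gives
`Emax = 1.10`/day (balance point 1.13 cm³). The same anchor places the
balance point for γ = 0.25 at ≈0.055 cm³, just above the 0.05 cm³
measurability threshold, so the upper end of the reported response range
corresponds to lesions shrinking to the edge of detectability, and
fitted γ beyond ≈0.3 to frank eradication.

### Necrotic washout

With `λw = 0` the total volume `x1 + x2` can never decrease
(`(x1+x2)' = a·x1 ≥ 0`) and the accumulated necrotic mass drives the
burden term without bound, eventually extinguishing `x1` for any γ —
including untreated lesions. Observed post-treatment volume curves
decrease, so the default washout is positive (`λw = 1`/day), under which
necrotic and active tissue are comparable at balance
(`x2/x1 = (n+E)/λw ≈ 0.69`) and the system has a well-defined stable
balance point per γ. `λw = 0` remains available and is used by the
closed-form integrator checks.

### Burden normalisation modes

`C50t`'s printed unit is ambiguous ("% mm³"). Both readings are
implemented. Absolute mode (default) reads it as an absolute half-effect
volume of 50 mm³. Relative mode reads it as a percentage of the
lesion's own baseline. Relative mode makes the dynamics scale-invariant
in volume — the final volume is then *exactly* proportional to the
initial volume — whereas the cohort analysis shows sub-proportional
responses of the simulated final volume to baseline perturbations
(≤10% change for a 20% perturbation). Absolute mode reproduces that
saturation and is therefore the default.

## Calibration

Each lesion has exactly two measurements, so the fit target is a single
residual: simulated reported volume at `followup_days` minus the
measured post-RT volume (in mm³, cohort volumes are cm³ and converted at
the boundary). The objective (squared residual) is scanned on a
32-point geometric grid over γ ∈ [1e-3, 1] — covering the reported range
0.043–0.25 with margin — and refined by bounded Brent minimisation to an
absolute tolerance of 1e-5; grid ties resolve to the smallest γ.
Lesions measured as no longer present fit a 0 mm³ target; the optimum
then sits at the upper bound and is flagged (`bound_hit="upper"`) rather
than special-cased. Multi-lesion patients are fitted independently per
lesion, as they were treated.

The fitted-γ ↦ final-volume map is continuous and non-increasing for
every cohort lesion (checked over a γ grid), which makes the
single-residual fit well-posed: any measured volume between the balance
floor and the low-γ growth limb is matched essentially exactly, which is
why the measured-vs-simulated regression attains r ≈ 1 (the published
analysis reports r = 0.994, slope 0.968).

## Outcome statistics

* **Efficacy** per lesion: `100 − 100·v_post/v_pre` (%); negative values
  are progression; 100% exactly when the lesion was unmeasurable.
* **Regimen means**: unweighted means of per-lesion efficacies within
  each (total dose, fraction count) group, over lesions flagged
  `in_regimen_stats`. The reference cohort prints 23 lesion rows but
  counts 22 treatment schemes; one lesion (patient 012, lesion 3) is
  excluded from that accounting and one further lesion (patient 020,
  lesion 1) from the regimen means. These are the unique exclusions
  under which the published group means (66.66 / 67.27 / 68.82 /
  −4.76%) emerge from the printed volumes, verified by brute force
  before the fixture was frozen.
* **Regression**: OLS of simulated final volume on measured post-RT
  volume over all lesions; reports slope, intercept, Pearson r, and the
  RMSE of simulated vs measured (cm³).
* **Sensitivity**: per lesion, the baseline volume is decreased by
  5/10/20% (a sign option allows increases), γ held at its fitted value,
  and the percent change in simulated final volume reported, summarised
  as per-level quartiles. Changes are sub-proportional and monotone in
  the perturbation for every cohort lesion under the default
  normalisation.

## Reference cohort notes

The bundled cohort is transcribed verbatim from its source table,
including two rows of patient 020 whose printed day list and fraction
count disagree (lesion 1: 48 Gy/4 with day "1"; lesion 2: 34 Gy/1 with
days "2-4-7-9" — an apparent transposition). The rows are bundled as
printed rather than silently corrected: record validation relaxes the
day-count consistency check for the bundled file, and dose schedules
follow the day list with the per-pulse dose set to
`total dose / number of pulses`, so the delivered dose always equals the
prescribed total. Post-RT volumes printed as 0 are kept as 0;
the subset footnoted as unmeasurable radiation-pneumonitis fields
carries `not_measurable=True`.

## Synthetic cohorts

The generator emulates the reference cohort's structure: log-uniform
baseline volumes over 0.3–20 cm³ (the observed two-decade span), the
four regimens at frequencies 2:9:10:1, treatment-day patterns drawn from
the repertoire actually used (not invented), follow-up uniform over
63–191 days, γ uniform over 0.043–0.25, and post-RT volumes produced by
forward simulation with optional multiplicative lognormal noise.
Simulated volumes below 0.05 cm³ are recorded as 0 with the
not-measurable flag, mirroring the clinical convention.

What the generator deliberately does **not** emulate: intra-patient
correlation between lesions, measurement error on the baseline volume,
follow-up-time dependence of measurement quality, and any toxicity/DVH
structure (those fields are carried through but never generated).
Passing recovery tests therefore demonstrate identifiability of γ under
the model's own data-generating process — not robustness to model
misspecification in real cohorts.

## Numerical choices and problem sizes

* Integration: explicit adaptive RK45, rtol 1e-8 / atol 1e-8, piecewise
  between forcing breakpoints; refining to 1e-10 moves final volumes by
  < 0.1%. Tiny negative excursions (below 1e-6 of the baseline volume)
  are clipped to zero; larger ones raise an integration error.
* Calibration: 32-point geometric grid + bounded Brent, γ tolerance
  1e-5, ≈60 objective evaluations per lesion; the full 23-lesion cohort
  calibrates in ~10 s on one CPU.
* The test suite uses 20-lesion recovery experiments (noise-free
  maximum |γ̂ − γ| < 1e-3; at 5% lognormal noise the median error stays
  below 0.02) and fixed seeds throughout.

## Known limitations

* The growth/necrosis rates (0.693/0.10 per day) imply a ~1.2-day
  doubling time — far faster than clinical lung tumours — so the
  calibrated dynamics should be read as an effective description on the
  follow-up horizon, not as cell-kinetic estimates.
* `Emax` is an identifiability closure, not a measured quantity; fitted
  γ values are conditional on it and on the washout rate.
* The Michaelis–Menten clearance interaction sometimes associated with
  this model family is not implemented: no half-saturation constant is
  available for it, and the displayed equations do not contain it.
* With a single residual per lesion, γ is exactly identified but its
  uncertainty is not; no standard errors are reported.
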