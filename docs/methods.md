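# Methods

## The cycle model

The actomyosin ATPase cycle is represented as a continuous-time linear
reaction network over eight enzyme states: the nucleotide pathway
M → M·T → M·D·Pi → M·D → M on detached myosin, the same pathway on
actin-bound myosin (A·M …), and actin attachment/detachment edges joining
the two branches. Occupancies evolve as dx/dt = Q·x with Q the generator
matrix; mass is conserved exactly (rows of Q sum to zero), and simulations
re-normalize away integrator drift so the conservation invariant holds to
1e−9 at every time point.

Modelling choices:

- **ATP binding** is a rapid-equilibrium association followed by an
  essentially irreversible isomerization. The pseudo-first-order binding
  rate is therefore hyperbolic in substrate,
  k_T([ATP]) = K₁k₊₂·[ATP]·k₊₂/(K₁k₊₂·[ATP] + k₊₂): linear with slope
  K₁k₊₂ (µM⁻¹ s⁻¹) at low [ATP] and saturating at k₊₂ (s⁻¹). This builds
  the "fast phase never exceeds k₊₂" constraint into the model.
- **Hydrolysis** is lumped into a single relaxation rate (the sum of the
  forward and reverse hydrolysis rates) and treated as irreversible for
  flux purposes; the two microscopic rates are not separately identifiable
  from the relaxation experiments the model serves.
- **Actin interaction.** Weak-binding states (A·M·T, A·M·D·Pi) detach at
  `actin_off_weak`; strongly bound states (A·M, A·M·D) leave actin only via
  ATP-induced dissociation, i.e. through the weak states. Attachment is
  `actin_on·[actin]` for all states. Neither actin rate constant is an
  experimentally measured quantity here; both are free parameters.
  `actin_on` defaults to 1 µM⁻¹ s⁻¹, and `with_km_target` calibrates
  `actin_off_weak` by root-finding on the *simulated* half-activating actin
  concentration so the network reproduces a configured K_M(actin). A simple
  closed-form assignment (off = on·K_M) is not exact for this topology, so
  the calibration is numerical.
- **Basal phosphate release** (`k4_basal`, detached branch) defaults to
  0.1·k₊₄. Actin accelerates phosphate release by an order of magnitude or
  more in muscle myosins; without a slower basal release the network shows
  almost no actin activation and no value of `actin_off_weak` can realise a
  physiological K_M(actin). Tying the default to k₊₄ keeps a blocked release
  step blocked on both branches.
- **Steady-state turnover** comes from the null space of Q (stationary
  distribution), with the flux read off the phosphate-release edges. A
  network disconnected by a zero rate reports zero flux rather than raising.
  The long-time ODE flux agrees with the null-space rate to 1e−6 relative;
  this dual route (matrix algebra vs integration) is tested on random rate
  sets spanning six orders of magnitude.
- **Single-turnover mode** adds free ATP as a dynamic species depleted by
  binding (pool set by the head concentration); multiple-turnover mode
  clamps ligand concentrations (pseudo-first-order).
- **Integration**: LSODA with rtol 1e−8 / atol 1e−10 — the rate constants
  span five orders of magnitude, so a stiff adaptive method is required.
- **Units**: seconds and µM throughout; temperatures are °C at interfaces
  and Kelvin internally (R = 8.314 J mol⁻¹ K⁻¹).

A known tension is kept deliberately: the series-of-steps arithmetic over
the measured microscopic constants (1/Σ 1/kᵢ ≈ 0.086 s⁻¹ at saturation)
undershoots the independently fitted k_cat of 0.12 s⁻¹ by ~30%. The model
does not force agreement; the test suite requires only the 30% band.

## Synthetic data

Every experiment class is generated from explicit true parameters, a
sampling grid, a noise level and a seed; identical specs produce identical
bytes. Noise is additive, per-point independent Gaussian — homoscedastic at
a fraction of the signal span by default (instrument noise in stopped-flow
and plate-reader traces is approximately signal-independent), with
`absolute` and `relative` modes available (`relative` is used for rate
series spanning several-fold, e.g. Arrhenius). Published noise magnitudes
are not available, so 1% of span is the default (2% for steady-state rate
curves, 5% for the long refolding incubations); these are choices, not
measured values.

Per-dataset seeds are split from one master seed by hashing a dataset label
(SHA-256) into the seed sequence, so adding a dataset never perturbs
previously generated ones and any dataset can be regenerated in isolation.

Default grids mirror the experimental regimes: transients sampled densely
over the fast rise and out to six slow-phase lifetimes (split-timebase
acquisition), melts 25–90 °C at 1 °C, refolding 0–2 h every 5 min,
temperature series 25–45 °C.

What the generator does *not* emulate: photobleaching and mixing artefacts,
heteroscedastic detector noise, baseline drift, filament-tracking errors,
day-to-day preparation variability. Passing recovery tests therefore show
that the estimators are unbiased and precise under the stated noise model at
the stated designs — not that every systematic error of the real
instruments is handled.

## Fitting stages

- **Exponential transients**: y(t) = baseline + Σ Aᵢ(1 − e^(−kᵢt)), 1–2
  phases. Rates are estimated by variable projection (the linear baseline
  and amplitudes solved exactly at each candidate rate set) with eight
  log-spaced multi-start initializations; ties break to the lowest residual
  norm. A final full-parameter polish supplies the covariance. Flat traces
  return a flagged failure result instead of raising. Phases are reported
  fastest first.
- **kobs-versus-[ATP] analysis**: the fast-phase rates are fitted with a
  binding hyperbola whose plateau is k₊₂ and whose initial slope
  (plateau / half-saturating [ATP]) is the apparent second-order constant
  K₁k₊₂ — this estimator is exact on noiseless data. The classical
  graphical estimate, a straight line through the low-[ATP] points
  (predicted kobs ≤ 0.3·plateau), is also reported (`K1k2_linear`); on
  hyperbolic data it is biased low by roughly x̄/K_half (≈10–30% for
  realistic designs), which is why it is not the primary estimate. Fold
  changes between paired conditions are taken slope-against-slope, where
  the bias cancels. The slow-phase rates saturate at the hydrolysis
  relaxation rate; saturation is flagged unreliable if the largest observed
  kobs is below 80% of the fitted plateau.
- **Active-site titration**: tight-binding model — amplitude rises linearly
  in [mant-nucleotide] until the competent sites are filled, then plateaus;
  the breakpoint is located by a coarse grid plus bounded 1-D refinement.
  Fractions above 1 are capped at 1 with a warning (the raw value is kept).
- **Actin activation**: offset hyperbola with the basal rate as a fitted
  offset by default (a basal-subtracted convention is selectable). Both
  coupling conventions are always reported: the ratio k_cat/K_M and the
  initial slope (k_cat − basal)/K_M; they coincide exactly when basal = 0.
  The generator's basal defaults (0.049 and 0.081 s⁻¹) are back-computed
  from the two published coupling conventions so the paired curves are
  internally consistent.
- **Hill fits** (dose–response, isotherms): Hill coefficient free within
  [0.5, 4]. Flat dose-responses report fold_max = 1 with the half-activation
  flagged undefined; flat isotherms report a no-binding result.
- **Arrhenius**: OLS of ln(rate) on 1/T; Ea = −slope·R. Non-positive rates
  are excluded with a warning. Whether the original linear fits were
  weighted is not stated; unweighted is used and documented.
- **Boltzmann melts**: signals are affine-normalized to [0, 1] (folded → 0)
  using the three lowest/highest-temperature points, then fitted with
  base + span/(1 + e^((Tm−T)/s)). Tm is invariant under affine transforms
  of the raw signal; normalization is idempotent. Aggregation
  (light-scattering) transitions use the same form.
- **Refolding recovery**: rectangular hyperbola in time,
  y = base + (plateau − base)·t/(t_half + t), with a saturating-exponential
  alternative behind a flag and residual norms exposed for model
  comparison. The observed rate constant is reported as kobs = 1/t_half —
  the transform is a documented choice applied identically to synthetic
  truth and fits, so recovery experiments are self-consistent. The
  kobs-versus-[compound] line is a weighted (1/SE²) least-squares fit;
  slope = k_rescue, intercept = dissociation rate.
- **Rescue scheme**: four states — trapped (T), compromised (0), rescued
  (R), aggregated (†, irreversible). In the two-state reduction
  (maturation off) the relaxation of the bound fraction is exactly
  k_on·[compound] + k_off, matching the linear analysis; with fast
  maturation the back-flux is suppressed and the apparent rate tends to
  k_on·[compound]. Only k_rescue and k_off are measured; the remaining
  transitions are free parameters used in property tests.
- **Motility**: velocities above a stall threshold (default 0.1 µm s⁻¹ —
  the criterion for "moving" is not defined experimentally, so this is a
  documented choice) are histogrammed (Freedman–Diaconis, fixed 0.05 µm s⁻¹
  fallback) and fitted with a Gaussian; sample moments are the fallback for
  sparse histograms.

## Recovery experiments and problem sizes

`myokin.recovery` defines one function per headline constant: generate at
the study conditions (12-point isotherms at 1% noise; 8-point dose and
actin curves; six-concentration transient series with 1000-point traces;
five-temperature Arrhenius series at 2% relative noise; 66-point melts at
1% noise; four-concentration rescue batteries at 5% noise) and report the
median fit over 100 seeds. These sizes keep every battery in seconds and
the full reproduction script under a minute on one CPU while leaving the
medians well inside the published uncertainties. The pipeline's single-seed
demonstration report uses a fixed tolerance policy (15% per parameter, 25%
per fold change, 2% for melting temperatures); individual seeds
occasionally graze these bounds — the medians are the quantitative claim.

## Limitations

- No force generation, cross-bridge mechanics, or Ca²⁺ regulation; no
  NADH-assay absorbance conversion (rates enter in s⁻¹).
- Actin association/dissociation constants are free parameters, not
  measurements; conclusions about them should not be drawn from this model.
- ADP-release constants have no dedicated fitting stage (no relaxation
  experiment in scope isolates them), so they appear as model inputs only.
- The two published nucleotide-free melting temperatures (45.8 °C in the
  text, 45.1 °C in the supplement) are both retained as references; the
  package does not adjudicate between them.
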