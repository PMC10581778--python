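# Methods

This note documents the models, conventions and numerical choices behind
`thermoclamp`, and what the synthetic-data validation does and does not
demonstrate about real recordings.

## The measurement being modelled

A *Xenopus* oocyte expressing a heat-activated channel is clamped at
−60 mV while the bath is cycled between a cool hold (5–9 °C) and ~40 °C,
each cycle lasting about a minute; temperature, current and voltage are
recorded gap-free at 2 kHz. The recorded current is the sum of the channel
current, endogenous/leak currents, and instrument noise — the clamp cannot
separate these, which shapes several conventions below.

## Van't Hoff transform and segmented fitting

Analysis downsamples to 100 Hz by 20-sample block means (white-noise SD
shrinks by √20), splits the recording into per-activation heating segments
(smoothed-temperature peaks ≥ 30 °C, ≥ 10 s apart; each segment runs from
the preceding temperature minimum to the peak), and transforms each
segment to (1/T_K, log |I|). Only the heating phase is fitted: cooling
branches in this preparation show hysteresis, and the heating branch is
the one on which activation thresholds are defined. Samples with
|I| < 1 pA are dropped (and counted) before taking logs.

The fitted model is a continuous piecewise-linear function with k = 0, 1
or 2 breakpoints. For each k the breakpoint position(s) are optimized
exactly over the grid of observed 1/T values (ordered pairs for k = 2):
for every candidate the model is a linear least-squares problem on the
hinge basis {1, x, (x−b)+, …}, and all normal-equation sums come from
prefix sums, so the whole grid is evaluated in closed form. The final
coefficients and RSS of the best candidate are recomputed with a clean
lstsq refit (the prefix-sum path accumulates rounding at thousands of
points). When more than `max_candidates` (default 400) grid values are
admissible the grid is thinned evenly; on a standard 100 Hz ramp this
resolves breakpoints to < 0.1 °C. Each segment must contain at least
`min_seg_points` = 5 points. k is selected by BIC on gaussian RSS
(p = 2 + 2k parameters), with ties resolved toward fewer breakpoints; a
`force_k` override exists because published practice chose the breakpoint
count by the visual shape of each curve. Breakpoint standard errors come
from a seeded nonparametric bootstrap over points (200 resamples by
convention).

### Conventions and their consequences

- **Logarithm base.** Natural log by default. Every derived quantity is
  base-invariant by construction because Q10s are computed from fitted
  currents: `Q10 = (I2/I1)^(10/(T2−T1))` evaluated at segment endpoint
  temperatures. Measured agreement between natural-log and base-10 runs is
  at floating-point rounding level (≲1e−12 relative).
- **Fitting in 1/T.** A pure Q10 process is exactly log-linear in T, not
  in 1/T. Fitting straight lines in 1/T (the van't Hoff/Arrhenius
  convention) therefore leaves a small systematic curvature within
  segments. Quantified on noiseless synthetic data over the experimental
  spans: endpoint Q10s are recovered to ~0.1–1% relative and breakpoints
  to 0.03–0.18 °C, independent of grid resolution. The package follows the
  convention and documents the bias rather than "correcting" it; it is an
  order of magnitude inside the recovery tolerances that matter (±1 °C,
  ±15%).
- **Threshold classification.** A curve has a *distinct threshold* when
  some breakpoint's following segment has Q10 above the thermosensor floor
  (3.0, the conventional criterion for temperature-gated channels). If the
  *first* segment — from the hold temperature up — already exceeds the
  floor, the cell is classified *no distinct threshold* (channels already
  open at the hold, as seen after strong threshold-lowering treatments);
  if no segment exceeds the floor the curve is *baseline only*
  (water-injected-control behaviour). Classification never raises.
- **Scalar metrics.** Leak is the mean current over a 2 s window ending at
  the detected ramp onset (sustained heating slope > 0.2 °C/s for 0.5 s);
  maximum current is |I interpolated at 35 °C on the heating branch| −
  |leak|, using the first crossing if there are several. Both are
  magnitudes, invariant to the inward-negative sign convention.

## Boltzmann I–V analysis

Steady-state current per voltage step is the mean over the last 20% of
the 100 ms test step. Chord conductances G = I/(V − E_rev) (E_rev = 0 mV
default for the nonselective cation conductance; points within 5 mV of
E_rev excluded) are fitted with

    G(V) = g_leak + g_max / (1 + exp((V50 − V) / s))

by bounded nonlinear least squares from a deterministic grid of starts.
The constant `g_leak` term is deliberate: every oocyte carries an ohmic
background conductance, and omitting the term biases V50 by several mV
whenever the channel conductance is not much larger than the leak (at
25 °C, with the thermal gate mostly shut, the bias was ~4.5 mV in
simulation). EC50 and V50 are treated as the same quantity — the voltage
of half-maximal conductance. Note the fitted `g_max` is the maximal
conductance *at the test temperature* (g·Po(T)), not the channel's
absolute maximum. Fits whose sigmoid moves less than 30% of full scale
across the tested span are flagged not voltage-dependent (e.g. leak-only
cells).

## Mixed-model condition comparisons

Metrics are compared with `value ~ condition * activation` plus a random
intercept per oocyte (repeated activations of one cell are not
independent; random slopes are not used because the experimental design
repeats few activations per cell). Preprocessing: 3×IQR fences within each
condition × activation cell (linear-interpolation quartiles, the R-default
convention; 1.5×IQR values are flagged but kept; an IQR of 0 collapses the
fence to the quartile points so all-equal cells lose nothing), then a
Shapiro–Wilk check on fixed-effects residuals with a natural-log fallback
for positive (or uniformly negative, via magnitudes) metrics.

Estimation is REML via statsmodels' MixedLM, trying lbfgs, then Powell,
then Nelder–Mead (gradient methods can hit exactly singular information
when the between-cell variance is zero; the singular flag reports that
profile). Wald statistics for the main effects and interaction are
referred to an F distribution with *containment* denominator degrees of
freedom (cells − conditions) — statsmodels provides no Satterthwaite
approximation, and the containment rule keeps the type-I error of the
condition test at the nominal 5% in the null calibration (rejection rate
within [0.03, 0.07] over 1000 seeded replicates). Estimated marginal means
average the fixed-effect design over activation levels; pairwise contrasts
use Bonferroni correction (`p_adj = min(1, m·p)` exactly). A cell-level
permutation test provides a distribution-free cross-check.

## The synthetic-data generator

The generator exists so every stage can be validated by parameter
recovery. Two gating families:

- **Piecewise-Q10** — |I| grows with fixed Q10s on up to three temperature
  bands (baseline / activation / supra-saturation). This is the exact
  inverse of the downstream Q10 computation, so recovery is well-posed.
- **Two-state** — Po(T) = 1/(1 + exp((ΔH − T·ΔS)/(R·T))) with
  R = 8.314 J/(mol·K), optionally times a Boltzmann voltage gate; used for
  I–V simulations and saturation realism. Defaults place the gating
  midpoint at 35 °C with ΔH = 200 kJ/mol (a large opening enthalpy, as
  expected for strongly temperature-gated channels).

Cycles are triangle ramps (hold plateau = 1/6 of the cycle, up and down
ramps splitting the rest equally) — the real heater's ramp shape is not
published, so this is a stand-in, and the analysis never assumes it.
Between-cell variation is lognormal (CV 0.3) on magnitude parameters and
normal on thresholds; published per-condition dispersions (e.g. ±1.31 °C
for the control threshold) are used as the between-cell SDs. Measurement
noise is i.i.d. gaussian, 2 nA at 2 kHz — a typical TEVC noise floor,
small against the ~25 nA hold current and the hundreds of nA near the
peak. Per-activation schedules multiply the activation-band Q10 and the
leak conductance per heating cycle and can mark activations where the
distinct threshold is lost (the activation Q10 then applies from the
reference temperature up). The sub-threshold temperature dependence of a
channel-expressing cell (channel baseline + endogenous + leak, which TEVC
cannot separate) is carried entirely by the channel term's baseline Q10;
the explicit leak term is used alone for water-control populations
(Q10 1.24) and alongside the conductance in I–V simulations (0.05 µS).
Reproducibility: one master seed; cell i uses `default_rng(seed + i)`.

### What recovery does and does not show

Passing recovery tests shows the chain is unbiased and well-calibrated
*for data generated by these models*: exact-Q10 or two-state gating,
triangle ramps, stationary gaussian noise, no temperature-sensor error, no
capacitive transients, no series-resistance error, no Ca²⁺-dependent
desensitization, no hysteresis beyond the heating-branch-only convention.
Real oocyte recordings violate several of these; recovery results bound
algorithmic error, not total experimental error.

## Problem sizes and defaults

Validation scenarios mirror the study designs: 12 cells (control TRPA1b-
like), 21 (TRPV1a-like, with activation-Q10 schedule 20.48 → 3.95 → 2.70),
19 (cholesterol depletion, threshold 15.1 °C), 8 (1 mM H2O2, 16.97 °C),
9 (water controls), 7 (voltage-step conditions); three 60 s cycles per
cell at 2 kHz. A full recovery run of all scenarios completes in well
under a minute on one CPU; the exhaustive-pair breakpoint search on a
downsampled ramp takes ~0.1 s per curve at the default 400-candidate grid.

## Known limitations

- Breakpoint count selection by BIC can split a genuinely straight but
  curvature-bearing (1/T-convention) segment; the classification layer is
  designed so this does not corrupt threshold assignment, but reported
  `n_breakpoints` can exceed the generating model's count.
- Containment degrees of freedom are conservative for highly unbalanced
  designs.
- The ABF vendor format is not read; recordings enter through the
  documented text trace format (or any constructed `Recording`).
- Kinetics (activation time course, tail-current analysis, hysteresis
  quantification) and enthalpy/entropy estimation from slopes are out of
  scope.
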