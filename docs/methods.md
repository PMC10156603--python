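# Methods

## Kinetic model

Decoding is a continuous-time Markov chain over named conformational
states.  The canonical tRNA–tRNA perspective uses four states — Unbound
(FRET 0), codon recognition CR (0.23), GTPase-activated GA (0.49) and
accommodated AC (0.74) — with ternary-complex binding as the single
bimolecular edge (µM⁻¹ s⁻¹ × concentration in µM).  The generator matrix
`Q` has the pseudo-first-order rates off-diagonal and zero row sums;
`state_occupancy` (`p0·expm(Qt)`) and `mean_first_passage` (target made
absorbing, linear solve restricted to states that can reach it) are exact
oracles used to validate the stochastic simulator and the estimators.

Assumptions: time-homogeneous rates (no temperature interpolation —
25 °C and 37 °C are separate presets), exponential dwells, no hybrid-state
kinetics beyond a single reversible AC↔GA excursion edge, and a P-site
reference dye that does not move.

### Presets and parameter provenance

The preset file (`smdecode/presets/decoding_presets.yaml`, versioned)
anchors the measured constants: k_on = 70 µM⁻¹ s⁻¹, CR lifetime 10 ms,
GA→CR = 1/0.620 s⁻¹ (so the GA lifetime is 620 ms when hydrolysis is
blocked), GA→AC = 1.7 s⁻¹ (25 °C) or 12.8 s⁻¹ (37 °C), and the state
FRET means/SDs.  Two quantities are not independently measured and were
fixed once so that the scheme reproduces the measured catalytic
efficiency of 43 µM⁻¹ s⁻¹ exactly at the default working concentration of
0.0125 µM: the CR-exit branching (95.337 s⁻¹ onward / 4.663 s⁻¹
rejection, i.e. ~95% of codon-recognition events productive) and the
AC→GA excursion rate (0.5 s⁻¹, slow reversible excursions preceding
stable accommodation).  Note that GA→AC = 1.7 s⁻¹ and a 620-ms GA
lifetime cannot coexist in one uninhibited scheme (total GA exit would
have to be ≤ 1.61 s⁻¹); the 620 ms lifetime belongs to the
hydrolysis-blocked condition, which is why `cognate-25C-GTPyS` exists as
its own preset.  The `near-cognate` and `cognate-25C-uL11` presets are
qualitative only.

## Synthetic data generator

`sample_path` is a plain Gillespie sampler on `Q`.  `render_trace` turns
a path into raw donor/acceptor intensities:

* **Frame integration.**  The ideal FRET of a frame is the
  occupancy-time-weighted mean of state FRET means inside the frame, so a
  5-ms CR visit inside a 10-ms frame produces an intermediate value, not
  a midpoint sample.  This is essential: CR dwells sit at the integration
  time and all time-resolution effects downstream follow from it.
* **Detection model.**  With corrected-space total intensity T (default
  1000 a.u.), the raw channels are `D = (1−E)·T/γ`,
  `A = E·T + α·D` (γ = 1.15, α = 0.075 by default) — the exact algebraic
  inverse of the correction step.  Gaussian channel noise (SD 25 a.u. per
  frame, giving a frame FRET SD of ~0.02) is added last.  Shot-noise
  scaling is deliberately not modelled.
* **Static heterogeneity.**  The per-state FRET SDs (0.09/0.13/0.06) are
  the widths of measured population histograms; those widths absorb frame
  noise, frame-averaged sub-frame dynamics and molecule-to-molecule
  spread.  The most dynamic state (GA) has the largest width, so the
  printed numbers cannot be mostly static.  The generator therefore
  realizes a per-trace, per-state offset with SD equal to 0.4× the state
  SD (configurable via `static_heterogeneity_scale`); draws that would
  bring adjacent state means closer than 0.10 are replaced by their
  mirror image (sign-flipped offsets), which restores the margin whenever
  the base separations exceed it and keeps the sampler exactly
  mean-unbiased — a molecule whose states genuinely collapse would fail
  the 6:1 signal/signal-noise selection criterion in a real experiment
  anyway.  Full-size static offsets are not usable: a trace whose GA
  level drifts to ~0.32 is indistinguishable from CR and per-trace label
  association becomes ill-posed.
* **Photophysics.**  Single-step exponential photobleaching per
  fluorophore (donor 0.025 s⁻¹, acceptor 0.005 s⁻¹ by default; clocks are
  free-running).  After acceptor bleaching all emission returns to the
  donor; after donor bleaching, and during donor blinks (on-rate
  0.01 s⁻¹, recovery 20 s⁻¹, donor only), both channels fall to
  background.
* **Reproducibility.**  The master seed is split with
  `SeedSequence.spawn` into one child per trace; identical
  (model, config, seed) gives bit-identical datasets and any trace can be
  regenerated alone.

What the generator does **not** emulate: camera/image-level effects
(EMCCD gain, spot overlap, drift), shot noise, multi-molecule aggregates,
acceptor blinking, spectral bleed-through beyond one crosstalk
coefficient, and slow conformational drift within a trace.  Passing tests
therefore demonstrate correctness of the analysis chain under the stated
statistical structure, not robustness to every instrumental pathology.

Equilibrium titration data for the eIF5A isotherm are generated at FRET
level: two-state telegraph paths (classical 0.70 / hybrid 0.30, Gaussian
frame width 0.06, relaxation 2 s⁻¹) whose stationary classical occupancy
equals the isotherm value f_c(L).

## Trace processing

Correction is `A' = A − αD`, `D' = γD` (double correction refused), FRET
is `A'/(A'+D')` clipped to [0,1], with frames whose total falls below the
detection floor set to 0.  The floor is background mean + 4× background
SD of total intensity, with the background estimated from
post-catastrophic-bleach frames.

Photobleach detection is binary segmentation of the total intensity into
plateaus (O(n) best-step search, minimum segment two frames so that a
bleach landing mid-frame does not produce duplicate steps).  A
catastrophic step is a significant downward step (≥ 4σ of the
frame-to-frame noise and ≥ 40% of the preceding level) after which no
plateau recovers; dips that recover are donor blinks and are counted
separately.  Acceptor bleaching is a step down of the acceptor channel
with the total staying at signal level.  On simulated data the detected
donor-bleach frame is within ±2 frames of truth for ≥ 99% of traces.

The five selection criteria use these statistics; two definitions of the
signal/signal-noise ratio are provided because upstream imaging software
does not define it publicly.  The default follows the FRET reading: mean
separation of adjacent FRET modes over the pooled within-mode width,
computed robustly (histogram modes of the above-floor, above-0.15 values;
MAD-based widths so transition-smeared frames do not inflate them; single
-mode traces return ∞, i.e. the criterion is not informative for them).
The alternative `intensity` strategy is mean pre-bleach total over its
SD.  The donor–acceptor Pearson correlation is computed on corrected
intensities over pre-bleach frames; genuine FRET dynamics anticorrelate
the channels, so anything ≥ +0.5 indicates a non-FRET artefact.

## Idealization (segmental k-means)

`skm_idealize` alternates Viterbi decoding under per-trace Gaussian
emissions with re-estimation of emission means/SDs and transition
frequencies from the decoded segmentation, to convergence (relative
decoded-path likelihood change < 1e-4, ≤ 100 sweeps).  Determinism: no
random initialization (states start at the spec means), Viterbi ties
break toward the lower state index.  Numerical choices: emission SD floor
0.01 FRET; transition pseudo-count 0.1; per-trace mean re-estimation is
regularized toward the initial means with a 10-pseudo-frame prior, which
anchors sparsely occupied states (a handful of CR frames must not drag
that state onto transition-smeared values) while leaving well-occupied
states free to follow molecule-specific offsets.  The zero-FRET state is
part of the HMM (four states for the tRNA–tRNA perspective, three for the
uL11 perspective).  Batched decoding over padded arrays gives results
identical to per-trace decoding (tested) at ~100× the speed.

Dwells are run-length encodings with censoring flags: the first and last
events of each trace touch the trace start and the photobleach cut and
are censored by construction.  One-frame dwells are retained.  Population
FRET statistics use only the *interior* frames of dwells of ≥ 3 frames
(boundary frames are frame-averaging mixtures) and take the across-trace
median, which is robust to the rare molecule whose labelling is distorted
by offsets.

## Rate estimators

All confidence intervals are percentile bootstrap over traces (1000
resamples, fixed seed).  CDF fits are least squares on the empirical CDF
at the event times, never on binned histograms.  The "mean" of a
multi-exponential fit is the amplitude-weighted component mean plus any
delay.

* **Binding events** are maximal intervals of FRET above the background
  noise threshold (4× the zero-state frame FRET SD, shared with the floor
  rule).  In the pipeline an event must also reach 1.5× the threshold at
  its peak — with a 4σ threshold, long traces still produce occasional
  single-frame noise crossings that would otherwise split zero-state
  dwells.  First and last events are eliminated (mixing time,
  photobleaching).
* **Association rate**: single-exponential CDF fit to the zero-state
  dwells between retained events, divided by the ternary-complex
  concentration.  Gaps containing donor-dark frames are discarded: a
  blink reads FRET 0 but the molecule is still bound.  Because ~95% of
  cognate events are productive and terminal, the uninhibited condition
  yields almost no between-event dwells; association is measured under
  hydrolysis block (GTPγS preset), where the same bimolecular step recurs
  — binding precedes hydrolysis, so the constant is the same.
* **Catalytic efficiency**: waiting times from trace start to the first
  accommodated-state visit; traces that bleach first enter as censored
  observations.  The mean arrival is taken from the Kaplan–Meier
  estimate of the arrival distribution (restricted mean plus a
  last-decile mean-excess tail completion).  A small survival plateau
  (≤ 10%, starting beyond 4× the arrival scale) is treated as the
  fraction of traces whose accommodated state is never labelled and the
  mean is computed conditional on detection; without this guard the ~1%
  labelling failures inflate the mean by ~3%.  The conventional
  two-exponential-with-delay fit is also computed and reported, but its
  mean is systematically high by 5–8% on delay-free data (the delay
  parameter soaks up the hypoexponential rise of a multi-step arrival),
  so the empirical mean is the primary estimate.  Efficiency is
  1/(mean × concentration).
* **Passage rate**: two-exponential CDF fit to the time from the start of
  the binding event directly preceding the first accommodation to the
  accommodation event (degenerate, near-deterministic inputs fall back to
  the empirical mean).
* **State lifetimes**: exponential MLE; censoring-aware mode uses total
  observed time over the number of observed terminations.
* **Transition rates**: the continuously-observed Markov MLE, transitions
  over time-in-state, on the idealized paths.  Steps into the target from
  an adjacent short-lived state can be credited to the physical source
  (`merge_from`): a GA→AC step landing mid-frame may leave the boundary
  frame labelled CR, and the scheme has no CR→AC edge; entries from the
  zero-FRET state (blink artefacts) stay excluded.

### Missed-event corrections

Dwells near the integration time are systematically distorted: ~10-ms CR
visits at 10-ms frames are detected only ~half the time, so consecutive
GA dwells merge (naive GTPγS GA lifetime ≈ 0.87 s instead of 0.62 s), and
when GA itself is short (37 °C) visible dwells are length-biased (naive
GA→AC ≈ −9%).  Closed-form dead-time corrections are fragile for
frame-integrated data, where visibility depends on how a dwell straddles
frame boundaries.  Both corrections therefore calibrate the full
generative + analysis chain on itself:

* `missed_event_corrected_lifetime` simulates small calibration datasets
  from the running parameter estimates over a grid of neighbour lifetimes
  (0.5–2.5 frames), matches the observed mean recorded neighbour duration
  to pick the neighbour lifetime (~10 ms is recovered), reads off the
  lifetime inflation factor and divides it out, iterating once.  Observed
  neighbour statistics cap dwells at 8 frames — a frame-time neighbour
  cannot genuinely dwell longer, and rare mislabelled traces would
  otherwise dominate the mean.
* `calibrated_transition_rate` runs the naive estimator on calibration
  datasets simulated at candidate values of the target rate (other rates
  taken from the scheme), fits the response line and inverts it at the
  observed naive value (indirect inference).

Both corrections use only quantities available to an analyst: the fitted
scheme, the known acquisition settings, and the data.

### Binding isotherm

Classical-state fractions come from a two-Gaussian mixture fit to the
pooled equilibrium FRET distribution; their standard errors come from the
spread of per-trace classical occupancies (or a bootstrap over traces) —
frames are strongly correlated in time, so fit-covariance SEs would be
~5× too small.  The isotherm
`f_c(L) = A_C5A (K_D + L) / (L + K_D·A_C5A/A_Capo)`
(limits `f_c(0) = A_Capo`, `f_c(∞) = A_C5A`, monotone) is fitted by
weighted least squares with parametric-bootstrap CIs; a flat response or
collapsed mixture modes raise errors rather than returning numbers.  In
the coverage study (8 concentrations spanning K_D, 300 traces each), the
true K_D lies inside the 95% CI in ≥ 90 of 100 replicates.

## Structural module

Atomic models are read with gemmi (PDB and mmCIF).  A bridge contact
point — one residue per subunit — is formed when any two non-hydrogen
atoms are within 4.0 Å (inclusive); bridge formation is the percentage of
points formed, and the change between two conformations compares
individual points, signed by net gain, so two models with identical
totals can show 100% individual change.  Unresolved residues are dropped
from denominators with a warning.  The packaged bridge list
(B2b, B2e, B7a, B8, eB8, eB13) is a fixture-scale placeholder: real
residue-level assignments are tied to a specific deposited numbering and
must be supplied by the user as TSV.

Buried surface area is SASA(receptor) + SASA(ligand) − SASA(complex)
with an in-package Shrake–Rupley SASA: 960 Fibonacci sphere points per
atom (doubling changes fixture BSA by < 1%), probe 1.4 Å, Bondi van der
Waals radii, hydrogens excluded.  The two-sphere fixture agrees with the
analytic spherical-cap area within 2%, and BSA is rigid-motion invariant
and decays to zero beyond contact range.

## Reproduction studies and problem sizes

`smdecode.reproduce` fixes the study conditions: 1000 traces × 40 s at
10-ms frames for the uninhibited 25 °C dataset (efficiency, GA→AC, FRET
means); 800 traces × 80 s at reduced bleaching (0.012 s⁻¹, the
long-recording condition) for the GTPγS dataset (association rate, GA
lifetime); 600 traces × 25 s for 37 °C; 100 replicate titrations for the
K_D coverage study.  These sizes keep each recovered constant's
uncertainty a few percent — comfortably below the experimental errors —
with the whole script finishing in a few minutes on one CPU.  Idealizer
accuracy is scored against ground truth on attributable frames (≥ 99%
single-state occupancy, before the first true bleach): frames straddling
a transition have no single true label, and frames after an undetected
acceptor bleach carry no signal.

## Known limitations

* Rate estimation is per-dataset dwell/transition statistics, not a
  global multi-trace likelihood optimization; the simulation-calibrated
  corrections recover the desk-scale targets but are not a general
  substitute for full missed-event likelihoods.
* The calibration corrections assume the scheme's non-target rates are
  approximately known (they are, from the complementary datasets);
  errors there propagate at second order.
* The titration module simulates at FRET level; it does not exercise the
  intensity-level pipeline.
* The structural module treats models rigidly: no superposition,
  refinement or map handling; BSA values depend at the few-percent level
  on the radii table and probe, so cross-software comparisons should use
  matched settings.
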