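# Methods

## Model

The reporter is a fluorescent (or NanoLuc) protein fused to a ligase
degron, expressed from a constitutive promoter. Its nuclear level R(t)
follows a synthesis–degradation balance

    dR/dt = s − k(t)·R,

where s (a.u./h) is constant and k (1/h) is the first-order degradation
rate constant set by the ligase. k is piecewise constant over cell-cycle
phases and drug epochs. The relative ligase activity is the degradation
flux A(t) = s − dR/dt = k·R (a.u./h); the level-normalized rate
k = A/R (1/h) is also reported, since flux depends on the instantaneous
reporter level. Flux is the default activity measure; both conventions
are exposed because the normalization choice is genuinely open.

Perturbations act as parameter switches with an optional onset lag:
cycloheximide sets s → 0 (translation block, so the decay reads out k);
MLN-4924 scales every k by a residual factor, default 0 (neddylation
block halts all Cullin-RING degradation, so the accumulation slope reads
out s); sunitinib scales k ×3 with a 1 h lag; mitogen withdrawal/
stimulation switch the effective phase to/from G0.

## Simulator

The trace generator integrates the ODE analytically per constant-
coefficient segment (R(t0+τ) = s/k + (R(t0) − s/k)e^{−kτ}; linear when
k = 0), so noiseless trajectories are exact and serve as oracles for
the inference. Frames are sampled every 0.2 h (12-min imaging cadence;
configurable). Defaults encode the study conditions: k_G1 = 0.2521 /h
(2.75 h half-life), k_S/G2 = 0.0770 /h (9 h half-life), s = 10 a.u./h.
Phase schedules cycle G1 (8 h) → S (6 h) → G2 (5 h) → M (0.6 h),
optionally lognormal-jittered, giving mitoses every ~20–24 h; a
G0-only spec gives quiescent cells. At division the daughter inherits
the mother's latent level (concentration is conserved); one daughter
continues the track by default, with full two-daughter lineages
available for tracking tests.

Measurement effects are applied on top of the latent trajectory:
an M-frame multiplicative spike (default ×1.8) emulating the apparent
intensity rise from cell rounding and nuclear-envelope breakdown — the
study describes this artifact only qualitatively, so the amplitude and
the M duration are free parameters here — and multiplicative lognormal
noise parameterized by its CV (fluorescence noise scales with signal;
the noise distribution has unit mean).

The image renderer fills elliptical nuclei uniformly, so the per-nucleus
median equals the trace value by construction; frames are
`bias × (background + signal)` with a strictly positive smooth bias
surface. The plate simulator reads wells 6 h after compound addition
from the reporter steady state, with per-compound k/s scalings, gain
and baseline chosen so the neutral median is ≈1000 a.u.; negative
(media-only) wells emit baseline only. The live/fixed pair generator
draws (activity, protein) from a bivariate normal with target
correlation ρ and affine marginals, and jitters fixed-cell centroids.

What the generator does *not* emulate: photobleaching, camera physics,
segmentation-confounding debris, cell death and overlap, focus drift,
or plate-edge effects. Passing recovery tests therefore demonstrates
estimator correctness under the stated kinetic model and noise, not
robustness to every artifact of real microscopy.

## Estimators and numerical choices

- **Bias field**: pixels below the per-frame 10th intensity percentile
  are pooled across sampled frames and fit with a 2nd-order 2D
  polynomial (normalized coordinates, least squares), normalized to
  unit mean. Low order prevents the surface from absorbing signal.
  Correction is `frame / bias − background`, background = 5th
  percentile of the flattened frame; output is not clipped.
- **Segmentation**: Gaussian smoothing (σ = 2 px) → Otsu threshold →
  area filter (40–10 000 px) → distance-transform watershed with
  smoothed-distance peaks (min separation 7 px) to split touching
  nuclei. Empty frames yield empty label maps.
- **Tracking**: greedy mutual-nearest-centroid linking within
  `max_disp`; divisions are detected when a parent's second daughter
  appears as an orphan object within 1.5×`max_disp` of the parent one
  frame later (either with the parent otherwise unmatched and two
  orphans nearby, or with the parent already linked to one daughter).
  A heuristic, configurable; it reproduces simulated lineages but is
  not a globally optimal tracker.
- **Phase annotation**: S entry is the first frame where the Geminin
  signal exceeds baseline + 0.2×(max − baseline) within the
  inter-mitosis segment and rises for ≥3 consecutive frames. The
  threshold rule necessarily lags true S entry by the time Geminin
  needs to clear the threshold (~2 h at default parameters); the
  annotated labels are M / G1 / SG2 because Geminin cannot separate S
  from G2.
- **Synthesis rate**: per-cell least-squares slope of R(t) from the
  MLN-4924 effective onset to trace end; population s = median of
  slopes. Cells whose late-half slope drops below 0.9× the early-half
  slope are flagged for residual degradation (slope then underestimates
  s). The population median is applied to all cells by default;
  per-cell conversion is available.
- **Derivative/activity**: dR/dt at each frame is the slope of a
  centered local linear fit over 5 frames (1 h), computed by windowed
  least squares that skips masked frames; windows with <3 valid points
  propagate NaN. The window suppresses frame noise without blurring
  drug-response onsets. A is not clipped at zero — negative values flag
  noise or unmodeled synthesis changes. Mitosis frames ±2 frames
  (24 min) are masked before differentiation.
- **Half-life**: log-linear least squares of ln R vs t over the
  post-cycloheximide window (variance-stabilizing under multiplicative
  noise, and linear regression is unbiased there). Non-positive
  intensities are dropped (error if >10% of the window); a non-positive
  fitted k is reported as no-decay with t½ = ∞, never silently.
- **Percent activity**: PA = 100·(lum − med_neutral)/(med_neutral −
  med_negative), medians computed within each plate (robust to
  plate-to-plate gain drift). Signs follow the control behaviour:
  degradation block raises luminescence, so PA > +50 (strict) is an
  inhibitor hit and PA < −50 an activator hit.
- **Dose–response**: 4-parameter logistic fit by Levenberg–Marquardt
  from the best of a grid of starts (log-spaced IC50 over the dose
  range × Hill ∈ {0.5, 1, 2, 4} × both orientations). Curve classes are
  reduced to {converged, non_converged, flat, incomplete_curve
  (IC50 outside [min dose/10, max dose×10])}. Titrations default to 11
  points from 13 µM at 1:3.
- **Correlation**: Spearman by default (immunofluorescence intensity is
  an unknown monotone transform of abundance); Pearson available.
  Bootstrap percentile 95% CIs, 2000 resamples, seeded. Per-cell
  "activity" for the live/fixed comparison is the median inferred A
  over the final 2 h of imaging.
- **Folds**: fold of group medians with a seeded bootstrap CI; IC50
  fold shifts propagate uncertainty by residual resampling and
  refitting.

## Benchmark experiments

`ligaseflux.benchmarks` packages the desk-scale recovery experiments:

- **CHX-chase half-lives** — 200 traces per condition, decay constants
  0.2521 and 0.0770 /h, 8 h and 24 h chases respectively (≈3 and ≈2.7
  half-lives of data), 5% CV noise. The median fitted half-life
  recovers ln 2/k (2.75 h and 9 h).
- **Population activity fold** — two populations with k differing 3:1
  at matched steady-state reporter levels (each population's s = k ×
  level, so levels match while fluxes differ by the k ratio). s is
  inferred from each population's own MLN arm (30 cells), activity from
  60 cells each; the fold of median activities recovers the 3:1 ratio.
  With a *shared* s both populations would converge to identical
  steady-state flux (A = s), so matched levels via per-population
  synthesis is the condition under which the fold reflects the k ratio.
- **IC50 fold shift** — paired 11-point titrations with generating
  IC50s 0.5 and 0.1 µM, 5% CV response noise, 20 replicates; the median
  fitted fold recovers 5.

Cohort sizes (200/60/30 cells, 20 replicates) are the package's chosen
benchmark scale: large enough that median estimators are stable to a
few percent, small enough to run interactively.

## Known limitations

- The derivative window biases A near sharp kinetic switches (onset
  frames mix pre/post slopes); masked-frame gaps widen this locally.
- The finite-difference check of the ODE holds to O(Δt²) (~0.1% at
  k ≤ 0.5 /h), not machine precision; exactness is asserted via the
  closed-form propagator instead.
- The tracker is frame-local and greedy; it is validated on simulated
  divisions, not crowded real movies.
- Percent-activity orientation and the curve-class taxonomy follow the
  assay's control behaviour and a reduced four-class scheme; screening
  pipelines with richer curve grammars will classify borderline curves
  differently.
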