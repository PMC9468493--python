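# Methods

This note records the model, the numerical scheme, the default settings and
the design choices behind `cainfer`, together with what the synthetic
benchmark does and does not demonstrate.

## Kinetic model

The evolution function is a Li-Rinzel-type model of IP3-receptor-mediated
calcium exchange between cytosol and ER, extended with calcium-dependent
IP3 production and first-order IP3 decay (the Nadkarni-Jung formulation
commonly used for astrocytes). State variables: cytosolic calcium C_CS
(uM), InsPR recovery variable q (dimensionless, in [0, 1]), IP3
concentration p (uM). ER calcium is eliminated through conservation of the
total cell calcium: c1*C_ER + C_CS = C0*(1 + c1), so the model's domain is
0 <= C_CS <= C0*(1 + c1).

Default parameter values (uM, s):

| symbol | meaning | value | free in inversion |
|---|---|---|---|
| v_s | max SERCA rate | 0.9 uM/s | yes |
| C0 | total cell calcium | 2 uM | no |
| v2 | ER leak rate constant | 0.11 /s | yes |
| k_s | SERCA half-activation | 0.1 uM | yes |
| a2 | InsPR inactivation coefficient | 0.2 /(uM s) | no |
| d1, d2, d5 | InsPR dissociation constants | 0.13, 1.049, 0.08234 uM | no |
| v1 | max InsPR flux rate | 6 /s | yes |
| c1 | ER/cytosol volume ratio | 0.185 | no |
| tau | IP3 lifetime | 7.14 s | yes |
| p0 | baseline IP3 | 0.16 uM | no |
| v_p | max IP3 production rate | 0.13 uM/s | yes |
| k_p | IP3 production half-activation | 1.1 uM | no |

The six free parameters are the "extensive" rate constants that scale with
expression levels of the corresponding proteins; the dissociation constants
and geometric/stoichiometric constants are intrinsic and held fixed.
The table prints a2, d1, d2, d5 and k_p without units in the source
literature; we adopt uM (and 1/(uM s) for a2) as the assignment that makes
the rate equations dimensionally consistent.

With these defaults and the prior-mean initial state (0.1 uM, 0.5, 0.5 uM)
the system produces a sharp initial calcium spike (to ~1.5 uM within a
second) relaxing onto a stable plateau near 1.24 uM; IP3 settles around
0.74 uM, outside the sustained-oscillation window, so the default
trajectory is a transient rather than a limit cycle.

## Integration

Dynamics are integrated by explicit forward Euler on a "microtime" grid
finer than the acquisition grid: frames of `frame_dt` = 1 s are covered by
`frame_dt/micro_dt` sub-steps with `micro_dt` = 0.1 s by default. The
system is comparatively stiff during spikes; after every sub-step the state
is clamped to its physical domain (C_CS into [1e-9, C0(1+c1) - 1e-9] uM, q
into [0, 1], p >= 1e-9 uM), and clamp events are counted and logged. An
additional purely numerical ceiling caps p at 1e4 uM — far above any
physical value — so that float overflow cannot occur when line searches
probe extreme rate constants. Accuracy is checked against classical RK4 at
a 1e-3 s step: over a 10 s horizon from the prior-mean state the Euler
scheme agrees within 1% per component (the error peaks at a few percent on
the calcium component mid-spike around t = 1 s and contracts afterwards).
Raising `micro_dt` above 0.1 s is not recommended.

## Observation model

Fluorescence is an instantaneous hyperbolic function of cytosolic calcium,
g(C_CS) = kappa_F*C_CS/(C_CS + K_d) + d_F, with K_d = 0.167 uM (167 nM,
GCaMP6m). kappa_F and d_F absorb per-recording gain and background and are
inferred per trace. Indicator binding/unbinding kinetics, fluorescence
decay time, photobleaching and baseline drift are deliberately outside the
model; on the multi-second timescale targeted here the instantaneous
approximation is the standard choice, and a decay term is the natural next
extension. Internally all calcium quantities are uM; interfaces that quote
the dissociation constant in nM (`ObservationParams.with_kd_nanomolar`,
the `k_d_nm` config key) convert on entry to avoid silent 1000x errors.

## Inversion

The generative model is the deterministic evolution plus additive mean-zero
Gaussian disturbances: state noise eta ~ N(0, alpha^-1 I) per frame
(applied at frame resolution, isotropic over the three state dimensions)
and measurement noise eps ~ N(0, sigma^-1). The approximate posterior
factorises as Q(states) x Q(parameters) x Q(alpha) x Q(sigma), Gaussian for
the first two blocks and gamma for the precisions.

The inversion vector has 11 entries: the initial state (identity scale,
priors N(0.1, 0.05) uM, N(0.5, 0.2), N(0.5, 0.2) uM), the six free rates
(log scale: physical value = prior mean x exp(xi), xi ~ N(0, 2)), and the
observation scale/offset. The exponential transform guarantees positivity;
the value 2 is read as a variance of the dimensionless exponent. Posterior
means are reported on the physical scale by plug-in transform of the
posterior mode (prior_mean * exp(mu)), with delta-method variances.

Observation-parameter priors are data-scaled so the scheme is indifferent
to the arbitrary fluorescence units. Because the indicator never traverses
its full dynamic range, the observed trace range underestimates kappa_F;
over typical calcium excursions (~0.1-1.5 uM at K_d = 167 nM) the
saturation s = C/(C+K_d) spans roughly 0.35-0.85, i.e. about half the unit
interval. The priors therefore centre kappa_F on twice the trace range and
d_F on the trace minimum minus 0.7x the range (the implied baseline
contribution kappa_F*s_min), both with variance (2*range)^2. Centring
kappa_F on the raw range instead provably biases the fit along the
kappa_F-kinetics degeneracy valley (in our benchmark, +48% group bias on
v_s). Flat traces fall back to a small positive scale floor.

Moments are updated by Gauss-Newton iteration on the parameter block:
gradients and curvatures come from central finite differences of the
forward prediction (relative step 1e-4) for the nine trajectory-shaping
entries, and analytically for the scale/offset (the prediction is affine in
them). A candidate step that lowers the free energy is halved, up to 8
times, before the iteration is abandoned; the measurement-precision gamma
moments are re-updated conjugately at every candidate. The reported
free-energy sequence therefore cannot decrease. Iteration stops when the
free-energy gain falls below 0.02 nats (default) or after 100 iterations.
Non-finite intermediate quantities mark the run diverged-and-rejected
instead of raising, so batch runs never abort on a pathological trace.

The state block is computed at the optimum by an extended Kalman filter
with a fixed-lag smoother: each state estimate uses at most `update_lag`
(default 2) subsequent observations, keeping cost linear in trace length.
State-transition residuals of the smoothed path update the gamma posterior
of the state-noise precision alpha; three fixed-point passes of
filter-then-update are run. Driving the Gauss-Newton step acceptance on a
free energy that includes the state-entropy terms stalls the optimisation
(the state terms mask data-fit progress), which is why the iteration is
driven by the parameter/measurement-block bound and the state block is
refined afterwards; the per-iteration free energies reported in
`PosteriorSummary` are those of the driving bound.

Precision hyperpriors default to gamma(shape = 1e-3, rate = 1e-3) for both
alpha and sigma — weakly informative and scale-free. A gamma(1, 1) default
was rejected: with arbitrary fluorescence units the rate term dominates the
posterior rate whenever residuals are numerically small, capping the
inferred measurement precision near n/2 independently of the actual noise
and visibly biasing noiseless fits.

Acceptance follows the positive-state-noise-precision rule: a run is
accepted iff its alpha estimate is finite and strictly positive (with the
gamma parameterisation this fails only on divergence, matching the
observation that rejections stem from stiffness of the kinetics rather
than from lack of fit). R^2 of the predicted trace is reported as a
diagnostic; for constant traces (zero observed variance) it is NaN rather
than an error.

## Synthetic data

`generate_trace` forward-simulates the kinetics, optionally adds per-frame
Gaussian state noise (off by default — the "generator" for real data is
the cell itself), maps through the observation function and adds i.i.d.
Gaussian observation noise. `generate_cohort` draws per-ROI free
parameters log-normally (sd 0.1 of the log) around group means, with
optional multiplicative group effects, and derives per-trace sub-seeds
deterministically from the master seed (bitwise reproducible). Defaults
emulate the targeted acquisition: 180 frames at 1 Hz, observation noise sd
equal to 2% of the noiseless trace range, observation scale 1.0 and offset
0.1 (arbitrary units), initial state at the prior means.

What the synthetic benchmark shows: the inversion recovers the generating
parameters essentially exactly from noiseless traces, tracks a 1.5x SERCA
shift in the majority of noise replicates, keeps rejection at 0% across
seeds, and the group layer is calibrated. What it does not show: real
astrocyte recordings contain richer spontaneous oscillations, drift,
motion and extraction artefacts absent from the generator, and the
deterministic default trajectory (single transient onto a plateau)
compresses kinetic information into a few tens of frames. Single-trace
estimates of v_s under 2%-of-range noise have a standard deviation around
0.35 uM/s — an identifiability limit of the saturating indicator (an exact
MAP oracle given the true noise precision scatters at least as much), which
is why per-ROI estimates are treated as noisy individual measurements and
inference about conditions runs through the group layer.

## Statistics layer

Accepted per-ROI posterior means are treated as individual measurements.
Groups are summarised by mean and standard error (sd/sqrt(n)) per free
parameter; rejected runs are excluded from statistics, counted in the
rejection rate, and listed in a side log by the CLI. Group contrasts use
the two-sample two-sided Kolmogorov-Smirnov test with asymptotic p-values
(exact small-sample computation behind a flag), uncorrected across the six
parameters by default to match per-parameter reporting; a Bonferroni flag
is available. On null cohorts (n = 20 per group) the measured type-I rate
is 4% over 200 repetitions, consistent with the nominal 5%.

## Problem sizes of the shipped benchmarks

The reference cohort is 20 traces of 180 frames (master seed 42 in the
test suite; the acceptance script takes the seed from the command line).
Recovery tests use one noiseless trace plus 30 noise replicates of the
shifted-SERCA trace; KS calibration uses 200 null repetitions at the
statistics layer with direct parameter draws, which reuses the generator's
jitter distribution and costs no inversions. These sizes were chosen as
the smallest that make the corresponding properties statistically stable.

## Known limitations

- Forward Euler at 0.1 s carries a few-percent local error at spike onsets;
  conclusions that hinge on sub-second spike shape need a finer micro-step.
- The fixed-lag smoother and the plug-in transition residuals approximate
  the state posterior; alpha is a diagnostic of dynamics/data consistency
  rather than a sharply calibrated noise estimate.
- kappa_F and d_F are only weakly identified from traces that stay deep in
  indicator saturation; their data-scaled priors then dominate.
- No model comparison across alternative kinetic models, no inference of
  the fixed constants, no indicator decay term.
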