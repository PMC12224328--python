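# Methods

This note records the models implemented in `nanocascade`, the
assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate.

## Cascade kinetics

**Model.** One catalyst carries two activities: glucose + O₂ → H₂O₂ +
gluconic acid (Michaelis–Menten production law P) and 2 H₂O₂ → 2 H₂O +
O₂ (Hill decomposition law D).  The state is (G, H) in mM with time in
minutes:

    dG/dt = −P(G)·(C/C_ref)^a        (or 0 with a continuous supply)
    dH/dt =  P(G)·(C/C_ref)^a − D(H)·(C/C_ref)^b

with C the catalyst loading (mg/mL) and a, b the catalyst-scaling
exponents of the two reactions.  O₂ and gluconolactone/gluconic acid
are not tracked; pH and temperature dependence are out of scope.

**Catalyst exponents.** If both reactions scaled identically with
catalyst (a = b) the pseudo-order steady state k₁/k₂ would be
catalyst-independent, which contradicts the observed linear growth of
steady-state H₂O₂ with loading.  The physical picture is that at a few
mM glucose the production reaction runs near catalyst saturation
(substrate above Kₘ, rate limited by catalyst) while decomposition runs
far below K₀.₅ (rate limited by substrate), so decomposition responds
more weakly to added catalyst.  Both limits are exposed: a = b = 1
reproduces exact cancellation, b = 0 pure production scaling; the
default (a = 1, b = 0.5) gives the qualitative monotone behavior.  Any
quantitative claim should set the exponents from its own data.

**Pseudo-order reduction.** k₁ = P(G)·(C/C_ref)^a at the working
glucose; k₂ = Vmax_dec·(C/C_ref)^b / K₀.₅, the slope of the
decomposition law at H → 0.  The reduction is exact only for Hill slope
h = 1; for h ≠ 1 the same formula is returned with a warning flag
because a sigmoidal law has no first-order limit (its slope at the
origin is 0 for h > 1).  The closed-form relaxation
H(t) = (k₁/k₂)(1−e^(−k₂t)) + H₀e^(−k₂t) matches the full ODE to <1%
only when the steady state sits well below K₀.₅ (H_ss ≲ 0.01·K₀.₅);
tests exercise exactly that regime.

**Initial rates.** Assays measure remaining substrate after 3, 6 and
9 minutes.  Consumed substrate (c₀ − c(t)) is regressed on time
*through the origin* (consumption is definitionally zero at t = 0),
slope = Σt·y/Σt², and the t = 0 concentration labels the rate point.  A
course with rising substrate yields a flagged point, not an error.

**Fits.** Nonlinear least squares (`scipy.optimize.curve_fit`) with
v_max₀ = 1.2×max rate, K₀ = substrate nearest half-max rate, h₀ = 1.5,
bounds all-positive and h ∈ (0.1, 10].  Michaelis–Menten needs ≥3
distinct concentrations, Hill ≥4 (3 with h fixed).  Non-convergence is
reported as an explicit failed `FitResult`, never as silent defaults.
Standard errors are asymptotic (from the Jacobian), R² on the rate
scale.

**Integration.** `solve_ivp` (LSODA) at rtol 1e-8 / atol 1e-10 mM, with
rates evaluated on the nonnegative part of the state and the output
clipped at 0.  Steady state in a scan is declared when |dH/dt| <
1e-6 mM/min at the end of the integration window.

## Trajectory analysis

**Drift correction.** The ensemble-mean frame-to-frame displacement
over all tracks present in consecutive frames is accumulated into a
drift path subtracted from every track.  This estimator is robust to
heterogeneous track lengths (unlike averaging per-track velocities);
frame transitions with fewer than 3 simultaneous tracks get their
increment interpolated from neighbors and a warning.  The operation is
idempotent, and a single track is returned unchanged because common
motion is then unidentifiable.

**MSD.** Per track, the time-averaged MSD over all ordered pairs at
each lag (overlapping windows); the ensemble curve is the unweighted
mean over tracks with SEM across tracks.  A track-length-weighted mean
is deliberately not the default: the study design has near-uniform
track lengths, and unweighted averaging keeps each particle one unit of
evidence.  Dimensionality is fixed at 2 (in-plane dark-field tracking),
so D_eff = slope/4.

**Diffusion fit.** Ordinary least squares of mean MSD on lag over
(0, 1 s] by default — short-lag fitting keeps the estimate in the
regime where time-averaged MSD points are least correlated and least
biased by localization error; the intercept is left free to absorb that
offset.  The slope's uncertainty is *not* taken from OLS residuals:
successive points of a mean MSD curve are strongly positively
correlated, which makes the residual-based standard error badly
miscalibrated.  Instead the same OLS coefficient vector is applied to
each per-track MSD curve and the slope's standard error is the
between-track SEM of per-track slopes, with a t-interval (n−1 df).
Simulated-ensemble coverage of the resulting 95% CI is ≈94% (measured
over 200 replicate ensembles of 100 tracks × 20 s; coverage is a
per-ensemble property and does not depend on ensemble size, which is
why the replicate check runs below the full 250 × 60 s study scale).
A negative fitted slope is reported as-is with a flag, never clamped.

**Profile shift.** The co-flow shift statistic is the difference of
intensity-weighted centroids of the condition and control profiles on a
common grid, restricted to an analysis window when one is set.  A
centroid was preferred over half-maximum crossings for noise
robustness; on a pure translation both agree.  Sign convention: the
lateral coordinate increases toward the solute inlet, so positive
shifts mean migration toward the solute.

## Cell analytics

**Motility.** net displacement |r(T)−r(0)|, total path length Σ|Δr|,
directionality = net/total (defined as 0 for a stationary track), mean
speed = total/elapsed, mean velocity = net/elapsed.  Population tables
report mean ± SEM for displacement and distance and mean ± SD for the
ratio/rate metrics, the error conventions usual for such tables.

**Circularity.** 4πA/P² on a single connected component, clipped to 1.
The perimeter comes from the marching-squares contour smoothed with a
σ = 1.5 px Gaussian along the polyline: the raw contour's pixel
staircase inflates the length of smooth boundaries (a rasterized disc
would otherwise score ≈0.91), while σ = 1.5 px only slightly rounds
true corners (a square scores 0.80 vs the ideal π/4 ≈ 0.785).

**Gap closure.** Gap area = foreground pixel count × pixel_size², and
the series is normalized to 100% at t = 0, making the relative series
pixel-size-invariant.  `segment_gap` is a minimal texture pipeline
(local variance → Gaussian smoothing → Otsu threshold → largest
low-texture component) provided as a coarse stand-in for interactive
wound-healing segmentation tools; it is adequate for synthetic and
high-contrast images, not a re-implementation of any particular tool.

**Dry mass.** m = φ·λ/(2π·α) per pixel, total = Σm·pixel_size², with
α = 0.18 μm³/pg as the default specific refraction increment of
cellular dry matter and λ the imaging wavelength in μm.

**Doubling time.** Linear regression of log₂(value) on time;
doubling time = 1/slope, CI propagated from the slope's 95% CI
endpoints.  The log-linear form is exactly equivalent to a direct
exponential fit on noiseless data, variance-stabilizing under
multiplicative noise, and has a closed-form CI; the method is recorded
in the fit metadata.  A non-positive slope returns a flagged
"no growth" result with infinite doubling time.

## Synthetic data

The generators emulate the statistical structure the analyses assume,
at the study's acquisition settings:

- **Assay time-courses**: the cascade ODE sampled at 3/6/9 min with
  additive Gaussian measurement noise, clipped at 0.
- **Particle tracks**: exact 2D Brownian increments (variance 2DΔt per
  axis) at 25 fps for 60 s, plus optional uniform drift; no
  localization error, gaps or blinking.
- **Co-flow profiles**: a central plug with error-function edges
  (diffusion-broadened laminar streams), translated by the true shift
  and unit-normalized.
- **Cell tracks**: persistent random walk with fixed step length
  speed·Δt and von Mises heading increments whose concentration κ
  solves I₁(κ)/I₀(κ) = e^(−Δt/P), giving exponential heading
  decorrelation with time constant P (default 2 h, a typical
  fibrosarcoma persistence; sampling every 30 min for 24 h).
- **Gap masks**: a central band of width max(0, g₀ − rate·t) (defaults
  500 μm closing at 25 μm/h) with Gaussian edge roughness smoothed over
  10 rows.
- **Growth series**: n₀·2^(t/T_d) with optional relative ("5%")
  Gaussian noise, floored at a small positive value.
- **Phase maps**: disc cells with φ = 2πα·m/λ (the dry-mass relation
  inverted); overlapping discs add.

Noise magnitudes are conventions (experiments report replicate SDs, not
a noise model): 3% relative noise on rates and 5% on growth values are
used throughout the tests.  One top-level seed feeds independent
per-generator streams (CRC-tagged `SeedSequence`), so every output is a
pure function of (parameters, seed).

**What passing tests show — and don't.** Parameter recovery on these
generators verifies the estimators against data that satisfy their
assumptions exactly.  Real instrument data add localization noise,
track fragmentation, segmentation error, uneven illumination and
biological heterogeneity, none of which are simulated; the tests
validate the analysis chain, not instrument robustness.

## Problem sizes

Default test and script runs use 100–250 tracks of 20–60 s, 100
fit-recovery replicates, 200 coverage replicates, and ODE scans over
4–5 catalyst loadings; the full suite runs in well under a minute on
one CPU, and `scripts/acceptance.py` in a few seconds.

## Known limitations

- The catalyst-scaling exponents are a phenomenological bridge between
  the cancellation argument and the observed linear steady state, not a
  surface-site microkinetic model.
- The first-order reduction of the sigmoidal decomposition law is a
  convenience valid only near h = 1 and H ≪ K₀.₅.
- `profile_shift` measures translation of a conserved profile; strong
  shape changes between condition and control (e.g. focusing) would
  bias a centroid statistic.
- The motility summaries assume complete, uniformly sampled tracks;
  no gap-closing or track-linking is performed.
- MTS viability analysis, particle detection/linking from video,
  holographic phase reconstruction and flow CFD are out of scope.
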