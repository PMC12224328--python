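# nanocascade

Quantitative analysis pipeline for experiments on glucose-powered
Au–SiO₂ nanozyme particles ("nanorobots") and their effects on cells.
The particles carry out a two-step cascade on one surface — a
glucose-oxidase-like reaction producing H₂O₂ and a catalase-like
reaction decomposing it — and the pipeline covers the four quantitative
questions such experiments pose:

1. **Cascade kinetics.** Glucose oxidation follows hyperbolic
   Michaelis–Menten kinetics, v = V·S/(Kₘ+S), while H₂O₂ decomposition
   is sigmoidal (Hill / allosteric), v = V·Sʰ/(K₀.₅ʰ+Sʰ), with
   half-saturation constants two orders of magnitude apart
   (Kₘ ≈ 2.9 mM vs K₀.₅ ≈ 155 mM).  With a constant glucose supply the
   production of H₂O₂ is pseudo-zero-order (k₁) and its decomposition
   first-order (k₂), so d[H₂O₂]/dt = k₁ − k₂[H₂O₂] and the bulk
   concentration stabilizes at **[H₂O₂]ₛₛ = k₁/k₂** — a steady state
   tunable through the catalyst loading when the two reactions scale
   differently with it.  The package fits both rate laws to
   initial-rate data, integrates the full cascade ODE, and scans the
   steady state across catalyst loadings.

2. **Enhanced diffusion.** Nanoparticle-tracking trajectories (25 fps,
   60 s, ≥250 tracks per condition) are drift-corrected, their
   time-averaged mean squared displacement MSD(τ) = ⟨|r(t+τ)−r(t)|²⟩ is
   ensemble-averaged, and the first second of the curve is fitted with
   a line whose slope/4 is the in-plane effective diffusion coefficient
   D_eff, with a 95% CI from the between-track scatter.

3. **Diffusiophoresis.** In a three-inlet co-flow channel, migration of
   fluorescent particles toward or away from a solute gradient appears
   as a lateral shift of the intensity profile; the shift statistic is
   the difference of intensity-weighted centroids of condition and
   control profiles.

4. **Cell migration and proliferation.** Wound-healing gap closure
   (percent of initial gap area), random-walk motility summaries
   (net displacement, path length, directionality = net/total, speed,
   velocity), shape circularity 4πA/P², quantitative-phase-imaging dry
   mass m = φλ/(2πα) with α = 0.18 μm³/pg, and exponential doubling
   times fitted on log₂(value) vs time.

No instrument data are required: a seeded synthetic module
(`nanocascade.synthetic`) generates every input — cascade assay
time-courses, Brownian tracks with optional drift, error-function
co-flow profiles, persistent-random-walk cell tracks, closing gap
masks, growth series and phase maps — so the whole pipeline is testable
end to end.

## Worked example

The repository ships a demo configuration that synthesizes one dataset
of each kind and analyzes it:

```sh
nanocascade run --config examples/demo_config.yaml
```

From `results/demo/manifest.json` (seed 7):

- `analyze-tracks`: `d_eff_um2_per_s: 19.97`, `ci95: [18.55, 21.40]` —
  60 simulated Brownian tracks at D = 21.19 μm²/s; the fitted D_eff is
  within sampling error of the generative value and the CI brackets it
  (the demo uses a small ensemble; at the study scale of 250 tracks ×
  60 s the estimate tightens to ≈1%).
- `analyze-profiles`: `lateral_shift_um: 214.4` — the generator
  displaced the profile by exactly 214.4 μm, the shift measured for a
  glucose gradient in water; the centroid statistic recovers it to
  sub-grid precision.
- `analyze-gap`: `relative_area_percent: [100, 70.2, 40.1, 9.6, 0]` —
  a 500 μm gap closing at 25 μm/h; at 12 h the expected value is
  (500−300)/500 = 40%.
- `analyze-growth`: `doubling_time_h: 17.38`, `ci95: [15.15, 20.38]` —
  growth generated at 16.8 h with 5% measurement noise on 7 samples.
- `analyze-motility`: mean `total_distance` 240 μm for cells moving at
  10 μm/h for 24 h, with net displacement ≈85 μm — persistent random
  walkers wander, so directionality is well below 1.

Each subcommand (`simulate`, `fit-kinetics`, `analyze-tracks`,
`analyze-profiles`, `analyze-motility`, `analyze-gap`,
`analyze-growth`) also runs standalone; see `nanocascade --help`.

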