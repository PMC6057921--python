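# Methods

This note documents the models, conventions and numerical choices
behind `tirfkin`, and what the synthetic-data generator does and does
not emulate.

## Observation model for dwell times

A single molecule binds its target at a continuous time t₀ and stays
bound for a duration T. The camera samples the field at acquisition
instants k·Δt; exposure (tens of ms) is short relative to Δt, so a
molecule is treated as "present in frame k" iff it is bound at the
instantaneous time k·Δt. Because binding chemistry is asynchronous with
the frame clock, the start phase t₀ mod Δt is uniform on [0, Δt). Three
consequences define the data the fitting module sees:

* the recorded dwell is (number of covered instants) × Δt, always an
  exact multiple of Δt;
* events covering fewer than `min_frames` instants (default 1) are
  never detected — for an exponential dwell with mean τ the detection
  probability is C(τ) = (τ/Δt)(1 − e^(−Δt/τ));
* events still bound at the final recorded instant are right-censored.
  The recording-end convention is not dictated by the observation model
  itself; both censoring (default) and dropping are implemented, and
  censored events enter every likelihood as survival terms.

## Likelihoods and estimators

Two estimators are exposed because published descriptions of
dwell-time fitting rarely state how frame quantization was treated.

**naive** — treats dwells t = k·Δt as exact draws from the continuous
exponential (mixture) density, censored events as survival terms. For a
single exponential, τ̂ = Σt / n_uncensored. This estimator is biased
upward: undetected sub-frame events truncate the left tail and each
recorded dwell is rounded to whole frames. On a 0.46 s process the
inflation is ~30% at Δt = 0.25 s and ~2.5× at Δt = 1 s — the package's
property tests pin this direction and its growth with Δt, which matches
the qualitative contrast seen when the same molecule is measured at
different frame rates.

**phase_marginalized** (default) — models the frame count directly.
Marginalizing the uniform start phase and conditioning on detection
gives a geometric law P(K=k) = (1−q)q^(k−1) with q = e^(−Δt/τ) and the
closed-form MLE τ̂ = Δt/ln(k̄/(k̄−1)); with right censoring,
q̂ = S/(S+n_u) where S = Σ(k−1). For the two-exponential mixture each
component carries its detection probability:

    P(k | detected) ∝ (1−a)·C(T_s)·Geom(k; q_s) + a·C(T_l)·Geom(k; q_l)

so the fitted amplitude `frac_long` = a is the long component's share
of *underlying* binding events. This makes the estimator unbiased under
the generator's own convention, which is what the parameter-recovery
tests require. The long component's share of *detected* events is larger
(multiply the amplitudes by C(τ) and renormalise); at Δt = 0.15 s a
13% underlying share corresponds to ≈15% of detected events. We report
the underlying amplitude because it is the physically meaningful
mixture weight; the detected-share is one line of algebra away.

**Boundary and degenerate cases.** An all-ones uncensored sample puts
the geometric MLE on the q = 0 boundary; τ̂ is then reported at a lower
bound of Δt/50 with a warning. A sample that is wholly right-censored
cannot be fit.

**Mixture optimisation.** L-BFGS-B on (log T_short, log T_long,
logit a), bounds 10⁻³Δt–10⁶Δt on the components, convergence tolerance
1e−12 on the scaled objective. Ten starts by default: method-of-moments
(lower-half mean / top-decile mean), multiples of the single-exponential
τ̂, a near-degenerate start on the single-exponential ridge (which
guarantees loglik(2exp) ≥ loglik(1exp) by nesting), and seeded
log-uniform jitter. Components are reported in canonical order
T_short < T_long; bootstrap replicates inherit the ordering before SEs
are aggregated, which resolves label switching. Bootstrap refits
warm-start from the point estimate with a single start; full-size
problems (n ≈ 1000–5000) run 1000 mixture bootstrap replicates in a few
seconds.

**Model choice.** `compare_models` reports AIC with p = 1 vs 3; the
single exponential wins ties, matching the convention of fitting one
exponential unless the survival curve demands two.

**Survival curves.** S(t) = P(dwell ≥ t) evaluated on the frame grid;
with censoring the Kaplan–Meier product limit is computed directly
(deaths at t reduce the curve just after t). `lifelines` is used as an
independent cross-check in the test suite, not as the implementation.

## Site statistics

Binding frequency divides event starts in a 1.14 µm² detection box by
the box's available time (total minus the union of occupied intervals —
overlaps are merged before subtraction). Occupancy is total bound time
over n_sites × observation time, clipped at 1, with 370 sites/µm of
filament side and 1 site per branch junction (both configurable).
Occupancy refers to labeled molecules by default; an optional
`labeled_fraction` rescaling is off by default. The
occupancy-conservation identity occupancy × n_sites × observation =
total bound time holds exactly and is asserted in tests.

## Event extraction

The spot detector (local maxima above mean + k·SD, intensity-weighted
centroid within the spot radius) and the greedy nearest-neighbour
tracker are intentionally minimal: they exist to close the loop
simulate → render → detect → fit on synthetic movies, not to compete
with production particle trackers. Greedy frame-to-frame assignment is
adequate for the sparse fields the generator produces and degrades when
concurrent events overlap spatially; the round-trip test therefore pins
≥95% recovery of ≥2-frame events with <5% spurious tracks in a sparse,
high-SNR regime (SNR ≥ 5). Colocalization uses a default radius of one
pixel — a declared convention, since "spatial overlap" criteria in
image-analysis suites are tool-specific. The detection box is a square
of area 1.14 µm² centred on the target; branch boxes take priority over
filament-side proximity where they overlap.

## Photobleaching steps

Greedy binary segmentation adds the change point with the largest RSS
reduction while it improves BIC = n·ln(RSS/n) + 2m·ln(n), followed by a
backward-elimination pass that removes any boundary whose deletion
lowers BIC (greedy insertion can drop a boundary inside a level and
then legitimately refine both halves; pruning repairs this). Only
downward level changes count as steps. Two fluorophores bleaching in
the same frame are counted once — a limitation shared by any step
counter and quantifiable from the geometric bleach-time model (about 1%
of dimer traces at the default bleach rate of 0.02/frame). The penalty
constant 2 is a repository convention chosen for exactness on noiseless
traces and ≥95% accuracy at step/noise ratio 5.

## Branch dynamics and bulk assays

Cumulative branching counts appearances per FOV (default area
18,000 µm²) on a time grid, averaged across FOVs with SEM. Debranching
survival starts the clock at flow-in, treats branches surviving the
window as right-censored (they survive through the whole window in the
per-trial curves) and averages trial curves with SEM; on uncensored
data the curve equals 1 − ECDF exactly. Elongation rates are OLS slopes
in µm/s, optionally ×370 subunits/µm. Pyrene curves are shifted so the
mean of the first 5% of points is 0; a curve is plateaued when the OLS
slope over its final 10% of points is below 1% of the curve range per
100 s (a pinned, configurable convention), plateaued curves are scaled
to 1, and non-plateaued curves are scaled by the mean raw plateau of
the plateaued set — if nothing plateaus that fallback is inapplicable
and an error names it.

## Gel stoichiometry

Per-species standard curves I(c) = b₁c + b₂c² with no intercept (the
curve passes through the origin exactly), inverted by the quadratic
formula with a linear fallback when |b₂| is negligible; negative net
intensities clip to 0 with a warning. The Arp3 band proxies
whole-complex concentration (one Arp3 per complex). Because standards
and unknowns share each species' curve, the molar ratio is invariant to
any common multiplicative intensity rescaling of one species' lanes.

## Synthetic-data generator

The generator draws homogeneous-Poisson arrivals per site (filaments,
branch points, background locations), i.i.d. dwells (exponential,
two-exponential or fixed), uniform start phases, and renders movies as
2-D Gaussians with Poisson or Gaussian noise. Occupancy scenarios use a
stationary alternating bound/unbound telegraph process. Defaults mirror
the experimental conditions being modelled: Δt ∈ {0.15, 0.25, 1} s,
pixel size 0.27 or 0.18 µm, event counts at the studied scales
(200–10,000 dwells, 26 occupancy sites over 600 s, 1000 photobleaching
traces, 50 branches × 4 trials), dwell means at the published fitted
values, a 20% dimer fraction at step/noise 5, and 2:1 gel compositions
with 5% intensity CV and twofold standard dilution series from 1 µM
(Arp2/3) and 2 µM (Abp1).

What it does **not** emulate — and therefore what passing tests do not
show about real data: molecular diffusion and dynamic PSFs, blinking
and other photophysics, camera EM gain, drift, uneven illumination,
filament growth/movement during acquisition, and cooperative or
spatially correlated binding. Parameter recovery here demonstrates the
statistical pipeline is self-consistent and unbiased under its stated
observation model, not that the model captures every property of real
recordings.

## Reproducibility

Every stochastic path flows from an explicit integer seed through
`numpy.random.default_rng`; identical (seed, parameters) give
byte-identical outputs, pinned by tests. Pipeline artifacts embed the
config hash, seed and package version, and floating-point tables are
serialised at fixed precision so artifacts regenerate bit-identically.
`scripts/acceptance.py` derives all of its per-target seeds from the
single `--seed` argument via `numpy.random.SeedSequence`.
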