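# tirfkin

Quantitative analysis of single-molecule TIRF microscopy binding
kinetics, built around the measurements used to characterise how the
actin-binding protein Abp1 (a type II nucleation-promoting factor)
regulates the Arp2/3 complex on actin filaments: dwell-time survival
analysis with frame-interval censoring, single- and two-exponential
maximum-likelihood fits with bootstrap uncertainties, step-photobleaching
stoichiometry, per-site-class binding frequency and occupancy, branch
nucleation and debranching survival curves, and stain-free-gel
standard-curve stoichiometry. A first-class synthetic-data generator
emulates the TIRF observations with known ground truth, so every stage
of the pipeline is validated by parameter recovery.

## The statistical core

A molecule bound to its target is observed only at acquisition instants
k·Δt (Δt = 0.15, 0.25 or 1 s in the experiments this package models).
An event spanning k instants is recorded as a dwell of k·Δt seconds;
events shorter than one frame are never detected, and events still
bound at the last frame are right-censored. For an exponential dwell
with mean τ and a binding start phase uniform on [0, Δt), the observed
frame count conditional on detection is geometric,

    P(K = k) = (1 − q) q^(k−1),   q = e^(−Δt/τ),

with the closed-form MLE

    τ̂ = Δt / ln( k̄ / (k̄ − 1) ).

For a two-component mixture (1 − a)·Exp(T_short) + a·Exp(T_long) each
component additionally carries its detection probability
C(τ) = (τ/Δt)(1 − e^(−Δt/τ)), so the fitted amplitude a refers to the
underlying events and the estimator recovers the generating parameters
without censoring bias. A `naive` estimator (continuous likelihood on
the recorded dwells) is also provided; it overestimates τ by an amount
that grows with Δt, which is exactly the artefact the
phase-marginalized likelihood removes. Standard errors come from
nonparametric bootstrap (default 10,000 resamples), with mixture
components sorted T_short < T_long before aggregation.

Occupancy is Σ(bound time) / (n_sites × observation), with 370 binding
sites per µm of filament and 1 site per branch junction; binding
frequency is event starts per second of *available* (unoccupied)
detection-box time, with a 1.14 µm² box. Photobleaching steps are
counted by binary-segmentation change-point search with a BIC penalty;
gel band intensities are calibrated with per-species quadratic
standard curves forced through the origin.

## Worked example

```python
import numpy as np
from tirfkin import simulate_dwell_sample, fit_exponential, bootstrap_se, survival_curve

# 2000 detected binding events with true mean dwell 0.46 s, sampled at 0.25 s frames
sample = simulate_dwell_sample({"tau": 0.46}, frame_interval_s=0.25, seed=7, n_detected=2000)

naive = fit_exponential(sample, estimator="naive")
pm = fit_exponential(sample)                       # phase_marginalized (default)
boot = bootstrap_se(sample, fit_exponential, n_boot=10000, seed=7)

print(f"naive tau       : {naive.tau:.3f} s")
print(f"phase-marg. tau : {pm.tau:.3f} s +/- {boot['se']['tau']:.3f}")
```

prints

```
naive tau       : 0.594 s
phase-marg. tau : 0.458 s +/- 0.011
```

The naive estimate is inflated by ~30% because sub-frame events are
missing and every dwell is rounded up to whole frames; the
phase-marginalized fit returns the generating 0.46 s within its
bootstrap standard error. `survival_curve(sample)` gives the empirical
cumulative survival on the frame grid (S(0) = 1.000, S(0.5 s) = 0.577,
S(1 s) = 0.197, ...), the curve the fits are drawn through.

A command-line interface chains the stages
(`tirfkin simulate | detect | fit-dwell | occupancy | steps | branching |
survival | stoich | pipeline`); see `tirfkin --help`.

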