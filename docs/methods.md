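# Methods

## Models and estimation

Both models treat the observed methylation matrix ŝ (n sites × m
individuals) as a set of per-site linear trends in time with iid Gaussian
noise of one global variance σ². Under the **molecular clock** the time axis
is the chronological age vector t; under the **universal pacemaker** it is a
free vector of epigenetic ages t′, shared by all sites within an individual.
Because the noise is Gaussian with a common variance, the maximum-likelihood
fit of either model is the least-squares fit: with σ² profiled out, the log
likelihood at the optimum is −(nm/2)·log(RSS) + const, strictly decreasing
in the residual sum of squares.

**Clock fit.** The joint problem over all 2n site parameters can be written
as one mn × 2n linear system in which the row for entry (i, j) has tⱼ in
column i and 1 in column n+i. That system is block-separable by site, so the
production path (`fit_mc`) solves n independent simple regressions via the
centered closed form; the assembled system (`build_design_matrix`) is
retained only as a testing oracle, since solving it directly costs O((2n)³).

**Pacemaker fit.** For any fixed candidate time vector, the site parameters
have the same closed form as the clock fit, so the search lives entirely in
the m-dimensional time space. Two search strategies are implemented and
cross-checked:

* *alternating* (default): exact block-coordinate descent on the bilinear
  RSS — closed-form site update, then the closed-form per-individual time
  update tⱼ = Σᵢ rᵢ(ŝᵢⱼ − sᵢ⁰) / Σᵢ rᵢ², clipped below at the time lower
  bound. Each step is an exact minimization, so the RSS is monotonically
  non-increasing.
* *direct-search*: bounded SLSQP over the time vector with the closed-form
  site fit nested in the objective (sequential least squares).

Both run from `n_starts` starting points (default 10): the chronological
ages first — which guarantees the fitted RSS never exceeds the clock RSS —
then ages multiplied by iid lognormal jitter (σ = 0.2). On random 10×10
instances the two strategies agree to ~1e-9 relative RSS; on 3×3 instances
the fit matches an exhaustive grid-plus-coordinate-descent search to ~1e-11.

**Convergence and degenerate inputs.** Iteration stops when the relative RSS
improvement falls below `rel_tol` (default 1e-9) or after `max_outer_iters`
(default 500) steps. Epigenetic times are constrained to at least
`time_lower_bound` (default 1e-3 years): non-positive times are meaningless
and break average-rate computations. All-identical data columns are rejected
(times unidentifiable); a site with zero variance fits rate 0 without error,
as such probes occur on real arrays. Datasets need n ≥ 2 sites and m ≥ 3
individuals. If a time update would collapse all times to one value (gauge
collapse on pathological data), the previous iterate is kept.

## The gauge, and how fits are reported

The pacemaker likelihood is invariant under a two-parameter affine
reparameterization of time: t → a·t + b, r → r/a, s⁰ → s⁰ − (r/a)·b changes
no fitted value. (Scale invariance is widely noted; the shift direction is
also flat because the start levels are free.) Fitted epigenetic ages are
therefore only identified up to an affine map, and an optimizer may converge
anywhere on the orbit. `fit_upm` picks the orbit representative in which the
regression of epigenetic age on chronological age has slope 1 and intercept
0 — epigenetic age as an unbiased linear readout of chronological age, with
the per-individual deviations (the pacemaker signal) preserved at full
scale. The direction of that calibration matters: anchoring the other way
(regressing ages on fitted times) shrinks the inferred stretch toward the
mean and contaminates age ratios with a 1/t term. `normalize_scale` exposes
the scale part of the convention and is idempotent after anchoring. The
transform never changes the RSS; if it would push a time below the lower
bound, the fit is left un-anchored rather than clipped.

## Likelihood-ratio test

χ² = n·m·log(RSS_MC/RSS_UPM) = −2·log Λ, referred to χ² with df = m
(configurable). df = m counts the free epigenetic ages; the affine gauge
arguably makes the effective count m − 2, so df = m is mildly conservative
on that account. Natural logarithms throughout. RSS_UPM exceeding RSS_MC
beyond 1e-8 relative is treated as an upstream optimizer failure and raised,
never clipped; within that slack χ² is set to 0. Pipelines floor both RSS
values at 1e-12·Σŝ² before taking the ratio, so a clock fit that is already
perfect to machine precision yields χ² = 0 (no evidence for a pacemaker)
rather than a log-ratio of rounding artifacts.

## Synthetic data

The generator draws ages tⱼ ~ Uniform(10, 100) years, rates
rᵢ ~ Uniform(−0.03, 0.03) per year resampled until |rᵢ| ≥ 0.003, and start
levels sᵢ⁰ ~ Uniform(0, 1). The pacemaker multiplies each individual's age
by 1 + εⱼ with εⱼ ~ N(0, σ_t²), shared across that individual's sites (the
defining pacemaker property); εⱼ is resampled in the rare (~5σ at
σ_t² ≤ 0.15) event of a non-positive perturbed time. Observation noise
N(0, σ_s²) is added to every entry. Stored ages are the unperturbed tⱼ.

**Why these scales.** The study grid pairs pacemaker variances
σ_t² ∈ {0.1, 0.15} with site-noise variances σ_s² ∈ [1, 10]. The
pacemaker-induced misfit per matrix entry under the clock model is
≈ E[r²]·E[t²]·σ_t²; with E[r²] ≈ 3.3e-4 and E[t²] = 3700 this is ≈ 0.12–0.62
across the grid — the same order as the noise, so detection genuinely
transitions across the grid instead of one effect trivially dominating. Rate
magnitudes up to 0.03 per year correspond to sites that traverse a large
fraction of the methylation range over a lifetime, i.e. the high-variance
sites the analysis pipeline selects. All ranges are configurable.

**What the generator does not emulate:** bounded [0, 1] beta values (the
model and its Gaussian noise are unbounded, so no clamping anywhere),
probe-specific noise variances, batch effects, or correlated sites beyond
the pacemaker itself. Passing tests therefore demonstrate correctness of the
estimation and testing machinery under the model's own assumptions, not
robustness to array artifacts.

## Power study

A trial is: simulate → clock fit on chronological ages → pacemaker fit → LRT
with df = m → p-value. A grid run repeats this over deterministic
per-replicate seeds derived from one master seed and reports, per cell, the
detection frequency (fraction of replicates with p < α, default α = 0.05)
and the mean p-value. Default 30 replicates per cell (binomial SE ≈ 0.09 at
a frequency of 0.5). At σ_t² = 0.15 with 50 sites and 50 individuals the
pacemaker is detected in ≥ 85% of replicates at every noise level on the
grid (the acceptance script measures ~97–100%).

## Known limitations

* **The df = m reference is anticonservative when times are weakly
  identified.** Fitting the m epigenetic ages absorbs noise like a rank-one
  perturbation — on the order of (√n + √m)²·σ², not m·σ² — whenever
  Σᵢrᵢ²·Var(t)/σ_s² is not large. Measured at n = m = 50 with the default
  scales and σ_s² = 7: null χ² mean ≈ 89 against a χ²₅₀ 5% point of 67.5,
  i.e. a type-I rate near 0.9. Even in the strongly identified regime a
  milder inflation of order nm/(nm − 2n − m) remains (measured type-I ≈ 0.09
  at n = 50, m = 20 against the 0.05 nominal). Consequences: detection
  frequencies at small σ_t² partly reflect null inflation, and a measured
  "weak-pacemaker" detection frequency cannot fall below the inflated null
  rate no matter the noise level — maximum-likelihood fitting cannot
  reproduce a decline of detection below 50% at high noise, because the
  noncentrality of the test and the identification strength of the times are
  locked together by the age distribution (their ratio is
  σ_t²·m·E[t²]/Var(t) ≥ 4σ_t²m for uniform ages). A parametric-bootstrap
  null would calibrate the test properly and is the natural extension.
* Epigenetic ages are reported under the affine calibration above; only
  affine-invariant features of them (orderings, nonlinear trends, ratios up
  to the calibration) are meaningful.
* One global noise variance is assumed; no per-site variance heterogeneity,
  no weighted or robust variants.
* The average error per entry reported by the clock CLI is the RMS
  √(RSS/(n·m)), labelled as such; other conventions for "average error"
  exist and are not comparable.

## Problem sizes used in the shipped tests

Unit and property tests run on instances from 1×2 up to 100×100; the
acceptance-style checks use 30 replicates per grid cell at 50×50 (strong
signal, full σ_s² = 1..10 grid and the 7..10 sub-grid) and 300 null
replicates at 50×20 for type-I calibration. The full suite completes in a
few minutes on one CPU.
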