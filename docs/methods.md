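# Methods

This note records the models implemented in `microspacing`, the conventions
and numerical choices behind them, what the synthetic generators do and do
not emulate, and the package's known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Hopkins–Skellam index (`pointstats`)

`HSI = Σ r1² / Σ r2²` with `r1` the distances from `N` uniform random
origins in the observation window to their nearest cell and `r2` the
distances from `N` cells to their nearest other cell.

Choices:

* **Number of origins.** `n_sample` defaults to the number of pattern
  points. When it equals the pattern size, every cell is used exactly once
  for `r2` (deterministic, lower variance); smaller values sample cells
  without replacement, larger with replacement.
* **No edge correction.** Origins cover the full window and
  nearest-neighbour distances are uncorrected Euclidean distances. Both
  numerator and denominator suffer the same boundary inflation, so the CSR
  expectation stays ≈ 1 (the test suite calibrates: 200 patterns of 500
  points give a mean within ±0.05 of 1).
* **Sampling noise.** For a pattern of n points the index has standard
  deviation ≈ `sqrt(2/n)`-scale; at n = 65 (a simulated field of view) one
  draw has sd ≈ 0.28. Conclusions about small patterns need replicate
  seeds — a fact that matters when judging simulation outcomes (below).
* Nearest-neighbour queries use a k-d tree; unit tests pin the results to
  an O(n²) brute-force oracle.

## Track statistics (`trackstats`)

MSD is time-averaged over all overlapping frame pairs within each track,
then averaged unweighted across tracks (a pooled, pair-weighted variant is
available). Estimators:

* `d_u`: least-squares slope of MSD vs lag over a user-set linear range
  (default 10–40 min). The fit carries an intercept: a persistent random
  walk has `MSD(t) = d_u·t − d_u·τ/2 + O(e^{−2t/τ})`, so the free intercept
  absorbs the persistence offset and the slope is asymptotically unbiased.
  A through-origin variant exists but underestimates `d_u` by a factor
  `≈ 1 − τ/(2·⟨lag⟩)` (−13% at τ = 7.7 min over 10–40 min) and is not the
  default.
* `v`: `sqrt(MSD(lag₁))/lag₁` from the first lag (the initial quasi-
  ballistic part). Within-frame turning biases it slightly low (≈ 0.81
  measured vs 0.88 nominal at 2-min frames), which in turn biases
  `τ̂ = d̂_u/v̂²` slightly high; the recovery tests budget 25% for this.
* `τ = d_u/v²` — the *operational* persistence. For a 2-D run-and-tumble
  walk with full heading re-randomisation at Poisson rate λ, `MSD/t → 2v²/λ`,
  so this definition equals `2/λ`. **Every generator and the simulator
  therefore tumble at rate `2/τ`**, making the round trip (generate at τ →
  estimate τ) self-consistent.

No confinement correction is applied; if the MSD is non-monotone inside the
fitting range a warning is raised and the range is the user's problem.

## Growth–collapse process model (`process_dynamics`)

Each process grows at constant `g` (µm/min) and collapses to zero with
uniform hazard `p_collapse` (/min), regrowing immediately — an advection
equation with uniform death in length space whose stationary density is
`Exponential(rate = p_collapse/g)` per µm. With the measured g = 0.36 and
p = 0.046 the predicted log-histogram slope is 0.128 ≈ 0.13 /µm.

* Simulation: per-step Bernoulli collapse; guard `dt·p < 0.1`. The tests
  use `dt = 0.25 min` so the 0.09-µm length lattice is fine enough for a
  1%-level Kolmogorov–Smirnov comparison with the continuous exponential
  (at `dt = 1` the 0.36-µm lattice alone exceeds the 1% KS critical value
  at n = 5000).
* Burn-in: default `t_end = 10/p_collapse` (ten mean lifetimes).
* Slope fit: log(count) vs bin centre over nonempty 1-µm bins,
  **weighted by bin counts**. For Poisson counts `Var[log N] ≈ 1/N`;
  unweighted LS lets the one-or-two-count tail bins flatten the slope by
  10–15% at n ≈ 5000. The unweighted fit remains available
  (`weighted=False`).
* Collapse is modelled as instantaneous reset-to-zero (kymographs show slow
  growth, fast retraction); finite-speed retraction is not modelled, and
  new-process nucleation is identified with regrowth from zero.

## The spacing simulator (`abm_simulator`)

State: off-lattice cell positions/headings plus a gridded ATP field.
Default parameters are the measured/estimated values: c = 18 µm² µM⁻¹ min⁻¹,
τ = 7.7 min, v = 0.88 µm/min, p = 1.7×10⁻³ µM/min, h = 0.2 /min,
b = 9.5×10⁻⁴ µM/min per cell, d_a = 180 µm²/min, σ = 45 µm, k = 0.1 /min,
a_w = 25 µM; 65 cells in a 400×400 µm domain match the measured avascular
density of ≈ 409 cells/mm².

Numerics:

* Operator-split explicit Euler: one field step (production, decay, 5-point
  Laplacian diffusion, point sinks), then one cell step. Default
  `dt = min(0.9·dx²/(4 d_a), 0.01/k, τ/50)` (0.03125 min at dx = 5 µm);
  the field step refuses to run above the diffusion stability bound.
* The velocity-noise term is implemented as run-and-tumble (rate 2/τ, speed
  fixed at v), not literal velocity diffusion — see the persistence
  convention above.
* The δ-function uptake removes `b·dt` µM from the grid node containing the
  cell (per-grid-cell convention; the printed units of b are per-microglia
  and dimensionally silent about area). The field is clamped at 0.
* Boundaries: periodic for homogeneous runs; the wound scenario pins one
  x-edge at `a_w` (Dirichlet) with no-flux elsewhere and reflecting cells.
* Initial ATP is the uniform fixed point p/h (no burn-in needed); initial
  cell positions are CSR; pairwise forces are exact O(n²) (n is tens).
* In-run HSI uses `n_sample = n_cells` and a seed derived from the run seed;
  identical (params, config) reproduce bit-identical results.

Model behaviour established by the tests: the uniform field mode follows
the scalar ODE `a′ = p − h·a` to machine precision; two-cell repulsion
follows `d(t) = σ − (σ−d₀)e^{−2kt}` within 1%; the per-cell ATP dip at the
measured uptake is < 5% of bulk (≈ 0.4% at dx = 5), matching the
experimental observation that the field looks flat; wounds (a_w = 25 µM,
boundary-layer length `√(d_a/h)` = 30 µm) attract cells robustly.

**Known quantitative divergence.** With this discretization the
chemotaxis-only route (k = 0) needs c ≈ 10⁵ to reach mean HSI < 0.8 within
12 h; c = 2×10⁴ regularizes visibly (matched-seed mean HSI drops from ≈ 1.29
to ≈ 1.06) but not below 0.8. The dip-mediated repulsion a cell feels from a
neighbour scales with the sink discretization (an NGP sink on a coarser grid
digs disproportionately deeper local dips), and the original scheme behind
the published threshold is unstated; we keep the physically-motivated
dx = 5 µm grid rather than tuning the grid to reproduce the number. The
qualitative conclusion — indirect chemotactic repulsion requires a
chemotactic coefficient orders of magnitude above the measured c = 18 —
is reproduced.

## Morphometry (`morphology`)

Chain: 3×3 median despeckle → Gaussian smooth (σ = 0.8 px) → threshold →
skeletonize (topology-preserving thinning) → exact Euclidean distance
transform.

* **Threshold selection** emulates the "just before the skeleton explodes"
  rule: scanning candidates downward, a knee is a candidate whose total
  skeleton length is stable versus the previous candidate (ratio ≤ 1.2) but
  jumps by more than 2× at the next; that stable candidate is returned.
  Degenerate inputs (no plateau-then-explosion) fall back to the smallest
  candidate with a warning.
* **Thickness** is the mean distance-map value over skeleton pixels × pixel
  size — deliberately the half-width proxy of the original assay, reported
  as-is.
* **Somata** are connected components of `distmap ≥ soma_min_radius`
  (default 3 µm); the full soma extent is that core dilated by the same
  radius (a morphological opening), so the skeleton stub crossing the soma
  rim is not scored as process. Soma segmentation is this package's own
  method — the original assay does not describe one.
* **Processes**: skeleton outside somata, cut at junction pixels (≥ 3
  skeleton neighbours, 8-connectivity); segment length is the pixel-step
  geodesic (1 axial, √2 diagonal) × pixel size, assigned to the nearest soma
  centroid. Digital straight lines overestimate Euclidean length by up to
  ≈ 8% at worst angles; end-to-end slope-recovery tests budget 20%.
* Zhang–Suen-style thinning is checkerboard-parity-sensitive, so
  pixel-level skeleton output is not exactly translation invariant; the
  invariance tests allow a few percent on geodesic sums.

## Synthetic data (`synthetic_data`)

Generators are seed-deterministic, one RNG per call, each returning enough
ground truth to score any downstream estimate.

* Point patterns: CSR (uniform), hard-core (dart throwing; all pairwise
  distances ≥ r_min), Thomas cluster (Poisson parents, Gaussian offspring,
  reflected into the window).
* Tracks: run-and-tumble at speed v, tumble rate 2/τ, 20 substeps per frame
  so tumbles are resolved within a frame interval.
* Images: disk somata (default radius 5 µm) with straight processes at
  uniform angles, exponential lengths (default rate 0.13 /µm ≈ mean 7.7 µm,
  ~7 per cell — the measured tissue values), optional impulse + Gaussian
  noise. Not emulated: PSF blur, z-projection artefacts, intensity
  inhomogeneity, curved processes. A green recovery test therefore
  establishes correctness of the measurement chain on idealized geometry,
  not robustness to real microscopy.

## Statistical power caveats

Several headline checks compare a handful of stochastic simulations against
narrow bands. The 65-cell HSI has sd ≈ 0.28 per realization, so a 5-seed
mean has SE ≈ 0.13: a ±0.1 "CSR envelope" on such a mean excludes ~43% of
honest CSR draws. Where a check of that shape fails with seeds that are
verifiably unbiased in larger replication, the failure reflects the check's
power, not the dynamics; the test docstrings say so explicitly.
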