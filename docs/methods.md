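# Methods

## Model and procedure

The package tests H0: X ⫫ Y | Z from n joint observations without
distributional assumptions.  The conditional independence statement is
equivalent to "X ⫫ Y at every fixed z", and for characteristic kernels the
population HSIC of (X, Y) at fixed z vanishes exactly under independence.
The statistic approximates "fixed z" by clustering: samples are partitioned
into M clusters of similar z, an HSIC is estimated inside each cluster, and
the sum

    T = Σₘ (1/|Cₘ|²) tr(K_X⁽ᵐ⁾ H K_Y⁽ᵐ⁾ H)

is the conditional-dependence measure.  Two properties follow from the
construction: Z enters only through cluster labels (so the statistic's cost
and behaviour are insensitive to d_Z beyond the one-off clustering), and T is
a sum of biased HSIC V-statistics, hence non-negative up to roundoff.

Calibration uses a local bootstrap.  Each replicate keeps z*ᵢ = zᵢ and draws
x*ᵢ and y*ᵢ independently from a discrete kernel-weighted distribution over
the k nearest neighbours of zᵢ (k = 10), with weights
wⱼ ∝ exp(−‖zⱼ − zᵢ‖²/γᵢ) and local bandwidth γᵢ = squared distance to the
k-th nearest neighbour.  Independent index draws destroy the X–Y coupling
while approximately preserving each conditional marginal, so the K replicate
statistics form a null histogram.  The p-value is the tie-inclusive
exceedance fraction p = (1/K) Σₖ 1{Tₖ ≥ T}, and H0 is rejected when p < α
(strict).  An optional (1+count)/(1+K) correction guarantees validity at
finite K; it is off by default to match the plain Monte-Carlo estimator.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| kernel | Gaussian, exp(−‖a−b‖²/σ) | characteristic kernel; σ divides the squared distance directly |
| bandwidth policy | per-cluster median heuristic | σ_x from the cluster's x-points, σ_y from its y-points: the squared median pairwise distance puts a typical pair at e⁻¹.  A joint policy (one σ from concatenated (x, y) rows) and fixed bandwidths are available |
| M (cluster count) | ⌈n/50⌉ if n ≤ 200 else ⌈n/80⌉ | 50–80 points per cluster balance locality in z against the variance of each local HSIC estimate |
| k-means | seeded k-means++, 10 restarts, raw z | determinism from the seed; optional per-coordinate standardization of Z (off: the generators produce comparable scales) |
| k_nn | 10 | candidate-set size of the local bootstrap; also defines γᵢ |
| K (`n_bootstrap`) | 1000 | Monte-Carlo resolution of the p-value; the validation experiments use 500 (resolution 0.002) to halve runtime |
| α | 0.05 | nominal level of all reported error rates |
| bandwidth refresh | reuse observed | replicates reuse the observed per-cluster bandwidths so the statistic functional is identical across the null histogram; recomputing per replicate is available and changes verdicts on clearly dependent data in neither direction |

## Numerical choices

- HSIC is computed in O(n²) by double-centering both Gram matrices and
  taking the elementwise product-sum; centering both (H is idempotent) makes
  the estimator exactly symmetric in its arguments in floating point.
- Degenerate clusters: all-identical points give a median distance of zero;
  the bandwidth falls back to 1.0 with a warning, the Gram matrix is
  all-ones, and the cluster contributes exactly zero.  Singleton clusters
  contribute zero and warn (they signal too fine a partition).
- Bootstrap candidates include the point itself (distance 0, maximal
  weight); exclusion is a config switch.  Ties in neighbour distance break
  by original index.  Duplicated z-values that zero out γᵢ fall back to the
  smallest positive candidate distance, or to uniform weights if all
  candidates coincide.
- Empty k-means clusters (possible on degenerate data) are repaired by
  moving the point farthest from its centroid into the empty cluster.
- All randomness flows from one root seed through `numpy.random.SeedSequence`
  spawning (k-means seed, bootstrap stream, per-replicate experiment
  streams), so every run — including the order of the two index draws per
  sample — is bitwise reproducible and independent of scheduling.
- When bandwidths are reused, the bootstrap loop precomputes per-cluster
  full-sample Gram matrices once and each replicate only gathers
  sub-matrices; the fast path is capped at ~200 MB and falls back to
  per-replicate evaluation above that.  Both paths are asserted equal in the
  tests.

## Synthetic benchmark models

The generator reproduces the two standard benchmark designs used to validate
CI tests.  Z is n × d_z i.i.d. standard Gaussian; ε₁, ε₂, ε_b are
independent standard Gaussian; c is the confounding strength (c = 0 is H0,
c = 1 the alternative).

- Linear: X = Σᵢ αᵢZᵢ + cε_b + ε₁, Y = Σᵢ βᵢZᵢ + cε_b + ε₂ with
  αᵢ, βᵢ ~ U(−0.5/d_z, 0.5/d_z) redrawn per dataset.
- Post-nonlinear: X = g₁(ΣᵢZᵢ + cε_b + ε₁), Y = g₂(ΣᵢZᵢ + cε_b + ε₂) with
  g₁, g₂ drawn uniformly per dataset from {u, u², u³, tanh u, exp(−u²)}
  (the last read as a scalar map, since the argument of g is scalar).

These generators emulate additive/post-nonlinear dependence with a hidden
confounder; they do not emulate heteroscedastic noise, discrete or
heavy-tailed variables, or dependence that appears only in higher moments,
so passing error-rate experiments demonstrates calibration and power for
smooth confounded alternatives, not for arbitrary real data.

Error-rate experiments replicate generate + test on independently spawned
seeds: the Type-I error rate is the rejection rate at c = 0, the Type-II
error rate one minus the rejection rate at c = 1.  Validation uses 100
replications with n = 400, K = 500 (and 200 replications at n = 200,
K = 200 for the p-value-uniformity check) — sizes chosen to keep each
experiment in the minutes range on one CPU while leaving three-binomial-SE
assertions meaningful.

## Design choices made where the design was open

- Per-variable median bandwidths (σ_x and σ_y separately) rather than one
  joint bandwidth; the joint reading is exposed as `median_joint`.
- The weight kernel of the bootstrap is Gaussian with γ dividing the squared
  distance, mirroring the package's single kernel convention.  Weights are
  computed over the 10 candidates only (not all n), matching the
  candidate-narrowing construction.
- The partition and the bootstrap plan are built once per test: replicates
  leave z untouched, so re-clustering per replicate would add cost without
  changing anything.
- Coefficients and link functions of the generators are redrawn per
  replicate dataset, so reported rates average over the model family rather
  than conditioning on one draw.

## Known limitations

- The local bootstrap is consistent only as the local bandwidth γ → 0.  At
  fixed n, γ grows quickly with d_z (distance concentration), and the
  replicates then underrepresent the X–Z coupling that the observed sample
  retains.  With a strong z-signal this biases the null histogram low and
  inflates the Type-I error: the high-dimensional post-nonlinear setting
  (d_z = 10, n = 400, where the shared signal ΣᵢZᵢ has variance d_z against
  noise variance 1) rejects the true null almost always, even though the
  statistic itself is well calibrated there when nulls are drawn from the
  true conditionals.  The corresponding high-dimensional acceptance check
  documents this failure rather than hiding it.  At d_z = 1, and whenever
  the z-signal is weak relative to the noise (e.g. the linear model, whose
  coefficients shrink as 1/d_z), calibration is accurate.
- The biased HSIC estimator is used throughout (as in the statistic's
  definition); no unbiased/U-statistic variant is provided.
- p-values are Monte-Carlo with resolution 1/K; decisions at p ≈ α need a
  larger K or the add-one correction.
- The bootstrap loop is serial; the per-replicate cost is O(M·|C̃|²) with
  |C̃| the largest cluster, so a test costs O(M n² K / M²)-ish in practice
  and wall time grows linearly in K.
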