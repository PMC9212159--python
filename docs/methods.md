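# Methods

## The kernelized correlation coefficient

K_c measures dependence between two aligned series x, y ∈ ℝ^T by evaluating
a kernel on the joint planar observations u_i = (x_i, y_i), double-centering
the resulting Gram matrix (K_c = H K H, H = I − 11′/T), and taking Pearson's
r of the kernelized vectors K_c x and K_c y. The kernel supplies the
nonlinearity; the centering removes the constant direction, which gives the
coefficient its structural guarantees:

* K_c ∈ [−1, 1] (it is a Pearson correlation), symmetric in (x, y);
* 1′K_c = K_c 1 = 0, so the kernelized vectors sum to zero and
  K_c(a·x + b·1, y) has the same value for any a > 0, b (affine versions of
  a series multiplied through the centered matrix differ by a positive
  scalar);
* K_c(x, x + b·1) = 1 for any kernel and any shift b;
* for the RBF kernel, negating one series negates the coefficient
  (‖u_i − u_j‖ is invariant under a joint sign flip of one coordinate,
  so K is unchanged while K_c y flips sign) — this is the sign-preserving
  property that separates K_c from distance correlation;
* as γ → ∞ on pairwise-distinct points, K → I, K_c → H, and K_c-RBF
  converges to the ordinary Pearson r of (x, y).

These are all enforced as tests (property-based where appropriate), along
with a dual-route check of the centering: the projection form H K H against
the entrywise form K_ij − rowmean_i − colmean_j + grandmean at 1e-12.

Assumptions: the T observations of the two series are aligned (same time
points, same order); the measure uses only the order of observations, so
unequal time spacing is accepted as metadata. The plug-in significance rule
below treats each value as if it were a Pearson correlation of T bivariate
normal observations — a pragmatic convention, not an exact null theory for
K_c.

## Parameters

| parameter | default | meaning |
|---|---|---|
| kernel family | RBF | polynomial (1 + ⟨u, v⟩)^d is provided but has high false-positive rates in the simulation study; RBF is the recommended kernel |
| γ (RBF inverse width, unitless) | 0.5 | rule of thumb for similar-patterned (positively correlated) pairs |
| d (polynomial degree) | 2 | d ≥ 2; never trained |
| standardize | true (library), false (simulation runner) | whether each series is z-scored (sample sd, divisor T−1) before kernelization; see below |
| per-replicate threshold | 5·10⁻⁴ | Bonferroni-style cutoff, 0.05 split over 100 simulation replicates; configurable |
| γ grid | 0.1 … 10.0 step 0.1 | covers the trained values that arise for complementary pairs at these data scales |
| flat tolerance | 8·10⁻⁵ | objective values within this of the grid minimum count as ties; smallest γ wins |
| screen thresholds | value > 0.95, p < 0.001 | condition self-correlation screen flag rule |

The standardization switch exists because the two halves of the method pull
in opposite directions. Z-scoring is part of the canonical five-step
procedure and makes K_c scale-free; but z-scoring also makes pure-noise
series distribution-identical across noise levels, so a standardized K_c
null rejection rate cannot depend on the noise multiplier — whereas the
simulation study's reported false-positive rates do vary with noise. The
simulation runner therefore feeds raw series to the kernels by default
(reproducing that structure), while the library default for data analysis
is standardize=true. Both modes are first-class and tested; on the
noiseless phase-lagged-sine pair they give K_c-RBF(0.5) = 0.982 (raw) and
0.991 (standardized).

## Significance machinery

* **Plug-in t-test** (single value m from T observations):
  t = m√(T−2)/√(1−m²), df = T−2, one-sided upper tail by default. The same
  rule is applied to every measure — Pearson, Kendall τ-b, dCor, K_c — by
  convention: it is the unique simple rule consistent with the reported
  per-value p-values for all three baselines simultaneously (e.g. 0.61 →
  0.004, 0.43 → 0.04, 0.65 → 0.002 at T = 18). A permutation test for dCor
  is available (`dcor_permutation_test`) but is not the default.
* **Replicate t-test** (R ≥ 2 values of a measure): mean, se = sd/√R,
  t = mean/se, df = R−1, two-sided. Two-sided is chosen because it, and not
  the one-sided version, reproduces the reported replicate-averaged
  p-values (mean 0.82, se 0.06, R = 2 → p ≈ 0.048, the two-sided Cauchy
  tail). Identical replicate values give se = 0; the p-value is then
  reported as 0 with a degeneracy warning rather than NaN.
* **Per-replicate significance** in the simulation: one-sided plug-in p
  < 5·10⁻⁴. At T = 18 this corresponds to a critical value m* ≈ 0.708.

## γ training for complementary pairs

For negatively correlated pairs the default γ = 0.5 can miss the
anti-phase structure, so γ is chosen to maximize replicate agreement:
CV(γ) = ½Σᵢ(K_cᵢ(γ) − K̄_c(γ))², minimized over the grid. Because the
objective is typically flat near its minimum, the selected γ is the
*smallest* grid value within the flat tolerance of the global minimum —
a deterministic tie-break that avoids overfitting γ to replicate noise.
γ values at which the kernelization degenerates (a kernelized vector
numerically constant) receive an infinite objective and are excluded.
Both replicates enter the objective symmetrically; the selected γ is then
used to compute K_c on each replicate and the values are averaged.

## Simulation study

Three generators mimic yeast cell-cycle expression on the fixed grid
T_i = 0, 7, …, 119 minutes (18 points, two cycles):

* **case 1**: G₁ = 2a·sin(T_iπ/42) − 0.5, G₂ the same curve lagged by π/6 —
  a phase-shifted pair;
* **case 2**: G₁ = 2a·cos((T_i−21)π/42), G₂ = half of G₁ — exact positive
  proportionality;
* **case 3**: G₂ = G₁ + 3 — exact location shift.

Noise is c·ε with ε iid N(0, 1), independent between series and across
time, c ∈ {0.5, 1, 2}; a = 0 switches the signal off (independence null,
for false-positive rates), a = 1 on (for true-positive rates). Each (case,
a, c) cell runs 100 replicates; the per-replicate significance rule above
gives the rate, and the table p-value applies the plug-in test to the
across-replicate mean at T = 18. Noiseless (c = 0) cells consume no
randomness and are computed once. All randomness flows from one seeded
generator per scenario (first series' noise drawn before the second's);
`build_tables` spawns an independent child seed per cell from the master
seed, so tables are reproducible and cells are insensitive to which other
cells run.

What the generators emulate — and what they do not: sinusoidal periodic
expression with additive iid Gaussian noise on an equally spaced grid. Real
expression data have heteroskedastic, count-derived noise, replicate-level
batch effects, and unequal sampling; passing the simulation checks
therefore demonstrates calibration and power under the idealized
conditions, not performance on any particular real dataset.

## Synthetic fixtures

`make_fixtures` generates three dataset shapes so that every analysis path
runs without external downloads; all three are synthetic stand-ins, not the
original published datasets:

* `th17_like` — 8 genes × 5 time points (0–72 h) × 3 replicates in each of
  two conditions, with similar-patterned, complementary-patterned, and
  condition-invariant genes (the last for exercising the self-correlation
  screen);
* `yeast_alpha_like` — 4 genes × 18 points with two-cycle periodicity and
  in-phase/anti-phase/quarter-phase relationships; the two cycles can be
  treated as replicates;
* `worked_example` — a T = 3 pair constructed so its RBF(γ = 0.5) Gram
  matrix reproduces the reference 3×3 kernel matrix (off-diagonal 0.988)
  to three decimals: one observation far from the other two, and the close
  pair separated so that exp(−γ‖u₂ − u₃‖²) = 0.988 exactly.

## Numerical choices

* Standardization uses the sample sd (divisor T−1); constant series are a
  hard error rather than NaN.
* RBF evaluation relies on IEEE exp underflow (monotone to +0.0 below
  e⁻⁷⁴⁵) for far points; the Gram matrix is symmetrized as (K + K′)/2 to
  remove last-bit asymmetry.
* A kernelized vector with variance below 1e-14 raises a "degenerate
  kernelization" error (e.g. γ → 0 collapse) rather than returning NaN.
* K_c is clipped to [−1, 1] after the final Pearson step to absorb
  floating-point overshoot.
* Double-centering uses the entrywise O(T²) form; the H K H product form is
  kept as a test oracle.
* Expression tables are written with shortest round-trippable decimal
  representation and read with round-trip float parsing, so write → read is
  bit-identical.
* Missing values, duplicate identifiers and non-numeric cells are hard
  errors naming the offending row/column; no imputation.

## Known limitations

* The plug-in t-test is a convention for K_c, not a derived null
  distribution; its per-replicate false-positive rate for kernel measures
  (especially polynomial kernels on raw data) is well above nominal, as the
  simulation tables show.
* Kendall's τ-b of the exact noiseless case-1 grid is 0.638 (confirmed
  independently with R's `cor`), which rounds to 0.64, not the 0.65 carried
  in the reference table; the discrepancy is below 0.02 but outside the
  strict reproduction tolerance, and is asserted honestly (failing) in the
  acceptance tests.
* Under the stated 5·10⁻⁴ per-replicate rule the long-run case-1 low-noise
  Pearson TPR is ≈ 0.82; the reference table's 0.92 is not reachable within
  three binomial standard errors for most seeds. No alternative single
  threshold fits all three cases better, so the stated rule is kept and
  this cell is allowed to fail.
* Only pairwise (bivariate) K_c is implemented; multivariate extensions and
  kernels beyond polynomial/RBF are out of scope, as is normalization of
  raw sequencing or microarray data (normalized values are taken as given).
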