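# kercor — kernelized correlation for paired time series

`kercor` implements the **kernelized correlation coefficient** K_c, a
nonlinear dependence measure for two series observed at the same time points
(typically time-course gene expression: microarray or normalized RNA-seq).
Classical Pearson correlation only captures linear association, and distance
correlation (dCor) is non-negative by construction, so neither can report
that two genes with *complementary* (anti-phase) temporal patterns are
negatively correlated. K_c is sign-preserving: it ranges over [−1, 1] and
assigns complementary pairs a negative value while still detecting nonlinear
association.

## The measure

Given series x, y ∈ ℝ^T (T ≥ 3), optionally z-scored across time points:

1. form planar observations u_i = (x_i, y_i);
2. build the T×T Gram matrix K_ij = k(u_i, u_j) with a polynomial kernel
   k(u, v) = (1 + ⟨u, v⟩)^d or a Gaussian (RBF) kernel
   k(u, v) = exp(−γ‖u − v‖²);
3. double-center: K_c = H K H with H = I − (1/T)·11′;
4. K_c(x, y) = Pearson's r of the kernelized vectors K_c x and K_c y.

Significance of a single value m on T points uses the plug-in statistic
t = m√(T−2)/√(1−m²) with df = T−2; values computed per replicate are
combined by a one-sample t-test (df = R−1). For positively correlated
(similar-patterned) pairs the RBF default γ = 0.5 works well; for negatively
correlated (complementary) pairs γ is trained by replicate agreement,
minimizing CV(γ) = ½Σᵢ(K_cᵢ(γ) − K̄_c(γ))² over a grid.

The package also ships the baseline measures it is compared against
(Pearson, Kendall τ-b, sample distance correlation), a three-case simulation
study of false/true positive rates under sinusoidal signals with Gaussian
noise, expression-table I/O with an all-pairs engine and multiple-testing
adjustment, and a condition self-correlation screen for excluding
condition-invariant genes.

## Worked example

A complementary-patterned gene pair from the built-in synthetic yeast-like
fixture (18 time points over two cycles, the cycles treated as two
replicates), with γ trained by cross-validation:

```python
from kercor import PairCorrelation, TimeSeriesPair, make_fixtures

ds = make_fixtures("yeast_alpha_like", seed=3)
a, b = ds.series("CYCA"), ds.series("ANTI")
reps = [TimeSeriesPair(a[:9], b[:9]), TimeSeriesPair(a[9:], b[9:])]
res = PairCorrelation(reps, names=("CYCA", "ANTI")).fit(train=True)
print(res.summary())
```

```
Pairwise nonlinear correlation
==========================================================
pair:       CYCA - ANTI
T:          9 time points, R = 2 replicate(s)
kernel:     K_c-RBF(gamma=0.1) [trained]
standardize: True
----------------------------------------------------------
measure                   value       se    p_value
K_c-RBF(gamma=0.1)      -1.0000   0.0000  1.032e-06
pearson                 -0.9971   0.0011  0.0007176
kendall                 -1.0000   0.0000          0
dcor                     0.9966   0.0016   0.001011
==========================================================
```

K_c reports the anti-phase relationship as −1 with a small p-value, while
dCor — although it detects dependence — cannot express the negative sign.
The `value` column is the across-replicate mean, `se` its standard error,
and `p_value` the one-sample t-test across replicates (the plug-in t-test
when R = 1).

The same analyses are available from the shell:

```bash
kercor fixtures yeast_alpha_like --out yeast.tsv
kercor pair yeast.tsv --pair CYCA CYCB          # K_c + baselines, one pair
kercor matrix yeast.tsv --adjust bonferroni     # all n(n-1)/2 pairs
kercor --seed 1 simulate --out tables/          # the simulation tables
```

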