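# miprest — mixed ICA/PCA via reproducibility stability

Blind source separation with ICA rests on nongaussianity: a mixture's
nongaussian ("sparse") sources are identifiable, but any subspace spanned by
two or more Gaussian sources is rotationally invariant — ICA run on it
returns an arbitrary basis, and worse, unmodelled Gaussian sources
contaminate the sparse estimates.  Practitioners working with EEG, fMRI,
audio, or any multichannel recording therefore need to know *which* part of
a mixture is sparse and recoverable, *how many* dimensions the Gaussian
remainder occupies, and which extracted components are spurious artifacts
of asking for more sources than the data contains.

`miprest` answers all three questions with a repeated-estimation pipeline:

1. **RAICAR** — the data matrix `X` (N channels × p samples) is decomposed
   by K FastICA realizations from independent random starts (and, at large
   p, bootstrap resamples).  Components are aligned across realizations by
   absolute cross-correlation and each aligned group gets a reproducibility
   `R` ∈ [0, 1]: the mean |corr| over all member pairs.
2. **Decimation stability** — the same decomposition is repeated on an
   ensemble of random 2-fold column subsamples.  For source rank *j* in
   decimation *i*, the statistic `δᵢⱼ = Rᵢ(Sⱼ) − R⁰(Sⱼ)` measures how the
   reproducibility moves when the sample support changes.  True sparse
   sources have uniformly high `R` and small `δ`; Gaussian-subspace
   components are sometimes highly reproducible but fluctuate strongly
   between subsamples; spurious components (overextraction) have `R ≈ 0`.
   A three-way threshold classifier on the ensemble medians yields the
   sparse count `N′`.
3. **Projection and dimension** — the sparse subspace is projected out,
   `X̃ = X − A S`, using the parent decomposition's mixing columns, and the
   dimension of the residual Gaussian subspace is estimated by six PCA
   stopping rules on the covariance spectrum of `X̃`: Kaiser-Guttman
   (λᵢ > λ̄), Joliffe's variant (λᵢ > 0.7 λ̄), the broken-stick model
   (fₖ > lₖ = (1/n) Σᵢ₌ₖⁿ 1/i), the information dimension (n₀ = N^H̃ with
   H̃ the normalized spectral entropy), Horn's parallel analysis, and a
   permutation ("random lambda") test — plus a consensus (the rounded mean
   of the last four).

The package is organized as scikit-learn estimators —
`ReproducibleICA`, `MIPReSt`, and `SubspaceDimension`, all with
`fit`/`transform` and `get_params`/`set_params` — with functional wrappers
(`raicar_decompose`, `run_miprest`, `estimate_dimension`, …) that follow
the field's channels-by-samples matrix convention.  A synthetic-source
module generates the standard battery of super- and subgaussian test laws
(hyperbolic secant, Laplace, logistic, sinh/arcsinh-warped normals,
cosh-tilted Gaussian, generalized Gaussian, and a strongly leptokurtic
speech surrogate) with Gram-Schmidt orthogonalized random mixing.

## Worked example

Ten channels that secretly contain only five sources — two inverse-cosh
supergaussians and three Gaussians, overmixed by a random orthogonalized
10×5 matrix — so half of the requested components are spurious:

```python
from miprest import MIPReSt, overextraction_design

ds = overextraction_design(n=50_000, seed=1)     # X is 10 x 50000
est = MIPReSt(n_runs=10, n_ensembles=15, random_state=1)
est.fit(ds.X.T)                                  # sklearn orientation

print(est.classification_.counts())
print("parent R:", est.parent_.R.round(3))
print("median |delta|:", est.delta_table_.median_abs_delta().round(3))
print(est.rule_dims_)
```

prints

```
{'sparse': 2, 'gaussian': 3, 'spurious': 5}
parent R: [0.996 0.996 0.825 0.824 0.822 0.    0.    0.    0.    0.   ]
median |delta|: [0.002 0.004 0.057 0.111 0.146 0.    0.    0.    0.    0.   ]
{'kaiser_guttman': 3, 'joliffe_kg': 3, 'broken_stick': 3,
 'information_dimension': 3.0, 'parallel_analysis': 3, 'random_lambda': 3}
```

Read this as: the two truly sparse sources are almost perfectly
reproducible and stable under decimation (R ≈ 0.996, median |δ| ≤ 0.004);
the three Gaussian-subspace components are only moderately reproducible and
fluctuate (|δ| up to 0.15); the five surplus components never materialize
(R = 0).  After projecting the two sparse sources out, all six stopping
rules agree the residual Gaussian subspace is three-dimensional.

The same pipeline is available from a shell:

```sh
miprest simulate overextraction mix.tsv --n 50000 --seed 1
miprest run mix.tsv --outdir out --seed 1
miprest dims out/residual.tsv --out dims.json --seed 1
```

`run` writes the δ table, the classification (JSON), the sparse-removed
residual matrix, and the per-rule dimensions.

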