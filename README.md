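# betanest

Beta-diversity partitioning, nestedness and distance-matrix association
analysis for binary (presence/absence) community matrices, built around the
study design of land-bridge island surveys: a set of islands differing in
area, isolation and habitat richness, each with a species inventory per
taxon.

The central question the toolkit addresses: when island communities differ
in composition, is that because species are *replaced* from island to
island (spatial turnover), or because species-poor islands hold *nested
subsets* of the species on rich islands (nestedness)? The two patterns have
opposite conservation implications — turnover means every island adds
species to the region; nestedness means the richest islands suffice.

## Methods in the box

**Pairwise partition.** With `a` species shared by two islands and `b`, `c`
exclusive to each, Sørensen dissimilarity splits additively into a Simpson
turnover term and a nestedness-resultant remainder:

    β_sor = (b + c) / (2a + b + c)
    β_sim = min(b, c) / (a + min(b, c))
    β_sne = β_sor − β_sim = |b − c| / (2a + b + c) · a / (a + min(b, c))

Jaccard-family (β_jac = β_jtu + β_jne) and replacement/richness-difference
(β_cc = β_repl + β_rich) partitions are included for robustness checks.

**Multiple-site partition.** β_SOR = β_SIM + β_SNE over all islands at
once, replacing `b`, `c` with Σ min(b_ij, b_ji) and Σ max(b_ij, b_ji) and
`a` with Σ S_i − S_T. The ratio β_ratio = β_SNE/β_SOR classifies a system
as turnover-dominated (< 0.5) or nestedness-dominated (> 0.5). Subset
resampling makes systems with different island counts comparable.

**NODF + PP null.** Nestedness is scored by NODF (paired overlap under
decreasing fill, 0–100, for sites, species or both), with significance from
a proportional-proportional null model: each cell is Bernoulli with
probability equal to the mean of its row and column fill fractions;
Z-scores and one-tailed Monte Carlo p-values are reported.

**Associations.** Dissimilarity matrices are related to attribute
difference matrices (|Δlog₁₀ area| etc.) by multiple regression on distance
matrices (MRM) and by simple and partial Mantel permutation tests with
great-circle distance as the spatial covariate.

**Island models.** Pearson correlations among log-transformed attributes,
power-law species–area regressions (log₁₀–log₁₀ OLS) and backward stepwise
selection by AIC.

**Synthetic systems.** Generators for nested gradients, turnover windows,
mixtures of the two, and full island systems (lognormal areas, area-linked
habitat richness, power-law richness, ranked-occupancy assembly) so every
stage is testable without any downloads.

## Worked example

The package ships the fixed attribute table of the 37-island study system
(areas 0.57–1289.23 ha). Regressing log₁₀ bird richness on log₁₀ area:

```python
>>> import betanest as bn
>>> t1 = bn.table1_fixture()
>>> res = bn.species_area_regression(t1.richness_birds, t1)
>>> print(f"slope {res.estimate('area_ha'):.2f}, "
...       f"intercept {res.estimate('Intercept'):.2f}, R2 {res.r_squared:.2f}")
slope 0.09, intercept 1.34, R2 0.76
```

i.e. bird richness scales as S ≈ 22·A^0.09 — a shallow species–area curve
typical of highly mobile taxa. Partitioning a perfectly nested gradient:

```python
>>> m = bn.generate_nested([60, 40, 20, 10], n_species=60)
>>> ms = bn.multisite_partition(m)
>>> print(f"beta_SOR {ms.beta_SOR:.2f}, beta_SIM {ms.beta_SIM:.2f}, "
...       f"ratio {ms.beta_ratio:.1f} -> {ms.dominance}")
beta_SOR 0.55, beta_SIM 0.00, ratio 1.0 -> nestedness-dominated
```

All dissimilarity is nestedness-resultant (β_SIM = 0), and NODF for sites
is 100. The numbered drivers under `analysis/` walk a complete synthetic
study (simulation → partition → NODF null test → richness models →
distance associations) and write their tables under `results/`:

```sh
python analysis/01_simulate_islands.py   # then 02 ... 05
```

A `betanest` CLI exposes the same steps
(`betanest partition|nodf|associate|richness|simulate|reproduce`); see
`betanest --help`.

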