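# Methods

## Data model

All computations consume a binary site × species incidence matrix
(`CommunityMatrix`); the canonical orientation is sites in rows regardless
of how a CSV is oriented on disk (an `auto` mode sniffs orientation when
exactly one axis carries integer island codes, and refuses to guess
otherwise). Cells must be 0/1; abundances are only thresholded to presence
behind an explicit `truncate_abundance` flag, because every method here is
incidence-based. Sites with no species are removed (and recorded) before
any dissimilarity or nestedness computation — a pair of empty communities
has no defined dissimilarity, and an all-zero line makes NODF's paired
overlap ill-defined — mirroring the field practice of excluding islands
where a taxon was never found.

Island attributes are one row per island: decimal-degree coordinates
(converted once from degrees–minutes–seconds, stored to 6 decimals), area
in hectares (> 0), isolation as the water fraction of a 2-km buffer
(in (0, 1]), habitat richness (≥ 1 habitat types) and optional per-taxon
richness counts. The 37-island table of the study system ships with the
package as `table1_fixture()`.

## Beta-diversity partition

Pairwise: β_sor = (b+c)/(2a+b+c), β_sim = min(b,c)/(a+min(b,c)),
β_sne = β_sor − β_sim. The closed-form product for β_sne (richness-difference
fraction × Simpson similarity) is implemented separately and agrees with the
subtraction to ≤ 1e−12; when min(b, c) = 0 the Simpson-similarity factor is
taken as 1 (the limit value; this also covers the 0/0 case of a pair with
one empty side, where β_sne = β_sor). Multiple-site components use the sums
of pairwise exclusive-richness minima/maxima and the richness surplus
Σ S_i − S_T. β_ratio = β_SNE/β_SOR is reported with a dominance label
(turnover-dominated < 0.5 < nestedness-dominated) and is *undefined* — not
zero — when β_SOR = 0, to avoid silently classifying a homogeneous system.

Resampling for unequal site counts draws subsets without replacement
(independent across samples) and reports per-component means and sample
SDs; means retain additivity exactly because averaging is linear. Jaccard
(β_jac = β_jtu + β_jne) and replacement/richness-difference
(β_cc = β_repl + β_rich) families are provided for robustness comparisons.

## NODF and the PP null model

NODF scores every unordered pair of lines along an axis: if the two fills
differ, the pair contributes 100 × (shared presences)/(poorer fill); equal
fills contribute 0 ("decreasing filling" is required strictly). Axis scores
are plain means over pairs; the total pools row pairs and column pairs.
This pair-wise form is order-invariant, so packing the matrix (sorting
rows/columns by decreasing marginal totals, stable for ties) changes the
display but not the score; `max_pack` is provided for visual inspection.
"NODF for sites" always means the axis indexing islands, resolved after
orientation normalisation. The implementation is cross-checked against
`vegan::nestednodf` in the test suite.

The proportional-proportional (PP) null draws each cell independently as
Bernoulli((row fill + column fill)/2), preserving matrix fill in
expectation while letting margins vary. Null samples containing empty lines
have those lines removed before scoring (the same treatment as the observed
data); a sample still degenerate after removal is dropped from the null
distribution rather than redrawn, to avoid conditioning bias — with
realistic fills this is vanishingly rare. The test reports
Z = (N_obs − mean)/SD and a one-tailed Monte Carlo p in the direction of
the observed deviation with the (k+1)/(n+1) correction, plus a
nested/anti-nested label. With 1000 randomizations the smallest reportable
p is therefore 1/1001.

## Distance-matrix associations

Mantel statistics correlate the unfolded upper triangles of two distance
matrices; the exchangeable unit is the site label, so the null permutes
rows and columns of one matrix simultaneously. p-values are two-sided
(|r_perm| ≥ |r_obs|, +1-corrected) because negative correlations (turnover
falling with attribute differences) are substantively meaningful. The
partial Mantel r is the first-order partial correlation of the triangles
given a covariate matrix (here great-circle distance between island
coordinates, haversine on a 6371.0088 km sphere); the null permutes the
focal matrix and recomputes the partial r. MRM regresses the response
triangle on predictor triangles by OLS, with per-coefficient permutation
p from relabelling the response matrix. Because OLS is linear in the
response, MRM coefficients for β_sor equal the sums of those for β_sim and
β_sne exactly (≤ 1e−10 in tests). Whether published association figures
print simple or space-partialled r is often ambiguous; the pipeline
therefore emits both, side by side.

Attribute difference matrices are 1-D Euclidean (|Δx|), with a per-variable
transform switch. Defaults: log10 for area (it spans four orders of
magnitude), raw for isolation (a bounded fraction) and habitat richness (a
small count). Whether isolation should be logged is genuinely open; it is
a config switch, and the correlation table is likewise available raw or
logged.

## Richness models

Species–area regressions are OLS of log10(richness) on log10 attributes
(log base 10 is the convention that makes the study's printed bird
coefficients self-consistent: 1.34 + 0.09·log10(1289) ≈ log10(43)). For
taxa absent from some islands the default treatment excludes those islands
(no offset), which reproduces the study's printed lizard coefficients; an
explicit `zero_offset` is available instead. Backward stepwise selection
starts from the full model and repeatedly removes the term whose removal
lowers AIC most (statsmodels' Gaussian AIC; model comparisons are identical
to R's `step`). Note that AIC selection retains a pure-noise predictor with
probability ≈ P(χ²₁ > 2) ≈ 0.16, so occasional spurious terms are expected
behaviour, not a defect; the tests assert the active predictor is always
kept and spurious retention stays near that theoretical rate.

## Synthetic generators

`generate_nested` ranks species and gives site k the top `profile[k]`
species: at zero noise the matrix is perfectly nested (β_SIM = 0,
β_ratio = 1, NODF = 100) and richness equals the profile exactly.
`generate_turnover` slides a fixed-width window along the species list
(step = width gives disjoint inventories: β_SNE = 0, β_ratio = 0; step = 0
gives identical sites). Noise is symmetric Bernoulli cell-flipping, the
simplest mechanism that degrades structure continuously; a
richness-preserving variant swaps a presence and an absence instead.
Noise sensitivity is worth knowing: on a 30 × 60 nested gradient,
nestedness dominance (β_ratio > 0.5) survives 2% flip noise in ≈ 100% of
realisations but is already lost in most realisations at 5%, because the
multiple-site turnover term accumulates min(b_ij, b_ji) over all ~450
pairs and random flips feed it efficiently. The mixture generator assigns
each species to nested or turnover dynamics with a weight, interpolating
β_ratio.

`generate_island_system` emulates the study conditions: 37 islands with
log10-areas N(0.46, 0.80) (the observed scale and spread), habitat
richness mapped monotonically from a latent gradient correlated with
log-area (link strength 0.95 reproduces the observed r ≈ 0.88), richness
from log10(S) = 1.34 + 0.09·log10(A) + N(0, 0.04) (σ chosen to give
R² ≈ 0.75), rounded to integer counts, and a ranked-occupancy (nested
species-loss) community, optionally noised. Because richness is rounded to
whole species, the σ = 0 case recovers the generating coefficients only to
rounding precision (R² > 0.99), not machine precision. The generator
emulates the attribute structure and nested assembly of real land-bridge
systems but not spatial autocorrelation of composition, habitat-specific
species pools, or survey error — so passing tests demonstrate correctness
of the estimators under the generating model, not ecological realism of
any particular dataset.

## Pipeline and reproducibility

`reproduce(AnalysisConfig)` runs the full sequence per taxon (validation →
empty-site removal → fill/CV → multiple-site partition, optionally
resampled → NODF PP-null test → richness models → association table) and
writes a full-precision JSON bundle plus a text report rounded to two
decimals. Every random stage derives its own seed deterministically from
the single config seed, so reruns are byte-identical; every reported block
carries a tag naming its index family, transform and permutation counts.
Statistics that are undefined for a degenerate input (e.g. Mantel r against
an identically-zero turnover matrix in a perfectly nested system) are
reported as null with a note rather than aborting the run.

Default problem sizes (1000 null randomizations, 9999 Mantel permutations,
999 MRM permutations, 100 resampling draws) follow the study design; the
test suite and example drivers use smaller synthetic systems (14–37 sites,
20–60 species) chosen so the full analysis completes in seconds.

## Known limitations

- The PP null is the only null model (no fixed-fixed/swap algorithms);
  matrix temperature and discrepancy metrics are out of scope.
- Abundance-weighted dissimilarity (Bray–Curtis) is deliberately absent.
- Mantel-family tests have known inflated type-I error under strong
  spatial autocorrelation; the partial Mantel with a distance covariate
  mitigates but does not remove this.
- The published bird/lizard community matrices are supplementary files of
  the original study and are not redistributed; analyses that need them
  look for CSVs under `data/` and fail informatively otherwise.
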