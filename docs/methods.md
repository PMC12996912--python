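# Methods

This note documents the statistical procedures implemented in `corticov`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and known limitations.

## Preprocessing

Per region, cortical thickness is regressed by ordinary least squares on an
intercept plus the configured covariates (default `age`, `sex`; categorical
covariates are one-hot encoded with the first level dropped). Residuals are
divided by their sample SD (ddof = 1), so every downstream stage consumes a
subjects × regions matrix of standardized residuals with column mean 0 and
SD 1. The fit is performed jointly across the analysis sample by default; a
`subset` mask restricts it when within-group residualization is wanted.
Zero residual variance in any region aborts — it signals thickness that is
an exact function of the covariates, which only degenerate simulated input
produces.

Site harmonization is a per-site location–scale standardization (subtract
site mean, divide by site SD, restore the grand mean and pooled SD per
region). It is a deliberately simple, pluggable stand-in for empirical-Bayes
batch harmonization: the downstream mathematics needs only covariate-free
residuals, and full empirical-Bayes shrinkage is an external method outside
this package's scope. With one site it is the identity; singleton sites and
zero within-site variance are errors.

## Symptom dimensions

Integer row sums of 0–5 global scores: amotivation = avolition–apathy +
anhedonia–asociality; diminished expression = alogia + blunted affect;
analogous positive and disorganization composites from the positive-symptom
scale. Missing components propagate to missing dimensions — nothing is
imputed; each analysis pair then drops incomplete rows (listwise per pair)
and logs counts.

## Association statistics

* **Spearman** uses mid-ranks (ordinal symptom sums contain heavy ties) and
  the two-sided t-approximation p-value, clipped into (0, 1].
* **Bootstrap CIs** resample subjects with replacement, jointly over (x, y)
  pairs, and take the percentile interval of the resampled Spearman
  coefficients. Paired resampling is the default because resampling one
  margin against the fixed other destroys the association being
  interval-estimated; the single-margin variant exists behind
  `paired=False` for replication of ambiguous descriptions. Resamples with
  a constant margin are redrawn (≤ 100 sweeps, then an error).
* **FDR** is Benjamini–Hochberg step-up (statsmodels backend), rejection ⇔
  adjusted p ≤ q, default q = 0.05.
* **Partial Spearman** rank-transforms all three vectors, residualizes the
  x- and y-ranks on the covariate ranks, and correlates the residuals
  (t-approximation on n − 3 df).
* **Dependent-correlation comparison** (two overlapping correlations
  sharing variable j): Fisher-transform r_jk and r_jh, compute Dunn–Clark's
  covariance term c with the backtransformed average
  r̄ = tanh((z_jk + z_jh)/2) substituted for both correlations, and
  Z = (z_jk − z_jh)·√((n − 3)/(2 − 2c)). The default p is one-sided
  (directional hypotheses about which correlation is stronger);
  `two_sided=True` doubles the minimum tail. Inconsistent correlation
  triples (non-positive-semidefinite 3×3 matrix) are rejected.

## Covariance networks

For one subject with standardized residuals z the kernel
C(i,j) = exp(−(z_i − z_j)²) maps residual similarity into (0, 1] with unit
diagonal. The kernel choice resolves an ambiguity between an "inverse
exponential" and an "inverse squared difference" reading of the same
construction: the literal reciprocal 1/Δ² diverges as Δ→0 and cannot be a
bounded similarity, so the Gaussian-type kernel is the default and the
regularized reciprocal 1/(1 + Δ²) is available as `kernel="inv_sq_eps"` for
sensitivity analysis. The two kernels are strictly-monotone transforms of
each other, hence rank-identical for a single subject or a single
group-mean profile; after averaging across subjects the equivalence is only
approximate (empirically, profile rank correlations > 0.99).

Mean networks average the per-subject matrices element-wise. A single
profile vector (meta-analytic group-mean thickness) flows through the same
path as an n = 1 cohort.

**Alignment** correlates a seed's mean-covariance profile with an effect
map (Spearman by default — the reported statistic in the emulated analyses
is a rank correlation). The seed's self-entry is excluded from both vectors
by default: it is pinned at 1 and would mechanically couple with the seed's
own effect size; `include_seed=True` restores it for exact-replication
attempts. `rank_networks` repeats the alignment for all 68 seeds and sorts
by |rs| descending, ties broken by region index.

## Effect maps

Per region, Spearman between the residual column and the symptom vector,
missing symptom values dropped pairwise, at least 10 complete pairs. Maps
carry raw correlation coefficients (no Fisher transform): all downstream
comparisons are rank-based, so any strictly monotone rescaling is
immaterial (asserted by test).

## Spin-permutation null

Correlations between parcellated brain maps are inflated by spatial
autocorrelation; the spin test builds a null that preserves it. Rotations
are drawn uniformly from SO(3) (QR of a Gaussian matrix with the sign-fix
that makes the factorization unique, then a determinant correction); the
right hemisphere receives the mirrored rotation F·R·F with F = diag(−1,1,1)
so homologous parcels rotate to homologous places. Each parcel is
reassigned the value of the same-hemisphere parcel whose rotated centroid
has the greatest dot product with its own — the parcel-centroid variant;
many-to-one assignments are accepted, as is standard when no vertex-level
surface is available. The test statistic convention rotates the
symptom/effect map (map_a) and keeps the covariance or connectivity profile
fixed.

p_spin = (1 + #{null at least as extreme})/(1 + n_rot); the smallest
attainable value with 1000 rotations is 1/1001. Two-tailed by default; the
tail convention is configurable because published reports often leave it
unstated and borderline values (p ≈ 0.05) can flip. Exclusion sets (e.g.
the seed region) are removed from both vectors *after* permutation, so
excluded positions still donate values to rotated maps. Variogram-matching
and Moran-spectral surrogates are intentionally out of scope; the
`SpinEnsemble` container is the natural extension point.

## Epicenter mapping

For each region, Spearman between its connectivity row (structural zero
self-entry dropped from both vectors by default, `include_self` to keep)
and the effect map; spin significance per region with the region excluded;
ranking by |r| descending with the sign reported — the strongest epicenters
of thickness *reduction* have negative r, so ranking by signed r would
invert the intent. Ties break by region index. `run_both_modalities` runs
functional and structural connectomes and flags regions significant in
both. The scan is invariant to global positive rescaling of the connectome
(rank-based), and an epicenter need not carry a large own effect — both
properties are asserted by test.

## Synthetic data: the stated world

`make_atlas` places 34 quasi-uniform centroids (Fibonacci lattice with a
small seeded jitter) on the left half-sphere and mirrors them to the right,
using the standard 34 cortical region names per hemisphere so default ROI
lists resolve. `simulate_connectome` uses w_ij = exp(−d_ij/λ) + symmetric
Gaussian noise (clipped, symmetrized, zero diagonal) with geodesic centroid
distances; defaults λ = 0.75 rad, noise SD 0.05 (functional) and λ = 0.5,
noise 0.03 (structural).

`simulate_cohort` draws latent residuals from a multivariate normal with
correlation Σ = I + 0.6·W/ρ(W) (positive definite by construction), forms
alteration weights a from the epicenter's connectivity row (self-weight set
to the row maximum, unit norm), and generates the amotivation propensity
m = −γ⟨a, z⟩ + σ·ε. The propensity is quantile-thresholded into an 11-level
total split across the two amotivation globals, preserving rank order;
diminished-expression globals derive from an independent propensity, and
positive/disorganization scores, depression totals and doses are
independent nuisance columns. Thickness is 2.5 mm baseline per-region
variation − 0.01 mm/yr of age + 0.05 mm sex difference + site shift/scale +
0.12 mm × z — magnitudes typical of adult cortical morphometry. Defaults:
49 subjects per arm (the emulated study's arm sizes), γ = 1.5 and σ = 1,
chosen from the analytic target formula so the strongest planted per-region
Spearman is ≈ −0.28 (mean |ρ| ≈ 0.10), the magnitude of the ROI
associations reported in this literature. The analytic targets use the
Gaussian identity ρ_s = (6/π)·asin(r/2); realized maps track them with mean
absolute deviation ≈ 0.04 at n = 500.

`simulate_network_load` states the world for covariance-network recovery: a
hub seed shares its latent factor with 45 scattered partner regions at
coupling r = 0.5, and the symptom is the negative projection of residuals
onto the seed's empirical covariance profile plus N(0, 0.2²) noise. The
hub-and-spokes form is deliberate: when latent correlation decays smoothly
with distance, neighbouring seeds' covariance profiles differ by less than
the sampling noise of a 67-parcel rank correlation and *no* method can
single out the planted seed; likewise low-rank factor structure makes all
profiles collinear. A seed with a distinctive distributed network is the
identifiable case, and the scientifically interesting one.

What the generator does **not** emulate: scanner physics and realistic MRI
noise spectra, longitudinal structure, non-Gaussian thickness
distributions, item-level symptom scoring, empirical connectome topology
(hubs, modules, hemispheric asymmetries). A green recovery test therefore
establishes that the estimators recover structure they are designed for
under a Gaussian, stationary world — not performance on empirical data.

## Numerical choices

* p-values are clipped to [tiny, 1]; perfect rank correlations report the
  smallest positive double rather than 0.
* Bootstrap intervals are widened minimally to bracket the point estimate
  (percentile intervals can exclude it by a hair in skewed resamples).
* Connectome asymmetries ≤ 1e−6 are averaged silently; larger ones are
  averaged with a warning.
* The covariance kernel exp(−Δ²) is floored at the smallest positive
  double so extreme residual gaps cannot underflow outside the documented
  (0, 1] range.
* Spin null correlations that are undefined (a rotation maps a constant
  sub-vector onto the kept set) count as 0 — conservative for two-tailed p.
* All randomness descends from one configured seed; per-stage seeds are
  SHA-256 hashes of the stage name and seed, reduced below 2³¹.
* Ranking ties (identical |r|) break by region index, making orderings
  deterministic.

## Known limitations

* The location–scale site harmonization ignores site-by-covariate
  interactions and shrinkage across regions.
* Parcel-centroid spins approximate surface-based rotation; with 68
  parcels the null has coarse granularity and many-to-one assignments.
* The dependent-correlation z test assumes large-sample normality of
  Fisher-transformed rank correlations; at n ≪ 50 its calibration degrades.
* Percentile bootstrap coverage for rank correlations is known to run
  slightly below nominal (≈ 94–96% at n = 100) — acceptable here, but BCa
  intervals would be the upgrade path.
* Epicenter inference is correlational; no spreading dynamics are fitted.
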