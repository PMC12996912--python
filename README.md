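# corticov

Structural covariance networks, spin-permutation spatial nulls and
connectome epicenter mapping for parcellated cortical thickness data.

## What it is for

Negative symptoms along the bipolar–schizophrenia spectrum — especially the
**amotivation** dimension (SANS avolition–apathy + anhedonia–asociality) —
have been linked to reduced orbitofrontal cortical thickness. Testing
whether such localized associations reflect system-level organization
requires three layers of analysis beyond ROI correlations:

1. **ROI association statistics.** Spearman correlations between
   covariate-corrected thickness residuals and symptom dimensions, with
   paired percentile-bootstrap confidence intervals, Benjamini–Hochberg FDR,
   partial rank correlations (e.g. controlling for antipsychotic dose), and
   the backtransformed-average z test (Hittner) for comparing two dependent,
   overlapping correlations:
   Z = (z_jk − z_jh)·√((n−3)/(2−2c)), with Dunn–Clark's covariance term c
   evaluated at r̄ = tanh((z_jk+z_jh)/2).
2. **Intra-individual structural covariance networks.** Per subject s with
   standardized residuals z, regions i and j are assigned the bounded
   similarity C_s(i,j) = exp(−(z_i − z_j)²); subject matrices are averaged
   into mean covariance networks C̄(seed,·), whose spatial alignment with a
   brain-wide symptom **effect map** (per-region rs between residuals and
   the symptom) is tested against a **spin-permutation null**: parcel
   centroids are randomly rotated on the sphere (mirrored rotations across
   hemispheres) so the null preserves spatial autocorrelation.
3. **Epicenter mapping.** Each region's normative functional/structural
   connectivity profile is spatially correlated with the effect map; regions
   ranked by |r| with spin significance. An epicenter is strongly connected
   to strongly altered regions — it need not itself be strongly altered.

Real cohort and consortium data are out of scope here; the package ships a
**synthetic-data module** that generates 68-region atlases, distance-decay
connectomes and cohorts with planted, recoverable structure (covariate
effects, site effects, ordinal 0–5 symptom scores, a connectome-spreading
amotivation effect anchored at a chosen epicenter), so every stage is
testable against ground truth.

## Worked example

```bash
corticov simulate --out-dir sim --seed 7 --epicenter rh_medialorbitofrontal
corticov print-defaults > config.yaml   # edit paths/out_dir, keep defaults
corticov run-all --config config.yaml
```

or through the library:

```python
import corticov as cv
cfg = cv.RunConfig(atlas="sim/atlas.csv", cohort="sim/cohort.csv",
                   connectome_fc="sim/connectome_fc.csv",
                   connectome_sc="sim/connectome_sc.csv",
                   out_dir="run", rng_seed=7)
cv.run_pipeline(cfg)
```

With seed 7 and the planted epicenter in the right medial OFC, the run
directory contains (abridged):

`associations.csv` — ROI × symptom Spearman with bootstrap CIs and FDR:

```
                    roi     rs  p_fdr  ci_low  ci_high  significant
lh_lateralorbitofrontal -0.222  0.112  -0.404   -0.032        False
rh_lateralorbitofrontal -0.092  0.490  -0.307    0.134        False
 lh_medialorbitofrontal -0.121  0.374  -0.315    0.078        False
 rh_medialorbitofrontal -0.166  0.251  -0.342    0.015        False
```

Negative rs means thinner cortex with worse amotivation. At the default
98-subject cohort the planted effect (|rs| ≈ 0.1–0.25 at the ROIs) is
visible but does not survive FDR — a realistic power situation.

`epicenters_functional.csv` — every region's connectivity profile correlated
with the amotivation effect map, spin-test p, ranked by |r|:

```
           region_name       r  p_spin  rank
rh_medialorbitofrontal -0.6036   0.021     1
        lh_frontalpole  0.6018   0.037     2
             rh_insula -0.6012   0.016     3
```

The planted epicenter is recovered at rank 1 (functional) and rank 2
(structural): its connectivity profile matches the map of symptom-related
thickness reductions (negative r), which is the epicenter signature.

`run_manifest.json` records the config echo, per-stage seeds, library
versions and SHA-256 hashes of all outputs; identical configs reproduce
bit-identical CSVs.

## Acceptance script

`scripts/acceptance.py` re-runs the entire pipeline from scratch on
simulated data — atlas, connectomes and cohort generated from the given
seed, then residualization, symptom scoring, associations, effect maps,
covariance-network ranking and epicenter scans at the default settings
(4 ROIs, 1000 bootstrap resamples, 1000 spin rotations, q = 0.05):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
|---|---|
| `corticov.atlas_io` | atlas/connectome/cohort readers & writers, region-order law |
| `corticov.synthetic_data` | generators with planted ground truth |
| `corticov.preprocessing` | OLS residualization, per-site location–scale harmonization |
| `corticov.symptom_dimensions` | SANS/SAPS composite dimension scoring |
| `corticov.association_stats` | Spearman, bootstrap CI, BH-FDR, partial Spearman, Hittner Z |
| `corticov.effect_maps` | brain-wide per-region symptom correlation maps |
| `corticov.covariance_networks` | exp(−Δ²) covariance kernel, mean networks, alignment, ranking |
| `corticov.spatial_null` | uniform SO(3) spins, mirrored hemispheres, permutation p |
| `corticov.epicenter_mapping` | connectivity-profile scans, dual-modality ranking |
| `corticov.pipeline` / `corticov.cli` | config-driven orchestration, `corticov` CLI |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
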