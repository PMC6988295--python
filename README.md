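# cytolv

Latent-variable profiling of multiplex (Luminex-style) cytokine panels.

Given a sample-by-analyte concentration table and per-sample group labels
(or a continuous phenotype), the pipeline:

1. normalizes concentrations to pg per mg total protein and drops analytes
   stuck below their detection limit in a majority of samples
   (`cytolv.panel`),
2. z-scores each analyte within the samples being compared,
3. fits a two-component NIPALS partial least squares model — discriminant
   (PLSDA, group-indicator response) or regression (PLSR, continuous
   response) mode (`cytolv.pls`),
4. applies an orthogonal rotation in the LV1–LV2 plane choosing a new LV1
   that maximizes a separation objective (designated-group contrast,
   omnibus Welch F, or phenotype correlation), with the rotated weight
   pair's scalar product checked against a 1e-15 orthogonality bound
   (`cytolv.profiles`),
5. estimates the stability of the per-analyte LV weights by Monte-Carlo
   subsampling (default 80% of samples, 1000 iterations, without
   replacement, stratified by group), refitting the whole pipeline per
   subsample and sign-correcting each refit against the full model, and
6. tests composite LV scores with Welch's ANOVA plus Dunnett-T3-style
   pairwise comparisons, or Pearson correlation against the phenotype
   (`cytolv.stats`), with optional ROUT-style robust outlier removal for
   univariate per-analyte statistics.

A synthetic-data generator (`cytolv.synthetic`) produces log-normal panels
with known group effects, a cooperative interaction effect in a combined-
pathology group, correlated analyte noise, detection-limit censoring, and
phenotypes coupled to the injected inflammation factor, so every stage can
be validated against ground truth.

## CLI

```sh
# write a synthetic panel + metadata + ground truth
cytolv simulate --scenario dbdb_like --seed 1 --out sim/

# discriminant analysis: rotated LV profiles, scores, ANOVA tables
cytolv plsda --panel sim/panel.csv --meta sim/metadata.csv \
    --contrast APP_PS1xdb_db --fraction 0.8 --iterations 1000 \
    --seed 1 --out results/plsda

# regression against a continuous phenotype
cytolv plsr --panel sim/panel.csv --meta sim/metadata.csv \
    --phenotype glucose --seed 1 --out results/plsr

# per-analyte Welch ANOVA + pairwise table with ROUT outlier removal
cytolv univariate --panel sim/panel.csv --meta sim/metadata.csv \
    --out results/uni
```

All flags can come from a YAML file via `--config`; explicit flags win.
Every run writes a `manifest.json` with the seed, a config hash, library
versions, the selected rotation angle, and a note that testing a
separation that the rotation was optimized for is a selection effect —
calibrate against the `null` scenario when in doubt.

Panel CSVs have a header row of analyte names, one row per sample, and an
optional `__lod__` row carrying per-analyte detection limits. Metadata
CSVs carry `sample_id`, `group`, optional `sex`, and any continuous
phenotype columns.

## Tests and acceptance

```sh
python -m pytest -q tests/            # unit + property + acceptance suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds the binding criteria: the rotation
orthogonality bound at every grid angle, SVD-oracle equivalence of the
first PLS component, brute-force equivalence of the rotation search,
exact subsampling degeneracies, Welch-ANOVA algebraic identities,
Dunnett-T3 family-wise error calibration, end-to-end recovery of injected
interaction effects, and ROUT calibration. The acceptance script runs a
seeded end-to-end self-check; there are no numeric report targets because
the pipeline's reference study deposited no data.
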