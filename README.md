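# bymspat

Areal Bayesian disease mapping for suburb-level ecological analyses:

* **geo_adjacency** — planar area maps (GeoJSON in/out), queen/rook
  contiguity graphs, GeoBUGS-style adjacency text files
  (`num`/`adj`/`sumNumNeigh`, 1-based in the file, 0-based in memory).
* **ecological_indices** — internally standardized expected counts and
  SMRs, entropy / Simpson / neighbourhood (metropolitan-reference)
  diversity indices, Index of Concentration at the Extremes.
* **factor_analysis** — correlation screening, Bartlett sphericity,
  KMO/MSA, principal-axis factoring, direct-oblimin rotation with Kaiser
  normalization (gradient projection), reporting with sub-0.30 loadings
  masked.
* **bym_mcmc** — Besag–York–Mollié spatial regression
  (`log RR = beta0 + X beta + u + v`, intrinsic-CAR `u`, iid `v`) fitted
  by MCMC with Poisson or lognormal likelihood, N(0, 10000) coefficient
  priors and Gamma(0.5, 0.0005) precision priors; DIC/pD, Gelman–Rubin,
  batch-means MC error, posterior and odds-ratio summaries.
* **model_selection** — forward covariate selection by mean DIC over
  repeated seeded runs, with the "decrease > 1 and every coefficient
  significant" acceptance rule.
* **decomposition** — exact per-draw multiplicative decomposition of
  posterior relative risk into intercept, per-covariate, spatially
  structured and unstructured surfaces, exported as CSV/GeoJSON.
* **synthetic_data** — connected grid/Voronoi lattices, factor-structured
  covariates, ICAR sampling and BYM-generated outcome counts with known
  ground truth for end-to-end testing.

## CLI

Each stage is a subcommand reading a JSON (or YAML) config and writing
outputs plus a run manifest into `output_dir`:

```sh
bymspat simulate  --config sim.json    # synthetic dataset + truth.json
bymspat indices   --config idx.json    # expected counts/SMR, diversity indices
bymspat efa       --config efa.json    # screening, diagnostics, pattern matrices
bymspat fit       --config fit.json    # BYM fit, DIC, posterior summaries
bymspat select    --config sel.json    # forward DIC selection trace
bymspat decompose --config dec.json    # RR component surfaces (CSV + GeoJSON)
```

Minimal `fit` config:

```json
{
  "seed": 1,
  "output_dir": "out/fit",
  "paths": {
    "outcomes_csv": "out/sim/outcomes.csv",
    "covariates_csv": "out/sim/covariates.csv",
    "adjacency": "out/sim/adjacency.txt"
  },
  "covariates": ["var01", "var02"],
  "bym": {"burn_in": 3000, "samples": 3000, "n_chains": 2}
}
```

Provide exactly one of `paths.adjacency` (GeoBUGS text) or
`paths.areas_geojson` (polygons; contiguity derived with the `contiguity`
key, default queen). All randomness flows from the top-level `seed`.

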