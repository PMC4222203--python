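# oceansdm

Presence-only species distribution modelling for ocean plankton, built
around a from-scratch maximum-entropy model (hinge features only, L1
penalty with a configurable beta multiplier) plus the classic envelope
algorithms (Bioclim, Envelope Score, Environmental Distance with four
metrics). The package covers the full workflow:

* **grids** — regular lat/lon environmental layers (SST, salinity, nitrate,
  silicate) with an ocean mask; ESRI ASCII grid and classic NetCDF I/O,
  bilinear/nearest regridding, unit harmonization (K→°C, mol m⁻³→µmol L⁻¹),
  mask-intersecting stack alignment.
* **occurrences** — CSV parsing, grid-cell deduplication in *yearly* (one
  record per occupied cell) or *monthly* (one per cell-month) mode,
  covariate extraction from annual or per-month layers, uniform or
  bias-grid-weighted background sampling, sampling-effort bias grids.
* **maxent** — hinge feature construction at quantile knots, deterministic
  cyclic coordinate descent with exact soft-thresholded line searches,
  raw (normalized) and logistic outputs, per-variable percent contributions
  from the gain trace, JSON model serialization.
* **envelopes** — Bioclim percentile envelopes, min–max envelope scores,
  and distance-to-presence-mean suitability (euclidean / mahalanobis /
  manhattan-gower / chebyshev), normalized by the training background.
* **projection** — suitability maps, thresholding, multi-model consensus
  counts, climate-ensemble mean/SD maps over pseudo-GCMs, per-longitude
  range-boundary profiles, rank-based AUC, k-fold cross-validation,
  jackknife variable importance, response curves.
* **synthetic** — a fully synthetic ocean (meridional SST/nutrient
  gradients, seasonal SST cycle, nitrate–silicate decoupling band, random
  land blobs, a known true suitability surface, seasonally biased presence
  sampling, warmed/nutrient-depleted future scenarios) so the whole
  pipeline runs end-to-end with no downloads.

## Command line

The `sdm` entry point chains the stages; every subcommand reads and writes
plain-text artifacts (ASCII grids, CSV, JSON):

```bash
sdm simulate --seed 5 --n 200 --out env/            # synthetic layers + occurrences
sdm prepare  --occurrences env/occurrences.csv --env-dir env \
             --mode monthly --background 10000 --seed 42 --out run1/
sdm fit      --prepared run1/ --beta-multiplier 1.0 --knots 30 --out model.json
sdm fit-envelope --prepared run1/ --kind env_distance --metric chebyshev --out ed.json
sdm project  --model model.json --env-dir env --month 2 --out feb.asc
sdm consensus --maps 'maps/*.asc' --threshold 0.2 --out consensus.asc
sdm evaluate --prepared run1/ --model model.json --cv 5 --seed 42 --out eval.json
sdm regrid   --in coarse.asc --like fine.asc --method bilinear --out out.asc
sdm run      --config config.yaml --out demo_run/   # full pipeline + manifest
```

`sdm run` executes simulate → prepare (yearly and monthly) → fit (maxent +
six envelope models) → project (annual and all 12 months) → future GCM
ensembles → consensus → evaluation, and writes `manifest.json` listing every
artifact with a content hash; reruns with the same config and seed are
bit-identical. The YAML config mirrors those stages (see
`oceansdm.config.DEFAULTS` for all keys and defaults).

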