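# screenmix

Empirical-Bayes mixture-model analysis of arrayed colony-fitness screens.

`screenmix` takes raw colony-size tables from high-density agar-plate
screens (384/1536 format) through a complete statistical pipeline:

1. **Plate normalization** — per-plate median scaling, or GFP-free
   reference-strain scaling for validation re-screens.
2. **Log growth ratios (LGRs)** — `ln(control / experimental)` per strain,
   averaged over one or two control conditions; dead/sick strains are
   flagged, never scored as infinities.
3. **Spatial smoothing** — self-excluding windowed-median correction of
   smooth plate artifacts, preserving isolated hits and the plate median.
4. **Z-scores** — classical standardization (mean 0, sd 1).
5. **Mixture modelling** — a five-parameter two-component Gaussian mixture
   (central/null peak + right-shifted hit peak) fit by multi-start EM, with
   BIC comparison against a single normal and automatic classification
   (`hit_peak` / `no_hit_peak` / `high_variance`).
6. **Hit calling** — the posterior probability q(x) of hit-peak membership,
   the `L_q,0.5` cutoff (q = 0.5) and the classical `L_Z` cutoff (Z = 2),
   with the q-based list used when the mixture fit supports it and the
   Z-based list otherwise.
7. **Validation prediction** — pV(x), the predicted probability that a
   strain validates in a 16-replicate re-screen (predicted FPR = 1 − pV),
   plus binned empirical FPR from real or simulated validation data.
8. **Cross-screen comparison** — (ρ2, μ2) screen-parameter tables,
   correlation-distance matrices, UPGMA clustering with Newick export, and
   "frequent flyer" detection across screens.
9. **Simulation** — a plate-level generator (lognormal colony sizes, plate
   offsets, spatial gradients, mixture-structured gene effects, replicate
   noise, GFP-free controls, matched validation re-screens) with ground
   truth, so the whole pipeline is testable with no external data.

## CLI

All stages are exposed through one entry point:

```sh
# simulate a screen (flat YAML config mirroring SimConfig)
screenmix simulate --config sim.yaml --out-dir sim/

# colony table -> per-strain LGR/Z screen table
screenmix normalize --colonies sim/colonies.tsv --geometry 16x24 \
    --plate-norm plate_median --smooth-window 7 --out screen.tsv

# fit the two-component mixture
screenmix fit --screen screen.tsv --seed 17 --starts 10 --out fit.tsv

# call hits under both cutoffs
screenmix hits --screen screen.tsv --fit fit.tsv --method auto --out hits.tsv

# predicted FPR curve (plus empirical bins when validation data are given)
screenmix fpr --fit fit.tsv --out fpr.tsv

# cluster screens by correlation distance (average linkage, Newick output)
screenmix compare --matrix matrix.tsv --axis screens --out-tree tree.nwk

# or run the whole pipeline at once (writes a run manifest)
screenmix run --colonies sim/colonies.tsv --seed 17 --out-dir results/
```

All tabular artifacts are TSV with `#`-prefixed metadata comments and `NA`
as the missing-value token; grid coordinates are 1-based integers.

## Python API

```python
from screenmix import (SimConfig, simulate_screen, colony_frame,
                       fit_mixture, FitConfig)
from screenmix.pipeline import run_pipeline

cfg = SimConfig.for_target_lgr(n_genes=4000, seed=1, rho2=0.15,
                               mu2=1.0, sigma1=0.2, sigma2=0.4)
obs, truth = simulate_screen(cfg)
result = run_pipeline(colony_frame(obs), cfg.geometry,
                      fit_config=FitConfig(seed=1))
print(result.fit.classification, result.cutoffs, result.method)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery over 20 simulated screens, cutoff ordering, cutoff dynamic range,
FPR calibration, oracle equivalence for q(x)/L_q/UPGMA, EM monotonicity).
One optional test re-analyzes the published 28-screen dataset and is
skipped unless `SCREENMIX_S2_DIR` points at a directory of per-screen LGR
TSVs (one `lgr` column each).

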