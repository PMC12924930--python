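# tilgraph

Spatial graph features of tumor-infiltrating lymphocytes (TILs) and
multiparametric modeling of neoadjuvant-therapy response.

Given cell centroids inside a tumor bed (as emitted by any nuclei
segmenter) the package computes a 371-feature spatial catalogue per core —
density-based cluster morphometrics (130), Voronoi (12), Delaunay (8),
minimum-spanning-tree (4), density (216) and TIL frequency (1) — aggregates
cores per patient under seven schemes, and trains clinical / graph /
probability-ensemble classifiers with collinearity filtering, z-scoring,
floating forward feature selection (fold-internal SMOTE), randomized
hyperparameter search, and DeLong ROC comparison. A synthetic-data module
generates point patterns (CSR / Thomas / hard-core), multi-core patients,
labeled cohorts and H&E-like tiles so the whole pipeline is testable without
external data.

## Library quick start

```python
from tilgraph import (Window, ProcessParams, simulate_core, extract_all,
                      default_registry)

core = simulate_core(ProcessParams(process="THOMAS", parent_intensity=1e-4,
                                   offspring_mean=10, offspring_sd=8, seed=0),
                     Window(500, 500))
vector = extract_all(core)        # 371 named features
registry = default_registry()     # name / family / parameter / statistic
```

## CLI

One entry point, `tilgraph`, with stage subcommands:

```bash
# synthetic inputs
tilgraph simulate cohort --n-patients 50 --pcr-fraction 0.3 --seed 1 --out-dir data/

# image front end (Otsu foreground, 750 px tiles with <=10% background,
# Macenko stain normalization) and tumor-bed filtering
tilgraph prep tile --image core.png --tile-size 750 --max-background 0.10 --out tiles.csv
tilgraph prep normalize --image tile.png --reference ref.png --out norm.png
tilgraph prep filter-tils --centroids data/centroids.csv --tiles data/tiles.csv --out tils.csv

# feature extraction (one row per core, 371 columns + ids)
tilgraph features extract --centroids data/centroids.csv --tiles data/tiles.csv \
    --out features.csv --registry-out registry.json

# modeling (config: feature_group, aggregation, classifiers, folds,
# selection_iterations, tuning_budget, seed)
tilgraph model train --config cfg.json --features features.csv \
    --clinical data/clinical.csv --out run/

# 100-weight ensemble scan and paired ROC comparison
tilgraph eval ensemble --clinical run/probs_xgb.csv --graph run/probs_gnb.csv --out ens.json
tilgraph eval compare --model-a run/probs_xgb.csv --model-b run/probs_gnb.csv
```

Text formats: centroid tables (`cell_id,core_id,x_px,y_px,cell_type`), tile
lists (`core_id,tile_x_px,tile_y_px,tile_size_px`), clinical tables
(`patient_id,pcr_label` + covariates), feature matrices (CSV), registry
(JSON).

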