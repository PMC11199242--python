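# mstate

EEG microstate analysis of resting-state and response-locked (go/no-go) data:
polarity-invariant modified k-means topographic clustering, meta-criterion
selection of the number of microstates, template backfitting with
Besag-penalized temporal smoothing, per-state temporal statistics (GEV,
duration, coverage, occurrence), microstate-guided scoring of the
error-related negativity (ERN), and the downstream association statistics
(robust outlier removal, hierarchical regression, Benjamini-Hochberg
correction). A synthetic-data module generates resting recordings, go/no-go
epochs and cohort tables with serialized ground truth so every stage is
testable offline.

## Package layout

| module | contents |
|---|---|
| `mstate.core` | `Topography`, `Recording`, neighbor graphs, average reference, GFP, spatial filter, GFP-peak extraction, epoch rejection/interpolation, trimming |
| `mstate.io` | plain-matrix (TSV + YAML sidecar), EDF and BrainVision readers; matrix/JSON writers |
| `mstate.clustering` | `spatial_correlation`, `modified_kmeans` (invariant/variant), seven cluster-validity criteria, `meta_criterion`, resampled clustering, group aggregation |
| `mstate.backfitting` | GFP-median normalization, gated backfitting, Besag-penalized smoothing, minimum-segment rule, temporal statistics |
| `mstate.ern` | trial filtering, condition averaging, difference waves, grand-average segmentation, error-microstate identification, ERN scoring and residualization |
| `mstate.stats` | MCD outlier flagging, hierarchical regression with F-change test, BH step-up correction |
| `mstate.synth` | template-map, resting, go/no-go and cohort simulators with ground truth |

## CLI

```bash
# generate synthetic data (fully seeded, bit-for-bit reproducible)
mstate simulate rest   --out sim/rest   --seed 1 --channels 32 --k 4 --duration 157
mstate simulate gonogo --out sim/gng    --seed 1 --n-go 120 --n-nogo 80
mstate simulate cohort --out sim/cohort --seed 1 --n 90 --effect ern_resid=0.7

# preprocessing, segmentation, backfitting
mstate preprocess --input sim/rest/rest.tsv --trim-seconds 157 --out prep
mstate segment  --input prep/preprocessed.tsv --k-min 1 --k-max 12 --restarts 20 --seed 1 --out seg
mstate backfit  --input prep/preprocessed.tsv --states seg/maps.tsv --min-corr 0.5 \
                --smooth-half-ms 32 --besag 10 --min-seg-ms 32 --out fit

# microstate-guided ERN scoring (auto window/ROI from the difference wave)
mstate ern --go sim/gng/go_avg.tsv --nogo sim/gng/nogo_avg.tsv \
           --times sim/gng/times_ms.tsv --seed 1 --out ernout

# association models
mstate stats --table sim/cohort/cohort.csv --models models.yaml --bh-m 8 --out statsout
```

`models.yaml` declares one entry per model:

```yaml
models:
  - dependent: rest_gev
    step2: ern_resid
    step1: [age, sex]
    transform: {rest_gev: sqrt}
```

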