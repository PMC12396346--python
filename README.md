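# gliaquant

Quantification pipelines for neuron–glioma interaction assays, packaged as a
tested Python library with a CLI and a synthetic-data module so every stage
runs offline with known ground truth.

## What it does

- **`gliaquant.sc_state`** — single-cell expression processing: cell filtering
  by detected genes (2000 for smart-seq2, 1000 otherwise), top-k gene
  filtering (default 7000 by mean expression), `log2(CPM/10 + 1)`
  normalization, per-sample centering, signature scoring against
  expression-bin-matched control genes (30 bins, 100 controls per gene),
  OPC/OC/AC state scores, the stemness–lineage 2-D cell-state representation
  (stemness = OPC − max(OC, AC); lineage = signed max(OC, AC) with seeded
  jitter when both are negative), receptor-high cell flagging (centered
  value > 1), pseudo-bulk aggregation over malignant cells, within-sample and
  across-sample (per-study) Pearson/Spearman correlation screening, and
  Benjamini–Hochberg FDR adjustment.
- **`gliaquant.photometry`** — fiber-photometry trace processing: mono-/
  bi-exponential debleaching (model chosen by corrected AIC), baseline
  z-scoring, LOESS smoothing (tricube local linear regression, default
  fraction 0.1), and trapezoidal AUC over analysis windows
  (pre/during/post-stimulation).
- **`gliaquant.puncta`** — synaptic puncta quantification: slice-wise
  rolling-ball background subtraction, difference-of-Gaussians peak detection
  in physical units (anisotropic voxels supported), and colocalization as the
  percentage of postsynaptic puncta within 1.5 μm (3-D Euclidean) of the
  nearest presynaptic punctum.
- **`gliaquant.assay_metrics`** — proliferation indices (e.g. EdU⁺/DAPI⁺,
  per field, pooled, and per-group) and spheroid migration ratios normalized
  to the time-zero diameter.
- **`gliaquant.synth`** — seeded generators for all of the above: a
  negative-binomial three-state count matrix with planted signatures and an
  optional state-coupled receptor gene, bleach+events+noise photometry
  traces, 3-D puncta fields with a known colocalized fraction (optionally
  rendered as Gaussian-blob stacks), and Bernoulli-labelled cell tables.

## CLI

A single `gliaquant` entry point with subcommands (see `--help` on each):

```sh
# generate synthetic inputs with ground truth
gliaquant simulate sc         --config sc.yaml     --seed 1 --out sim/
gliaquant simulate photometry --config photo.yaml  --seed 1 --out sim/
gliaquant simulate puncta     --config puncta.yaml --seed 1 --out sim/ [--render]
gliaquant simulate cells      --config cells.yaml  --seed 1 --out sim/

# single-cell state pipeline (MTX triplet or dense TSV input, GMT signatures)
gliaquant scstate run --matrix sim/ --signatures sim/signatures.gmt \
    --receptors CHRM1,CHRM3 --correlate --out out/

# photometry session (CSV trace + YAML windows)
gliaquant photometry run --trace sim/trace.csv --config session.yaml --out out/

# puncta colocalization (TIFF stacks or puncta CSVs)
gliaquant puncta run --pre pre.tif --post post.tif --voxel 0.15,0.1,0.1 \
    --sigma 0.3 --radius 2.0 --threshold 1.5 --out out/

# tabular assay metrics
gliaquant metrics proliferation --cells cells.csv --numerator EdU \
    --denominator DAPI --out out/
gliaquant metrics migration --spheroids spheroids.csv --out out/
```

Session YAML example for `photometry run`:

```yaml
baseline_window: [0, 300]
windows:
  pre:    [300, 600]
  during: [600, 900]
  post:   [900, 1200]
frac: 0.1        # LOESS smoothing fraction
model: null      # or "mono"/"bi" to skip AICc selection
```

## Layout

```
src/gliaquant/
  synth.py          # seeded generators + ground truth
  sc_state.py       # expression matrix ops, scoring, stemness/lineage, FDR
  photometry.py     # debleach, z-score, LOESS, AUC
  puncta.py         # rolling ball, DoG detection, colocalization
  assay_metrics.py  # proliferation index, migration ratio
  io.py             # MTX/TSV/GMT/CSV/JSON readers and writers
  cli.py            # typer CLI
tests/              # unit, property, and acceptance tests
scripts/acceptance.py
```
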