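# simscorr

Correlative EM/NanoSIMS image analysis: tiled multi-pass instance
segmentation of organelles on large EM images, morphological filtering,
landmark registration of ROI masks onto NanoSIMS ion images, ion-count
corrections (dead time, inter-plane drift), per-organelle ¹⁵N-enrichment
extraction, and pulse–chase exponential-decay half-life estimation with
group statistics.

The package ships a fully synthetic test bed: EM-like phantom images with
ground-truth organelle masks and matched Poisson ion-count stacks whose
per-class enrichment decays with known half-lives under a known EM→SIMS
similarity transform, known inter-plane drift and optional dead-time
distortion. Every pipeline stage is validated against these phantoms, so no
external data are required.

## Modules

| Module | Purpose |
|---|---|
| `simscorr.phantom` | synthetic EM phantoms, matched ion stacks, full on-disk studies |
| `simscorr.preprocess` | histogram matching, offset multi-pass tile grids |
| `simscorr.segment` | segmentation backend contract, deterministic toy backend, polygon-label dataset export |
| `simscorr.assemble` | multi-pass detection merging, shape descriptors, morphological filtering |
| `simscorr.metrics` | IoU, precision/recall/F1, AP, mAP@0.5–0.95, confusion matrix |
| `simscorr.sims` | ion-count stacks, dead-time correction, drift estimation, plane accumulation |
| `simscorr.register` | similarity-transform fitting from anchors, mask warping, automatic nucleus anchors |
| `simscorr.turnover` | ROI/multipoint enrichment, half-life decay fitting, group t-tests |
| `simscorr.pipeline` | end-to-end orchestration from one YAML config with a reproducibility manifest |

The enrichment decay model is explicit:
`E(t) = E_nat + (E0 − E_nat) · 2^(−t / t_half)`, so the fitted time constant
is the half-life directly. The default baseline `E_nat = 0.0037` is the
natural ¹⁵N/¹⁴N abundance and is configurable everywhere.

## CLI

`simscorr` exposes each stage as a subcommand:

```bash
simscorr simulate --config phantom.yaml --out study/      # synthetic study
simscorr preprocess --image in.tif --reference ref.tif --out matched.tif
simscorr segment --image in.tif --backend toy --frame 640 --passes 5 --out det.json
simscorr assemble --detections det.json --passes 5 --out rois
simscorr evaluate --truth-png t.png --truth-csv t.csv --pred-png p.png --pred-csv p.csv
simscorr dataset --images study/ --out dataset/ --splits 0.8,0.2
simscorr sims-correct --cn14 a.tif --cn15 b.tif --meta meta.json --out corr
simscorr register --anchors anchors.csv --out transform.json
simscorr quantify --rois-png r.png --rois-csv r.csv --cn14 c14.tif --cn15 c15.tif --out meas.csv
simscorr fit --series meas.csv --baseline 0.0037
simscorr compare --series meas.csv --groups hNPC,postmitotic
simscorr run --config study.yaml --out results/              # everything
```

`simscorr run` consumes a study YAML (see `simscorr.phantom.make_study` for
a generator) and writes per-sample artifacts, a long-format measurements
table, per-class decay fits, group comparisons, and a `manifest.json`
recording the config hash, versions, seeds, pass offsets and stage timings.

## Notes

- Ion stacks are ingested as multi-page TIFF plus a JSON sidecar
  (species, dwell time, dead time); vendor raw formats are an upstream
  conversion step.
- The neural detector used in production settings is a drop-in
  `SegmentationBackend`; only the deterministic classical toy backend is
  bundled (no trained weights are distributable, and pipeline correctness
  is independent of the detector choice).
- Deliverables are text-only: masks as indexed PNG + CSV tables, labels as
  normalized polygon text files, metrics as JSON/CSV.
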