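# icdetect

Patch-based detection and localization of invasive carcinoma (IC) on
breast whole-slide images, with a two-phase **master → calibrated**
transfer-learning workflow for adapting the classifier to a new
acquisition center from a small amount of local data.

The pipeline mirrors the classic WSI screening layout:

1. **Filtering** — tissue mask (HSV saturation), epithelial-nuclear region
   detection (hematoxylin color deconvolution + local density), parsing of
   the regions into 256×256 patches at "x20" (pyramid level 0), rejection
   of blur / no-tissue / no-nuclei patches. Filtering typically discards
   the vast majority of the slide.
2. **Classification** — for each kept x20 patch, the same-center 256×256
   "x5" context image (downsample-4 level) is scored by a CNN feature
   extractor with a random-forest head. The score is attributed to the
   x20 patch.
3. **Slide scoring** — patch threshold `P0` (picked by F1 maximization on
   validation data), slide score `S_IC = Σ_{P>P0} P / N`, binary slide
   call, and a blue→red heatmap.
4. **Two-phase training** — a master model trained on a reference-center
   cohort; a calibrated model obtained by fine-tuning the master (no
   frozen layers, same hyperparameters) on a ~10× smaller target-center
   training set, with the RF head refit and `P0` re-selected.

Everything is exercisable without any real WSI: `icdetect.synthetic`
generates pyramidal slides (tiled multi-page TIFF + GeoJSON annotations +
TSV manifests) with labeled epithelial/IC regions and parametric
per-center appearance (stain colors, hue, brightness, noise, scanner
resolution), so inter-center domain shift exists by construction.

The default feature extractor is `tiny_cnn`, a small convolutional
network implemented in pure NumPy (training included), so the package has
no deep-learning-framework dependency; a torchvision ResNet50 backbone is
available where torch is installed.

## CLI

```sh
icdetect synth --patients 4 --slides-per-patient 2 --ic-fraction 0.5 \
    --slide-size 2048 --out cohort/                    # synthetic cohort
icdetect filter --slide cohort/P000_S0.tiff --out patches.tsv --report rep.json
icdetect extract --cohort cohort/manifest.tsv --out patches/
icdetect train --cohort cohort/manifest.tsv --out master/
icdetect calibrate --master master/ --cohort target/manifest.tsv --out calibrated/
icdetect infer --slide s.tiff --bundle master/ --heatmap h.png   # exit: 0 Rest, 2 IC, 3 no epithelium
icdetect score --manifest scored.tsv --p0 0.5 --slide-threshold 0.1
icdetect evaluate --predictions preds.tsv --level slide
icdetect two-phase --reference ref/manifest.tsv --target tgt/manifest.tsv --out run/
```

Filter thresholds live in a YAML mirroring `FilterConfig`; training
options mirror `TrainConfig` (BCE + Adam, initial lr 0.001, early
stopping, no frozen layers ever).

## Layout

```
src/icdetect/
  synthetic.py    # slide/cohort/patch generators, CenterStyle
  slide_io.py     # pyramids (tiled TIFF), GeoJSON ROIs, manifests, heatmaps
  filtering.py    # tissue mask, epithelium detection, patch parsing, QC flags
  backbone.py     # NumPy tiny CNN (im2col conv, Adam, BCE)
  augment.py      # flips/rotations/noise/hue/sat/contrast/brightness
  classifier.py   # training, RF head, bundles, calibration
  scoring.py      # P0 selection, S_IC, slide calls, metrics
  pipeline.py     # patient-level splits, inference, two-phase workflow
  cli.py          # `icdetect` entry point
```
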