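# hecif — reticulin-free quantitation of bone marrow fibrosis from H&E

Marrow fibrosis in myeloproliferative neoplasms (MPNs) is conventionally
graded on reticulin silver stains, a technique that is fragile in routine
laboratories: stain intensity varies widely between runs and sites, and the
destain/restain handling tends to detach bone and peri-trabecular tissue.
`hecif` implements a pipeline that learns to read fibrosis severity
directly from routine H&E-stained trephine sections, producing a
**Continuous Index of Fibrosis (CIF)** in [0, 1] per image tile instead of
a discrete 0–3 grade, together with slide-level heatmaps, stain/tissue QC
metrics and a subsampling-based fibrosis-heterogeneity (biopsy adequacy)
analysis.

It is aimed at computational-pathology researchers who want a fully
testable, desk-scale reference implementation of the approach: every stage
can be exercised on synthetic paired-stain *phantoms* with known ground
truth, so no clinical images or pretrained weights are required.

## Method

1. **Phantoms** (`hecif.phantom`) — synthetic co-sectioned slide pairs: a
   latent fibrosis field *f*(x) ∈ [0, 1], fibre strokes whose local density
   increases monotonically with *f* in both pseudo-stains, bone trabeculae
   and fat vacuoles, a known affine misalignment between the stain frames,
   per-slide colour drift and a bone-loss artefact in the pseudo-reticulin
   rendering.
2. **Tiling** (`hecif.tiling`) — tissue masking by luminance/saturation
   thresholding plus morphology; 512 px tiles (≈113 µm at 0.22 µm/px) on a
   fixed grid inside the tissue mask; *analysable* tiles have
   fat < 50 % and bone < 1 % (strict).
3. **Registration** (`hecif.register`) — a global affine transform between
   the stain pair estimated from the two tissue masks (moment
   initialisation, overlap refinement); tile centres are mapped across
   stains to cut matched, unresampled H&E tiles.
4. **Preprocessing** (`hecif.preprocess`) — channel-wise histogram
   equalisation, which removes global additive stain shifts exactly while
   preserving within-channel rank order.
5. **Ranking CNN** (`hecif.cifmodel`) — a small convolutional network
   trained on ordered tile pairs (i ≻ j whenever the teacher label gap is
   ≥ δ) with the pairwise logistic loss
   L = log(1 + e^−(s_i − s_j)); the scalar output is min–max calibrated to
   [0, 1] over the training set. The teacher is pluggable: phantom ground
   truth by default, or any callable producing per-tile labels (e.g. a
   reticulin-based scorer). The network is implemented in NumPy with
   manual backpropagation, so no deep-learning framework is needed.
6. **QC** (`hecif.qc`) — per-slide dominant colour in RGB and CIELAB
   (D65/2°), bone area in mm², analysable-tile counts; cohort comparisons
   by bootstrap colour-dispersion test and paired Wilcoxon.
7. **Subsampling** (`hecif.subsample`) — regions covering 2/15 … 10/15 of
   the analysable tiles are grown around random centres; a slide is
   *heterogeneous* when any smallest-fraction region's mean CIF deviates
   from the whole-slide CIF by > 0.1.

## Worked example

Run the full pipeline on four simulated slide pairs (Python API; the CLI
equivalent is `hecif run --manifest manifest.json --config config.yaml
--seed 1 --out run/`):

```python
from hecif.manifest import PairManifest, SampleEntry
from hecif.pipeline import PipelineConfig, run_end_to_end

def entry(i, mean):
    return SampleEntry(sample_id=f"phantom{i}", group="synthetic", phantom_spec={
        "width_px": 640, "height_px": 640, "tissue_scale": 1.3,
        "fibrosis_field": {"kind": "smooth", "mean": mean, "amplitude": 0.3,
                           "correlation_length_px": 70},
        "n_bone_blobs": 2, "fat_fraction": 0.06, "bone_loss_fraction": 0.3,
        "stain_drift_sd": 2.0, "ret_stain_drift_sd": 10.0,
        "misalignment": {"rotation_deg": 2.5, "translation_px": [10, -6]},
        "seed": 101 + i})

manifest = PairManifest([entry(i, m) for i, m in enumerate([0.2, 0.45, 0.7, 0.85])])
config = PipelineConfig.from_dict({"tile_size": 96, "seed": 1, "subsample_draws": 10,
    "train": {"input_px": 48, "channels": [6, 12], "epochs": 4, "seed": 1}})
run_end_to_end(manifest, config, "run/")
```

Output (per-sample `cif.csv`, `heatmap.png`, `subsample.json`; cohort
`qc_*.json`, `adequacy.csv`, `provenance.json`):

```
phantom0: slide CIF 0.284 over 14 tiles -> heterogeneous
phantom1: slide CIF 0.388 over 14 tiles -> heterogeneous
phantom2: slide CIF 0.592 over 13 tiles -> homogeneous
phantom3: slide CIF 0.617 over 14 tiles -> heterogeneous
colour dispersion ret/he trace ratio: 13.8
bone area he : 0.000198 0.000163 0.000265 0.000168 mm²
bone area ret: 0.000139 0.000114 0.000185 0.000118 mm²
```

The slide CIF values rise with the phantoms' latent severity means (0.2,
0.45, 0.7, 0.85); the reticulin arm shows ~14× the colour dispersion (it
was generated with 5× the drift) and ~0.7× the bone area (30 % simulated
bone loss). This tiny 4-epoch configuration is only illustrative — the
default desk-scale configuration (64 px inputs, 3 conv blocks, 8 epochs,
≥ 500 tiles) reaches held-out pairwise ranking accuracy and Spearman
correlation ≥ 0.9 against the latent severity, as checked by the test
suite.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main end-to-end computation from scratch —
simulating a phantom cohort, registering, tiling, training the ranking
model, scoring, QC and subsampling — and writes its JSON result to the
given path.

## Layout

```
src/hecif/          phantom, tiling, register, preprocess, cifmodel,
                    qc, subsample, manifest, pipeline, cli
tests/              pytest suite (unit + property + acceptance)
docs/methods.md     modelling and numerical notes
```
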