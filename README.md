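# spectravasc

Quantification of tissue vascularization from intravital spectral imaging.

Blood absorbs visible light below ~600 nm far more strongly than the
surrounding tissue, which autofluoresces under laser excitation. Picking the
excitation/emission pair that maximizes this contrast makes vessels appear as
sharply dark structures on a bright background, and a simple, user-independent
pipeline — weighted channel combination, automatic thresholding, edge
refinement — can then measure the blood-vessel area per mm² of tissue with
pixel-size accuracy. This package is aimed at researchers quantifying
(anti-)angiogenesis in small-animal models who want an inexpensive optical
readout validated against microvessel-density (MVD) style counting.

The package provides:

- **`spectral_model`** — Beer–Lambert contrast prediction. For a channel with
  excitation/emission absorption μa(ex), μa(em) and vessel diameter d, the
  predicted contrast is C = 100·(1 − e^(−(μa(ex)+μa(em))·d)) percent
  (2·μa(ex) when no emission filter is used), with an embedded whole-blood
  absorption table.
- **`phantom`** — a synthetic-data generator standing in for the camera:
  branching vessel networks with exact ground-truth masks, blood path maps,
  true areas and an MVD-analog count, rendered per channel through the same
  optical model, plus tumor-vs-control cohorts.
- **`imaging_io`** — TIFF channel libraries (`ex488_em550.tif`, …,
  `ex635_emnone.tif` + `library.json` sidecar), mask TIFFs, CSV results.
- **`contrast`** — measured vessel/tissue contrast per channel,
  C = 100·(Ī_tissue − Ī_vessel)/Ī_tissue, and channel ranking.
- **`segmentation`** — the quantification pipeline:
  combine → Otsu threshold → hysteresis edge refinement → area in mm² and as
  a fraction of the tissue ROI.
- **`validation`** — cohort experiments: Student's t-test, one-way ANOVA,
  and OLS regression (R²) of measured area against the MVD analog.

## Worked example

```
$ spectravasc simulate --out demo/lib --seed 7 --area-target 0.08
INFO spectravasc: wrote 4 channels to demo/lib (true area 0.3091 mm^2, MVD analog 4)

$ spectravasc contrast --library demo/lib --out demo/contrast.csv
INFO spectravasc: ex488_em550      contrast  84.27%
INFO spectravasc: ex488_emnone     contrast  71.10%
INFO spectravasc: ex590_emnone     contrast  31.16%
INFO spectravasc: ex635_emnone     contrast   2.83%
```

The ranking is the channel-selection physics in action: the 488 nm
excitation / 550 nm emission pair sits on strong hemoglobin absorption bands
(~84% contrast), while 635 nm light is barely absorbed by blood, leaving only
a few percent of contrast — that channel is useless for vessel detection.

```
$ spectravasc quantify --library demo/lib --out demo/area.csv
INFO spectravasc: vessel pixels 5506, area 0.3097 mm^2, fraction 0.0840 of 3.6864 mm^2 ROI
```

The measured 0.3097 mm² recovers the phantom's true 0.3091 mm² to 0.2%
despite the 2% sensor noise in the simulated images.

```
$ spectravasc validate --seed 1 --out demo/report.csv
INFO spectravasc: tumor 1.5354 +/- 0.2354 mm^2 vs control 0.5404 +/- 0.0479 mm^2 (p=5.322e-06)
INFO spectravasc: area vs MVD analog: R^2 = 0.9609 (n=16)
```

A 16-subject synthetic cohort (3 control + 13 tumor): tumor-bearing subjects
show the expected ~3× larger vascularization area (two-sided Student's t),
and the pipeline's area measurements regress tightly against the
histology-style MVD analog.

The same machinery is available as a library; see the module docstrings and
`docs/methods.md` for the model, parameter meanings, and limitations.

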