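# lome — low-mass-ion discriminant equations for serum screening

`lome` builds and validates **LOw-Mass-ion discriminant Equations**: signed
linear classifiers over small panels of low-mass ions (m/z ≤ 2500) from
MALDI-TOF serum profiles, of the kind used to screen one disease class
(e.g. a cancer) against everything else — healthy controls, other cancers
and benign conditions — from a single blood sample.

The score of a sample is

    DS = Σ_{i ∈ panel} w_i · x_i

where `x_i` is the Pareto-scaled intensity of reference ion `i` and `w_i`
its weighting factor from PCA-based discriminant analysis (PCA-DA); DS > 0
(or a trained threshold) screens positive.  The package implements the full
construction pipeline:

- **Preprocessing**: ppm-tolerance alignment of replicate measurements to a
  reference mass spectrum, total-area normalization, Pareto scaling,
  weighting, replicate averaging — with all scaling statistics fitted on
  the training set and frozen before they ever touch validation data.
- **PCA-DA** weighting factors (the loading vector) and data-driven
  selection of the best-separating replicate as the reference measurement.
- **Search algorithm 1**: preliminary candidates — ions whose weighted
  intensity magnitude exceeds 0.1 in more than half of the training
  columns.
- **Search algorithm 2**: a germination/growth combinatorial search over 2-
  and 3-ion combinations maximizing sensitivity + specificity, with
  fewest-ions and largest-Fisher-ratio tie-breaking.
- **Two-stage training**: stratified trisection into Sets A1/A2/B, weights
  from A1 only, panel from A = A1 ∪ A2, untouched validation on B, panel
  augmentation with externally identified ions and threshold training.
- **Synthetic cohorts** with planted discriminative ions and full ground
  truth, so every stage is testable without access to clinical spectra.

See `docs/methods.md` for the model, its assumptions and design choices.

## Worked example

```python
from lome import (CohortConfig, RunConfig, generate_cohort, build_lome, trisect)

# a desk-scale synthetic cohort: 4 classes x 10 samples x 6 measurements,
# 300 ions, 3 planted markers with a 3-log-unit effect
cfg = CohortConfig(n_per_class=10, n_ions=300, n_planted=3,
                   effect_size=3.0, rng_seed=11)
spectra, manifest, truth = generate_cohort(cfg)
manifest["set"] = manifest["sample_id"].map(trisect(manifest, ("label",), 11))

model, report = build_lome(spectra, manifest, RunConfig(rng_seed=11))
print("planted:", [round(m, 4) for m in truth.planted_mz])
print("panel:  ", [round(m, 4) for m in report["panel_mz"]])
print("Set B:  ", {k: report["sets"]["B"][k] for k in
                   ("sensitivity", "specificity", "ppv", "npv")})
```

prints

```
planted: [1328.4489, 1472.3291, 2004.2796]
panel:   [1328.4834]
Set B:   {'sensitivity': 100.0, 'specificity': 100.0, 'ppv': 100.0, 'npv': 100.0}
```

The search found that a single planted ion (1328.45, recovered on the
reference axis at 1328.48 — within the 300 ppm matching tolerance)
separates the training set perfectly, so the panel stops there; the frozen
model then classifies every held-out Set B sample correctly.  Metrics are
percentages: sensitivity TP/(TP+FN), specificity TN/(TN+FP), and the
positive/negative predictive values.

The same workflow is available from the shell:

```
lome simulate --config cohort.yaml --seed 7 --out cohort/
lome train    --manifest cohort/manifest.csv --seed 7 --out model/
lome score    --model model/ --manifest cohort/manifest.csv --out scores.csv
lome evaluate --model model/ --manifest model/training_manifest.csv \
              --input cohort/ --set B --out report.json
```

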