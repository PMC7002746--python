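# erqc — quantitative QC of ER immunohistochemistry via internal-control dynamic range

Estrogen receptor (ER) status in breast carcinoma is reported from an
immunohistochemistry (IHC) stain: a tumor with ≥ 1% nuclei stained at any
intensity is "ER positive".  A small fraction of tumors (~1%) land in the
ambiguous low-ER band (1–10% of cells), where a weak staining run is hard to
distinguish from genuinely low biology.  Normal breast ducts on the same
slide are the internal control: their luminal epithelium should express ER
across a broad biological range.  `erqc` quantifies that range.  For every
annotated duct it measures each nucleus's mean DAB optical density (OD) and
computes the duct's **dynamic range**

```
DR = (max positive mean nuclear DAB OD − min positive mean nuclear DAB OD) × 100
```

over nuclei at or above a detectability threshold τ (default 0.10 OD).  A
collapsed DR in internal controls flags a staining artefact and supports
repeating the test rather than trusting a low-ER read.

The package is aimed at pathology image-analysis and biostatistics users and
provides, end to end:

- **`erqc.stains`** — Beer–Lambert RGB↔OD conversion, Ruifrok–Johnston H-DAB
  stain vectors, Macenko-style (plane/percentile) stain-vector estimation,
  and linear color deconvolution into hematoxylin / DAB / residual maps.
- **`erqc.detect`** — watershed nucleus detection inside GeoJSON duct
  annotations, plus three automated exclusion rules (merged objects ≥ 2
  nominal nuclear areas, fragments < 0.5, non-nuclear shapes by
  circularity).
- **`erqc.quantify`** — per-nucleus positivity, per-duct dynamic range,
  per-case summaries, and a reference-quantile QC flag.
- **`erqc.stats`** — the inferential layer: for duct-level responses
  `y_ij` of case *i*, a maximum-likelihood linear mixed model

  ```
  ln y_ij = β₀ + β₁·cohort_i + b_i + ε_ij,
  b_i ~ N(0, σ_b²),   ε_ij ~ N(0, σ²·v_ij^(2δ))
  ```

  with a per-case random intercept and residual variance following a power
  δ of the duct's positive-cell count `v_ij` (nlme's varPower structure);
  the variance structure is chosen by likelihood-ratio test and AIC.
  Student's t, Fisher's exact and Spearman tests round out the toolkit.
- **`erqc.simulate`** — a calibrated synthetic-data generator: duct-level
  cohort tables with the study's case/duct variance structure, and rendered
  H-DAB duct images with per-nucleus ground truth, so the whole pipeline is
  testable without clinical images (which are not public).

## Worked example

```python
import numpy as np
from erqc import (RenderSpec, render_duct, rgb_to_od, deconvolve,
                  default_hdab_matrix, detect_nuclei, apply_exclusion_rules,
                  duct_dynamic_range)
from shapely.geometry import shape

spec = RenderSpec(n_nuclei=12, dab_od_values=tuple(np.linspace(0.12, 0.9, 12)))
image, truth, annotation = render_duct(spec, seed=5)

maps = deconvolve(rgb_to_od(image), default_hdab_matrix())
polygon = shape(annotation["features"][0]["geometry"])
retained, excluded = apply_exclusion_rules(detect_nuclei(maps, polygon))
m = duct_dynamic_range(retained)
print(len(retained), m.positive_count, round(m.dynamic_range, 1),
      round(truth.true_dynamic_range(0.10), 1))
```

prints

```
12 12 77.5 78.0
```

— all 12 rendered nuclei detected and retained, all 12 positive at τ = 0.10,
and a measured dynamic range of 77.5 against a ground-truth 78.0 (the
difference comes from edge pixels and the 0.02-OD rendering noise).

Cohort-level comparison from the shell:

```
erqc simulate --seed 5 --out sim/
erqc compare --low sim/low_er.csv --control sim/control.csv --out cmp/
```

`cmp/report.md` then shows the per-cohort medians, the chosen variance
structure, and the mixed-model contrast, e.g. β₁ ≈ −0.62 with p ≪ 0.001:
low-ER internal controls sit well below the clinical controls on the log
scale.

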