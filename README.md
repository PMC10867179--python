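# melvasc

Quantitative analysis of the tumor-associated lymphovasculature and immune
infiltrate in multiplexed chromogenic immunohistochemistry (mIHC) of primary
cutaneous melanoma.

Sequential chromogenic mIHC stains one marker per round (AEC chromogen over a
hematoxylin counterstain), strips, and re-stains, yielding a registered
grayscale image per marker for each region of interest (ROI). `melvasc` takes
such a 13-marker stack — S100, panCK, AQP1, CD34, αSMA, MECA79, PDPN, LYVE-1,
CD45, CD8, CD20, CD68, hematoxylin — and computes, per ROI and per sample:

- **Compartments**: tissue (triangle threshold on hematoxylin), intratumoral
  (IT: S100⁺ tumor nests after an alternating sequential filter, excluding
  single S100⁺ cells), and peritumoral (PT = tissue ∖ IT) masks.
- **Vessels**: candidate objects from the union of Otsu-binarized AQP1, CD34
  and PDPN channels (denoised, top-hat flattened, size-filtered, PDPN⁺panCK⁺
  basal epithelium removed), gated hierarchically into five subtypes:

  | family | profile | subtype |
  |---|---|---|
  | blood (AQP1⁺) | CD34⁺ αSMA⁺ | immature neovasculature |
  | blood (AQP1⁺) | CD34⁺ αSMA⁻ | activated capillary / postcapillary venule |
  | blood (AQP1⁺) | CD34⁻ αSMA⁺ | arteriole |
  | lymphatic (PDPN⁺) | LYVE-1⁺ | lymphatic capillary |
  | lymphatic (PDPN⁺) | LYVE-1⁻ | inflamed lymphatic capillary |

  AQP1⁺CD34⁻αSMA⁻ objects are rejected as single tumor cells; MECA79
  positivity on an AQP1⁺ vessel raises a cross-cutting HEV-like flag.
  Morphology (area, lumen area, perimeter, eccentricity, solidity, form
  factor) is extracted per object.
- **Leukocytes**: nuclei by smoothing + Otsu + watershed on hematoxylin,
  gated into mutually exclusive CD8 T cell / B cell / macrophage (CD68-first,
  tolerating weak myeloid CD45) / other CD45⁺ / non-leukocyte classes.
- **Spatial read-outs**: per-region densities (objects/mm²) and within-family
  subtype proportions; the IT:PT CD8 density ratio classifying each ROI as
  infiltrated or excluded; tertiary lymphoid structures (TLS) as single-
  linkage co-aggregations of CD8⁺ T and CD20⁺ B cells with their associated
  HEV-like and PDPN⁺ vessels.
- **Statistics**: ROI→sample aggregation, normality-gated t/rank tests and
  Pearson/Spearman correlations, one-way ANOVA, and Ward clustering of
  per-sample leukocyte density profiles into inflammatory environments
  (inflamed / T-cell-rich / uninflamed).

Patient slides are not redistributable, so the package ships a first-class
synthetic-data module (`melvasc.simulate`) that generates ground-truth-
annotated ROIs — tumor nests, annular vessels with subtype marker profiles,
leukocyte disks, TLS aggregates, Beer–Lambert chromogen-mixed RGB rounds —
against which every pipeline stage is validated.

## Worked example

```python
from melvasc import analyze_roi, generate_roi, random_roi_spec

spec = random_roi_spec(seed=1)          # 1 mm² ROI: 20 vessels, 300 cells, 1 TLS
stack, truth = generate_roi(spec)       # 13 channels + ground-truth tables
result = analyze_roi(stack)

print(len(result.vessels), "vessels,", len(result.cells), "cells,",
      len(result.tls), "TLS")
s = result.summary
print("infiltration:", s.infiltration, " IT:PT CD8 ratio:",
      round(s.cd8_it_pt_ratio, 2), " HEV-like vessels:", s.n_hev_vessels)
```

prints

```
20 vessels, 299 cells, 1 TLS
infiltration: INFILTRATED  IT:PT CD8 ratio: 1.69  HEV-like vessels: 2
```

— all 20 planted vessels are recovered (subtypes included), 299 of the 300
planted cells are detected, the planted T/B-cell aggregate is called as one
TLS, and this ROI's intratumoral CD8 density exceeds its peritumoral
density, so it is classed as infiltrated.

The same pipeline runs from the shell on a config file:

```sh
melvasc simulate --seed 1 --out demo/
melvasc run --config run.yaml --out results/run
melvasc report --summaries results/run/roi_summaries.csv \
               --manifest manifest.csv --out results/report
```

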