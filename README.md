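# slicequant

Quantification and chemosensitivity classification for ex vivo tumor-slice
drug-response assays.

Organotypic tissue slices — thin (~300 μm) living sections of a freshly
resected tumor — can be cultured for days and treated with chemotherapy at
a ladder of concentrations, offering a patient-specific readout of drug
sensitivity. `slicequant` implements the analysis side of such an assay
for breast carcinoma slices treated with FAC (5-fluorouracil, Adriamycin/
doxorubicin, cyclophosphamide — ex vivo as its active metabolite 4-HC):

* **Image quantification** of fixed, stained sections from multi-channel
  fluorescence fields (DAPI, pan-cytokeratin, EdU, TUNEL):
  - proliferation: EdU⁺ cells per cytokeratin⁺ tumor area,
    `PI = N_EdU / (A_keratin · p²) × 10⁴` cells per 10⁴ μm² (pixel size
    *p* in μm), via grayscale hole filling, Sobel edge detection and
    morphological cleanup for the area, and size-filtered component
    counting for the cells;
  - cell death: the Manders-style overlap fraction
    `100 · |DAPI ∩ TUNEL| / |DAPI|` of Otsu-binarized channels —
    the percentage of nuclear (DAPI) pixels that are TUNEL-positive.
* **The FAC dilution ladder**: 11 dilutions at the clinical molar ratio
  5-FU : doxorubicin : 4-HC = 46 : 1 : 22, one decade per three steps
  (doxorubicin 10 μM at dilution 1 down to 0.01 μM at dilution 10,
  dilution 11 untreated).
* **Threshold calling and classification**: per tumor and readout
  (manual nuclear-morphology calls, EdU inhibition, TUNEL induction), the
  threshold dilution is the most dilute concentration at which the effect
  criterion holds through an unbroken run from the strongest tested
  dilution; tumors are classed sensitive (threshold ≥ 7), resistant
  (≤ 2 or never) or intermediate.
* **Synthetic microscopy**: a seeded generator producing fields and whole
  dose-response cohorts with exact ground truth (nucleus positions,
  memberships, keratin mask), standing in for patient material in all
  validation.

A 15-tumor reference cohort (histopathology plus per-readout threshold
dilutions) ships with the package.

## Worked example

```python
from slicequant import FieldSpec, generate_field, quantify_field

image, truth = generate_field(FieldSpec(seed=42))   # 512x512, 0.7 um/px
q = quantify_field(image)
print(q.keratin_area_um2, q.edu_count, q.proliferation_index, q.tunel_pct)
```

Running `python examples/01_quantify_field.py` prints:

```
keratin-positive area : 126509 px = 61989 um^2
EdU-positive cells    : 9 (ground truth 9)
proliferation index   : 1.452 cells per 10^4 um^2 (ground truth 1.483)
TUNEL-positive DAPI px: 8.7% (membership fraction 8.3%)
```

The detected tumor area is within ~2% of the generator's mask, the nine
rendered EdU⁺ nuclei are counted exactly (the generator guarantees
non-touching nuclei, so counting has a correctness oracle), and the
proliferation index — 1.45 S-phase cells per 10⁴ μm² of tumor tissue —
matches the ground truth within 2%. The TUNEL figure is the share of
nuclear pixels flagged as dying.

`examples/` contains one short script per capability: field
quantification, the dilution ladder, cohort classification (reproducing
the reference cohort's 5/7/3 threshold split at dilutions 5/3/2),
simulated-cohort threshold recovery, and the full configured pipeline
(`simulate → quantify → dose-response → report`). The same stages are
exposed on the command line via `slicequant simulate | quantify |
dose-response | report`.

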