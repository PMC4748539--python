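# Methods

`slicequant` implements the analytical core of an ex vivo chemosensitivity
assay on organotypic tumor slices: thin living slices of a resected tumor
are cultured under a ladder of FAC chemotherapy dilutions, fixed, sectioned
and imaged, and each tumor is classified by the most dilute concentration
at which its slices still respond. This note records the models, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Readouts and per-field quantification

Each microscopy field carries up to four fluorescence channels: DAPI
(all nuclei), pan-cytokeratin (epithelial/tumor tissue), EdU (S-phase
nuclei after a labeling pulse) and TUNEL (fragmented DNA in dying cells).
All operators work on intensities normalized to [0, 1] from the image bit
depth, so user thresholds are bit-depth independent.

**Tumor area.** The cytokeratin channel is processed as: grayscale hole
filling by morphological reconstruction (marker = image maximum except on
the border, reconstruction by erosion), Sobel gradient magnitude
(Euclidean norm of the horizontal/vertical responses divided by the
maximum attainable response, √2, so the edge threshold lives on [0, 1]),
thresholding at `sobel_edge_threshold` (default 0.1), disk closing
(radius 2) to bridge gaps in the edge map, filling of enclosed regions,
then disk opening (radius 2). The opening runs *after* region filling: a
sharp step edge yields a 2-px-thick edge ring, and opening a 2-px ring
with any disk element annihilates it, so opening must smooth the filled
region rather than the raw ring. If no pixel exceeds the edge threshold
the operator returns area 0 with a "no edges detected" warning — a
uniform frame has no gradient and therefore no detectable area.

**EdU count.** The EdU channel is binarized at `edu_intensity_threshold`
(default 0.5); connected components with fewer than 10 pixels are
removed; enclosed holes are filled by reconstruction; the mask is eroded
with a flat disk (radius 1); components with more than 10 pixels are
counted. The two size rules are deliberately strict inequalities — an
object of exactly 10 px survives removal but is not counted after
erosion. Components use 8-connectivity (configurable).

**Proliferation index.** `edu_count / (keratin_area_px · pixel_size²) ×
10⁴` — EdU-positive cells per 10⁴ μm² of keratin-positive area. The
normalization confines the measurement to carcinoma tissue, so fields
with different stromal or lymphocytic content remain comparable. A field
with no detectable keratin is flagged ("no tumor tissue in field") and
excluded-and-counted, never imputed.

**Cell death.** Because nuclei in tissue sections are too crowded to
count individually, death is measured at the pixel level: DAPI and TUNEL
are each Otsu-thresholded independently and the readout is the
Manders-style binary overlap fraction, 100 · |DAPI ∩ TUNEL| / |DAPI|.
The Otsu implementation scans all cut levels of a 256-bin histogram for
the maximal between-class variance; tied maximizers are averaged, so a
two-valued image thresholds at the midpoint between its values. A
constant channel raises a "degenerate histogram" error. Note that Otsu on
a *signal-free but noisy* channel bisects the noise distribution and
reports a large spurious overlap — a known failure mode of automatic
thresholding; fields should carry at least some genuine signal in each
thresholded channel.

**Slice summaries.** Field-to-field heterogeneity is summarized by the
median and interquartile range over the fields of a slice (quartiles by
linear interpolation). The number of fields per slice defaults to 10.

## Dilution ladder and threshold calling

The FAC combination (5-fluorouracil, doxorubicin, and the pre-activated
cyclophosphamide metabolite 4-HC) is always mixed at the clinical molar
ratio 46 : 1 : 22 and laid out over 11 dilutions: doxorubicin runs from
10 μM at dilution 1 down by the repeating step pattern ÷2, ÷2, ÷2.5 (one
decade per three steps) to 0.01 μM at dilution 10; dilution 11 is the
untreated control. Dilutions 2–7 plus control are tested by default.

Effect criteria per dilution (both configurable):

* **EdU inhibition** — median proliferation index < 0.5 × control median;
* **TUNEL induction** — median TUNEL% > control median + 1.5 × control IQR;
* **morphology** — manual binary calls (karyolysis, pyknosis,
  karyorrhexis, apoptotic bodies on H&E) supplied as data; the package
  only aggregates them, it never scores histology.

**Threshold semantics.** The threshold dilution is the *most dilute*
concentration (largest index) at which the effect still holds, reached
through an unbroken run of affected dilutions from the strongest tested
one. This is the only reading under which the most sensitive cohort group
carries the largest threshold index and the resistant tumors score 2.
Isolated flags at weaker dilutions beyond a gap are ignored with a
warning; enabling any flag can never lower a called threshold
(a property-tested invariant). Classes: threshold ≥ 7 sensitive,
≤ 2 or never resistant, otherwise intermediate. Whether a threshold of
exactly 3 should count as resistant is ambiguous in the assay's verbal
definition; ≤ 2 was chosen and both boundaries are parameters.

## Synthetic-microscopy generator

No imaging data were deposited with the study, so validation rests on a
seeded generator that emulates the statistical structure the operators
assume, with exact ground truth:

* **Nuclei** are disks (radius uniform in 3–5 px) placed by rejection
  sampling with center separation ≥ 2·r_max + 3 px and a border margin.
  This is a *generator guarantee*, not a biological claim: it makes exact
  object counting well-posed, so the EdU counter can be held to
  zero-error agreement with a brute-force component count.
* **Keratin region**: a Gaussian random field (σ = field/8) thresholded
  at the coverage quantile, hole-filled (simply connected truth) and
  cleared in an 8-px border band so blob contours close inside the frame;
  the coverage parameter is therefore nominal.
* **Memberships**: EdU members number round(edu_fraction · n_nuclei) and
  are drawn preferentially from nuclei inside the keratin region
  (proliferating cells are epithelial), which aligns the measured index
  (all EdU objects / keratin area) with the ground-truth index. TUNEL
  members are drawn preferentially from non-EdU nuclei.
* **Rendering**: structures at `foreground_level` (default 45 000) on
  `background_level` (1 000) in 16-bit range, additive Gaussian noise
  (σ = 500) clipped to the valid range. Identical spec + seed give
  bit-identical rasters; cohorts derive one recorded sub-seed per field
  from the master seed.

**Dose-effect model.** Per simulated tumor, expected EdU and TUNEL
fractions follow a four-parameter logistic in log₁₀ doxorubicin
concentration with floor 0: EdU falls from its baseline (default 0.15)
toward 0, TUNEL rises from its baseline (default 0.08) toward
`max_tunel_fraction` (default 0.6). The midpoint sits at the *geometric
mean* of the threshold dilution's concentration and the next weaker step,
so the labelled threshold is the weakest dilution with a supra-criterion
effect — centering exactly on the threshold concentration would leave the
expected response exactly at the 50% calling criterion and make recovery
a coin flip. The default Hill slope of 12 makes the transition complete
within one 2–2.5× dilution step, matching the switch-like onsets the
assay reports (tumors flip from no effect to complete inhibition between
adjacent dilutions). The slope value comes from a design-time margin
analysis: the TUNEL criterion (control median + 1.5 IQR) sits close to
baseline, so at the dilution one step weaker than the threshold the
logistic tail must stay several median-standard-errors below the cut;
with slope 12 the residual rise there is ≈1.5% of the dynamic range,
versus ≈6% at slope 8, which would misfire at the ~1% per-boundary level.

**Heterogeneity.** Realized per-field fractions are beta-distributed
around the dose-effect mean with standard deviation `heterogeneity_sd`
(default 0.03, capped below the beta feasibility bound); sd = 0
degenerates to the expectation exactly. The TUNEL baseline default of
0.08 keeps at least one TUNEL-positive nucleus in essentially every
field, avoiding the empty-channel Otsu artifact above. The generator also
has a fraction-level mode (`render=False`) that produces realized
fractions without rasterizing images — the statistical granularity at
which single-tumor recovery properties are tested; the full rendering
path is exercised by the 15-tumor end-to-end recovery run.

**What the generator does not emulate:** optical blur and uneven
illumination, nucleus shape variation and touching/overlapping nuclei,
intensity gradients within structures, autofluorescence, sectioning
artifacts, and any real spatial covariance between proliferation and
death. Passing tests therefore demonstrate the *correctness of the
operators and of the threshold logic under the assay's stated
assumptions*, not robustness to real histology; on real images the
user-defined thresholds are expected to need per-batch adjustment (they
were "semi-automatic" in the original workflow for the same reason).

## Validation problem sizes

Oracle and recovery runs use compact fields chosen so the statistics, not
the pixel count, dominate: Otsu is checked against exhaustive search on
1,000 random histograms; EdU counting against a brute-force BFS component
count on 200 seeded 128×128 fields; the end-to-end experiment simulates
the 15-tumor cohort (true thresholds set to the reference morphology
column) at 160×160 px, 24 nuclei, 10 fields per slice, dilutions 2–7 plus
control, over 20 master seeds, and requires the {5:5, 3:7, 2:3} histogram
in ≥ 90% of seeds. Threshold-recovery accuracy depends on fractions and
counts per field, not on field size, so the compact fields test the same
statistical contract as full 512×512 fields.

## Known limitations

* Morphology scoring is consumed as manual data; no H&E analysis.
* No pharmacokinetics: a constant-bath dilution ladder is not a plasma
  concentration profile, and thresholds are assay-relative, not clinical
  predictions.
* The TUNEL overlap fraction is a pixel measure; it tracks, but does not
  equal, the fraction of dying cells (large or bright nuclei weigh more).
* Otsu-based binarization assumes a bimodal histogram; near-empty
  channels are unreliable (see above).
* The dilution ladder assumes the printed ÷2, ÷2, ÷2.5 pattern exactly;
  arbitrary ladders can be supplied but threshold semantics assume
  monotone concentrations.
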