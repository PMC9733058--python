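# Methods

## Problem and model

Mismatch-repair (MMR) status of a colorectal tumor is read from the IHC
staining of four proteins (MLH1, PMS2, MSH2, MSH6) as two functional
heterodimer pairs: loss of MLH1 usually takes PMS2 with it, loss of
MSH2 takes MSH6, and isolated PMS2 or MSH6 loss also occurs. A tissue
core is *pathological* when at least one of the four protein sections
shows no nuclear staining; with all four stained it is *normal*. This
package scores each section automatically and treats the per-core
score as a triage marker — not a diagnosis — whose job is maximal
sensitivity: flagged cores go to the top of the pathologist's queue,
and nothing is ever removed from review.

The per-section score is SIS = B·W, where B is the mean DAB positivity
of strong-positive pixels on a 0–100 scale and W the stained fraction
of the core's tissue pixels. The denominator of W is the tissue mask,
not the image frame, so glass background cannot dilute the score. Each
core is summarized by the minimum SIS over its four sections (a single
lost protein must dominate), and the score-equal-to-cutoff boundary
classifies as normal (strict `<` for pathological; the choice is
arbitrary for continuous scores and documented rather than load-
bearing). Only cores with all four sections present are scoreable;
anything else raises an incomplete-core error. Scores are kept at full
precision and rounded to one decimal only in reports.

## Synthetic cohort generator

The generator emulates the structure of the modeled study and is the
test bed for every downstream stage. Defaults: 11 patients, 3 MMR-
deficient, 623 routinely fixed cores spread evenly over patients (60%
tumor, 40% normal mucosa), plus 337 over-fixed stock-tissue cores that
lose PMS2 nuclear staining and always fail QC; blocks hold up to 60
cores. Published counts for that study are mutually inconsistent at
face value (cores obtained vs excluded vs analyzed), which is resolved
here by treating the over-fixed batch as separate from the 623 study
cores and by letting a configured 323-core subset go to digital
quantification; all counts are config parameters, and the 146/177
test/validation split is a seeded uniform partition (the original
partition was never recorded, so it is unreproducible by construction).

Deficient patients draw a loss pattern from {MLH1+PMS2: 0.5,
MSH2+MSH6: 0.25, PMS2: 0.125, MSH6: 0.125} — heterodimer pairs
dominating, weights configurable. Latent section truth: stained
sections draw B from a truncated Normal(80, 10) on [0, 100] and W from
Beta(5, 3) (optionally scaled down by a focal-heterogeneity fraction,
off by default); unstained sections have B = 0 and W equal to a
background ceiling (0.05) times a Beta(2, 8) draw, so unstained W is
strictly below the ceiling. Observed tabular measurements add Gaussian
noise (default sd 4 on B, 0.02 on W) and clip to range. A consequence
worth stating plainly: with unstained W capped at 0.05 the unstained
SIS cannot exceed ~5, the two classes separate almost completely, and
the Youden cutoff lands in the low single digits of the 0–100 scale —
nothing like a mid-scale cutoff selected on real, messier material.
Passing tests on this generator therefore demonstrate correctness of
the machinery (scores, ROC, intervals, worklist), not expected clinical
operating points; real cohorts with partial staining, heterogeneity and
fixation gradients will overlap far more and yield much lower
specificity at a sensitivity-first cutoff. The synthetic histoscore is
emitted as 300·W·(0.55 + 0.45·B/100) plus noise — monotone in both
latent components but deliberately not an affine image of SIS, so the
paired-AUC comparison between the two scores is non-degenerate.

All randomness flows from one run seed through `numpy.random.
SeedSequence` substreams per stage, making every table and JSON output
byte-identical across reruns of a (config, seed) pair.

## Image rendering and quantification

Rendering uses the Beer–Lambert forward model: per-pixel optical
density OD = −log10(I/I0) with I0 = 255, mixed from the Ruifrok–
Johnston hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570,
0.776) vectors (unit-normalized, third basis vector their cross
product). A core is a disk occupying 0.47 of a 512×512 raster
(configurable); nuclei are random ellipses (radii 3.8–5.0 px) on a
jittered 7 px grid, dense enough that their union covers >90% of the
tissue, as in cell-rich tumor cores — this is what lets the renderer
hit stained-pixel fractions up to 0.9. DAB-positive nuclei are
accumulated in random order until the stained pixel count reaches
latent_W times the tissue area (granularity: one ~60 px nucleus out of
~180k tissue pixels), each carrying DAB OD = 1.25·latent_B/100 so that
measured B recovers latent_B; all nuclei carry hematoxylin OD ~
N(0.55, 0.06) over a 0.08 stroma background, plus small OD noise
(sd 0.015).

Quantification inverts the same matrix (clamping negative
concentrations), then: stained = DAB OD ≥ 0.15 (detection floor);
positivity bins weak/moderate/strong at OD 0.15/0.40/0.80; W =
stained/tissue pixels; B = mean of min(OD/1.25, 1)·100 over strong
pixels (0 when the strong bin is empty); histoscore = 100·(weak +
2·moderate + 3·strong) with fractions taken over the analysis region.
By default analysis is restricted to nuclei (MMR staining is nuclear)
segmented from the hematoxylin channel by Otsu threshold, hole filling
and a 12 px minimum size, with an optional distance-transform watershed
to split touching nuclei; positivity averaging is per-pixel (per-
nucleus averaging of the commercial tool it replaces is unknown). The
proprietary histoscore formula of that tool is likewise undocumented;
the standard weighted-bin histoscore is a stated convention here, not a
claim of equivalence. Rasters are row-major, origin top-left, no
sub-pixel geometry.

## Statistics

- ROC: candidate cutoffs midway between adjacent distinct scores plus
  sentinels outside the range; prediction is score < cutoff
  (lower = pathological). Trapezoid AUC over the resulting (FPR, TPR)
  sweep equals the Mann–Whitney concordance probability with ties
  counted half, which the tests verify against brute-force pair
  counting and scikit-learn.
- Cutoff: maximize Youden's J = sensitivity + specificity − 1 ("best
  sensitivity and specificity" made precise); ties break toward higher
  sensitivity, then the lower cutoff.
- Intervals: exact Clopper–Pearson from beta quantiles, two-sided
  equal-tailed by default, one-sided lower bound available — the
  convention under which the published 100% results' lower limits
  print as 97 and 99 (both conventions round to those integers).
  Recomputing every published interval from its printed x/n counts
  reproduces the printed bounds to one unit in the last decimal; the
  residual unit-level differences (e.g. 84.548 printed as 84.6) are
  two-stage/half-up rounding in the source tables, which also printed
  53/54 = 98.148% as 98.2%.
- Paired ROC comparison: DeLong structural-components test with a
  two-sided normal p-value; identical or rank-equivalent scores return
  z = 0, p = 1. Its variance is checked against a 10,000-rep
  stratified bootstrap (agreement within 20%).
- Per-protein sensitivity is section-level: among ground-truth
  unstained sections of a protein, the fraction scoring below the
  cutoff.

## Problem sizes and runtime

Unit tests run miniature cohorts (tens of cores) and 160–256 px
rasters; the acceptance checks use the full study-shaped cohort (960
generated cores — the tabular path takes well under a second) and ten
512×512 renders for the recovery grid. The whole suite completes in
well under a minute on one CPU.

## Known limitations

- The generator models neither scanner optics, section thickness,
  antibody chemistry, nor patient-level genetics beyond the
  deficient/proficient label; heterogeneity is a single multiplicative
  focal fraction, off by default.
- Triage is per-core; patient-level diagnosis is out of scope (a
  patient is merely *prioritized* when any core is flagged).
- The renderer's nuclei may overlap at default density; segmentation
  counts are only validated on sparse geometries, and the measured-W
  contract is stated against ground-truth stained pixels, not against
  nucleus counts.
- Whole-slide dearraying, stain-vector estimation from data and
  learned segmentation are out of scope.
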