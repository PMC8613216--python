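# Methods

## Scope and model

`hrdcc` implements a high-resolution differential cell count (HRDCC)
pipeline for bovine blood and milk flow cytometry. It has three layers:

1. **A synthetic-cohort generator** producing event-level cytometry data
   with full ground truth (per-event population labels, doublet/dead/debris
   flags, true composition per sample).
2. **An automated hierarchical gating engine** that reproduces the manual
   HRDCC gating scheme with data-driven threshold placement.
3. **Statistics**: concordance between gating runs (linear regression,
   Bland–Altman), within-animal time-course testing (Friedman), and
   multivariate phase discrimination (PCA, Ward clustering, PLS-DA /
   sparse PLS-DA with one-vs-rest AUROC).

The real study this design emulates has no public event data, so every
quantitative claim the package makes is about its own synthetic cohorts;
the simulator is first-class, tested code, not a fixture.

## Synthetic event model

**Intensity model.** Each population is a template assigning every channel
a central linear-scale intensity and a log-normal multiplicative spread
(default sigma 0.35 for fluorescence, 0.13 for scatter). Flow intensities
are right-skewed and strictly positive; a log-normal is the simplest model
with those properties. Marker-positive locations sit 40x above the
negative level (60 vs 2400 a.u.), comfortably above the 10x separation
floor at which the analytic Bayes error of the geometric-midpoint boundary
is far below 0.1% (`norm.sf(0.5*ln(40)/0.35)` ~ 7e-8).

**Scatter geometry.** FSC-A modes of the leukocyte compartments are
deliberately broad and overlapping (70–90k a.u.) so that cellular events
form a single dominant FSC-A mode; the clean three-way compartment
separation lives on SSC-A (lymphocytes 12k, monocytes/macrophages 45k,
granulocytes 150k). This matters for the debris gate: a two-mode valley
search on FSC-A must see "debris vs cells", not two leukocyte sub-modes.
FSC-H is 0.80 x FSC-A with 1% log-normal noise — height tracks area
tightly for single cells.

**Doublets** are synthesized by summing the area-type channels of two
random single cells and taking the per-channel maximum for FSC-H, which is
exactly why an area-vs-height band separates them. **Dead cells** have the
viability-dye channel shifted to >= 50x the live location (>= 10x floor).
**Eosinophils** are bright in a dedicated autofluorescence channel
(AF-525/50) in which every other population is negative. **Debris** sits
at 7k FSC-A, far below cells. **Milk** adds mammary epithelial cells
(MEC): CD45-negative, pan-cytokeratin-positive, 8% of live single cells by
default. **Immature neutrophils** are an overlay: a CD11b-dim
(400 a.u.) share (8% default) of the neutrophil template, not a separate
terminal class. Milk ncMac (CD14+/- CD16+) draws CD14 from a 50/50 bimodal
overlay.

**Spillover.** Each panel carries a banded spillover matrix (default 3%
into the adjacent detector, 1.5% back); events are mixed with it at
generation and the pipeline compensates by inverting it before gating.

**Cohort structure.** Defaults mirror a three-group vaccination study:
3 groups x 5 cows; group A two vaccinations with pre1/post1/pre2/post2
days, group B pre/mid/post, group C (single vaccination) pre/post/late;
six sampling days per group. Acquisition sizes are log-normal with the
study's reported means and CVs (milk 468,843 events, CV 38%; blood
286,369, CV 21%); desk-scale experiments override the count explicitly
(50,000 for the concordance study, 6,000–12,000 for the repeated-seed
experiments) to keep runtimes in minutes. Per-animal baselines are
log-normal offsets (sigma 0.15) drawn once per animal and reused across
days; day-to-day jitter is sigma 0.08. Treatment effects multiply a
population's true proportion in the named (group, phase) cells and the
vector is renormalized; a decay factor < 1 attenuates repeat stimulations
(the second vaccination shifts less than the first).

**What the generator does not emulate:** instrument drift, spectral
overlap beyond a fixed linear matrix, autofluorescence continua,
population shape families beyond log-normal ellipses, doublets of unlike
sizes hiding inside the singlet band, or any real-cow biology. Passing
tests therefore demonstrate that the pipeline recovers a *well-specified*
generative model, not that it would gate any real FCS file correctly.

## Automated gating

**Valley placement.** Thresholds are placed at the minimum of a binned
Gaussian-kernel density estimate (Silverman's rule bandwidth, 512-point
grid) between the two (or three) most prominent modes; mode prominence
must exceed 1% of the density maximum. If fewer modes are found the gate
falls back to a configurable empirical quantile and flags the fallback in
the result's provenance. Positive-marker gates additionally clip the
data-driven threshold to an absolute floor (300 a.u. linear), so a parent
with no positive cells is not sliced by a quantile inside its negative
cloud; the viability and debris gates use floors of 600 and 15,000 a.u.
All fluorescence gates operate on arcsinh-transformed values (cofactor
150, typical for conventional flow); scatter gates on linear values.
Events exactly at a threshold go to the positive/upper side.

**Singlet gate.** Theil–Sen fit of FSC-H on FSC-A (deterministic
evenly-spaced subsample of <= 1000 events keeps the O(n^2) pair cost
flat), keep events within +/- k MADs of the line. The HRDCC trees use
k = 6: population scatter is heteroscedastic (absolute residual spread
grows with FSC-A), and a tighter band clips a percent of the large-scatter
granulocytes while doublets sit ~150 MADs away regardless.

**Three-way SSC split.** Three-mode valley thresholds on linear SSC-A of
the CD45+ events; if three modes are not found, a deterministic 1-D
3-means (quantile initialization, Lloyd iterations) supplies the two
boundaries.

**Tree engine.** Gates are evaluated parent-first; sibling nodes sharing a
gate family (the two sides of a threshold, the four quadrants, the three
SSC parts) share a single threshold computation, so declared partitions
conserve counts exactly. Children of an empty or too-small parent report
0% with a flag rather than raising, keeping cohort tables rectangular.
Every auto-placed threshold is retained in the result's provenance.

**Reference ("truth") placement** fixes every threshold at the geometric
midpoint between the generating template locations — the placement a
perfectly informed gater would use — and serves as the reference arm of
the concordance study and of accuracy tests (the per-event assignment of
live singlet immune events is >= 99.9% correct under it).

**Panel merging.** One HRDCC record per (animal, day, fluid): viability
and granulocyte/monocyte subsets come from the myeloid run; lymphocyte
subsets from the 7-color run are rescaled to the myeloid run's
live-singlet denominator via the shared lymphocyte-compartment percentage,
so a record has a single denominator. Both percent-of-parent and
percent-of-live are emitted, since either convention is defensible.

## Statistics

* **Concordance**: Pearson r with OLS slope/intercept of y on x and the
  two-sided t-test on n-2 df; degenerate (zero-variance) input is an
  error. Bland–Altman bias is first-argument-minus-second with
  1.96-sample-SD limits; the simple (non-repeated-measures) form is used
  deliberately.
* **Friedman**: within-row mid-ranks, tie-corrected statistic against
  chi-square with k-1 df (no exact permutation tables; the approximation
  is flagged when fewer than 5 blocks). Fully tied data yield Q = 0,
  p = 1; missing cells are rejected rather than imputed.
* **PLS-DA / sPLS-DA**: NIPALS extraction on a centered one-hot response
  with X deflation per component (tolerance 1e-9, max 500 iterations),
  built as a scikit-learn estimator. Sparsity soft-thresholds the X-weight
  vector each inner iteration so at most keepX features are non-zero
  (largest |weight| kept, stable ties to the first column); keepX equal to
  the feature count reproduces the dense model to 1e-8. Prediction is
  maximum predicted response ("max.dist"); the paper-equivalent default is
  3 components with keepX = 5. Cross-validation is leave-one-out —
  appropriate at cohorts of a few dozen samples.
* **AUROC** is the Mann–Whitney concordance of the class's predicted
  response, identical to the trapezoidal integral of the empirical ROC
  curve (asserted to 1e-12 in tests).
* Group-A phase fusion (pre1+pre2 -> pre, post1+post2 -> post) is a
  metadata relabeling applied before modeling.
* Significance convention: two-sided, alpha = 0.05.

## Experiment scales and numerical choices

The reproduction script runs the concordance study at 3 groups x 5
animals x 6 days, both fluids and panels, 50,000 events per acquisition
(~3,400 paired percentages; a few minutes on one CPU), and the
discrimination study at 4 animals x 9 days x 12,000 events with 2.5-fold
late-phase shifts in intM, CD8 T cells and eosinophils (the smallest
"strong effect" the design contemplates). The Friedman power experiment
uses 50 replicate cohorts of 4 group-A cows at 6,000 events, effect 2.5
with decay 0.7. Random state derives from a single seed through numpy
`SeedSequence` spawning: identical seeds give byte-identical cohorts.

## Known limitations

* FCS support is deliberately narrow: FCS 3.1 float list-mode is written;
  float/double/integer list-mode of either byte order is read. No FCS 2.0,
  Gating-ML, or biexponential display transforms.
* The CD45/SSC compartmentation is the only monocyte identification step
  (no CD172a refinement); absolute counts per mL are out of scope
  (percentages only).
* The valley gater assumes roughly unimodal-per-population 1-D
  projections; it has no 2-D mixture or curvature gates.
* Lab biomarkers are simulated independently of the event data — no
  mechanistic coupling between, e.g., haptoglobin and neutrophil counts.
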