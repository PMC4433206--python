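# Methods

## The data and the model behind it

DNA image cytometry of Feulgen-stained exfoliated oral mucosa cells yields
one DNA index (DI) per measurable nucleus — the ratio of integrated optical
density to a diploid reference. The working model throughout this package
is a finite Gaussian mixture on the DI axis: a dominant diploid population
near DI 1, a small tetraploid population (cycling cells) near DI 2, and, in
dysplastic or malignant lesions, an aneuploid fraction at DI ≥ 2.3 (the
British Columbia Cancer Agency operational criterion for an aneuploid
cell). Cells are treated as independent draws; instrument effects beyond
the DI value itself (staining chemistry, calibration, the other cytologic
parameters an instrument reports) are out of scope.

## EdTAR

**Peak identification.** Per case, a Gaussian-kernel KDE is evaluated on a
fixed grid of step 0.01 DI over [0, max(8, max DI) + 1] and renormalized to
unit trapezoid integral (the grid truncates the kernel tails). The ideal
bandwidth minimizes MISE, which depends on the unknown density; the
implementable proxy is the Sheather–Jones solve-the-equation plug-in,
implemented with binned pair-sum functional estimates (512 bins, diagonal
terms included — that is what keeps the ψ₆ functional on the correct sign)
and a Brent root find over a bandwidth ladder around Silverman's rule.
When the plug-in equation has no root the selector falls back to
Silverman. One unit test cross-checks the selector against R's `bw.SJ`
(tolerance 20%; the two implementations differ in binning details).
Candidate peaks are local maxima with prominence ≥ 0.5% of the maximum
height (the threshold for "how small a peak still counts" is not dictated
by the method; it is config-exposed). Two refinements make the geometry
robust to KDE noise:

* adjacent modes closer than 3 bandwidths are merged (flat-top samples
  otherwise produce spurious twin modes whose dip would be mistaken for a
  population boundary);
* a peak's flanking bound is the valley minimum toward an adjacent mode,
  or on an outer flank the nearest local minimum below half the peak
  height — shallow tail wiggles are not boundaries.

Overlapping populations that merge into one mode are detected as
shoulders: the first derivative is smoothed with a 5-point moving average,
and extra sign changes of its derivative on one flank (beyond the single
inflection a clean Gaussian flank has) mark a reflection point, added as a
split. Shoulder detection is deliberately conservative; it fires on
clearly merged two-population flanks in most seeds (a property test pins
≥ 6/10) and is used only to offer tetraploid candidates.

**Sequential extraction.** The dominant peak below DI 1.5 is the diploid
population; a case without one is flagged unanalyzable rather than
processed. The nominal diploid window is [0.8, 1.2], but real diploid
peaks drift below 0.8 (staining variation), so the dominant-below-1.5 rule
matches practice and the printed windows only label secondary peaks. The
population's spread is estimated from the left flank only — the right
flank is contaminated by higher-ploidy cells — under a half-normal
assumption: sd = √(mean((x − c)²)) over left_bound ≤ x ≤ c. The right
flank is then removed by mirroring: as many right-side cells as there are
left-side cells, nearest deviations first, capped at c + 4·sd. Cells
beyond the cap, and any excess over the mirrored count, survive as
residual. The mirror center c is the median of the cells inside the
peak's support [left_bound, p + 4·sd] rather than the KDE mode itself:
the mode carries location error of order the bandwidth, which would
unbalance the two flanks by O(n·h) cells, while the support median
balances them exactly for a symmetric population. The reported population
mean remains the peak location. A remaining peak in [1.5, 2.3) is
extracted identically as tetraploid; all residual cells at DI ≥ 2.3 form
the aneuploid population (one pooled summary, even when several high-DI
peaks exist); residual cells below 2.3 are reassigned to the nearest
extracted population by |DI − mean|/sd so that population counts always
sum to the case's cell count. Cases with fewer than 10 cells skip the KDE
entirely and are partitioned by the fixed windows [0, 1.5), [1.5, 2.3),
[2.3, ∞).

**Amplification.** With ratios R₁ (diploid), R₂ (tetraploid), R₃
(aneuploid) constrained to R₁ + R₂ + R₃ = 1:

| observed populations | rule |
| --- | --- |
| all three | R₁:R₂ preserved, R₁ + R₂ = 0.9, R₃ = 0.1 |
| diploid + tetraploid | R₁:R₂ preserved, R₁ + R₂ = 0.995, R₃ = 0.005, hypothetical aneuploid Norm(2.3, 0.3) |
| diploid only | R₁ ~ Unif[0.75, 0.8], R₂ = 0.995 − R₁, R₃ = 0.005, hypothetical tetraploid Norm(2.0, 0.3) and aneuploid Norm(2.3, 0.3) |
| diploid + aneuploid (no tetraploid peak) | not covered by the three stated rules; this package amplifies (R₃ = 0.1), draws R₁ ~ Unif[0.75, 0.8] as in the diploid-only rule, and fills R₂ with the hypothetical tetraploid |

Hypothetical components enter analytically (their Gaussian shape is
integrated directly); the only sampled quantity is the scalar R₁ draw,
whose seed is recorded. This removes pointless Monte-Carlo noise from the
features while honouring the sampled-ratio rule.

**Reconstruction.** Bin values are probability masses of the weighted
three-Gaussian mixture over the 16 half-open intervals [0, 0.5) …
[7.5, 8.0] (final bin closed). Masses, not point densities, make rows
comparable across cases and sum to ~1. Mass below DI 0 (negligible) folds
into the first bin; mass beyond the DI clamp at 8 folds into the last.
Any bin below 0.0001 is set to that filler.

## Risk model

Training uses normal and OSCC cases only (OLK is score-only: its risk is
the quantity being estimated). Preprocessing is per-bin median centering
and scaling by the training-column standard deviation (floor 1e-8),
frozen and applied unchanged at test time. The radial-kernel SVM's cost is
selected by leave-one-out cross-validated accuracy over the nine-value
geometric grid 2⁻², 2⁻¹, …, 2⁶, ties broken toward the smaller cost
(accuracy, not ROC, is the tuning criterion; the choice is config-exposed).
The kernel width σ (in exp(−σ‖x−y‖²)) comes from the
median-pairwise-squared-distance heuristic on the preprocessed training
data and is stored on the model; it is dataset-specific, so no particular
printed value is a target. Probabilities are Platt-type sigmoid
calibrations fitted on internal training folds
(`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`). OCRI is
the calibrated P(OSCC); OSCC is the positive class everywhere, and 0.5 is
the nominal decision cutoff.

The six-family benchmark (SVM, random forest, L2 logistic regression,
one-hidden-layer MLP, KNN, CART) runs under a single
`RepeatedStratifiedKFold(10, 5)` — identical folds for every model, 50
resamples — with preprocessing refitted inside each training fold. Each
family starts from library defaults with a light internal 3-fold grid
(SVM cost, logistic C, KNN k, CART pruning α); the forest and MLP run
fixed small configurations. Models are ranked by median ROC AUC, then
sensitivity, then specificity.

## The synthetic generator

`synthetic.py` draws per-case DI values from explicit Gaussian mixtures
with per-cell ground-truth component labels, rejecting non-positive draws
(DI is a positive ratio; at the parameters used, P(X ≤ 0) is negligible,
so rejection introduces no measurable truncation bias). The reference
mixture is diploid μ=1.001 σ=0.19, tetraploid μ=2.002 σ=0.25, aneuploid
μ=2.300 σ=0.5 at ratio 0.893:0.092:0.005 (normalized — the stated ratio
sums to 0.990). Case profiles:

* **normal** — diploid 99.6%, tight tetraploid Norm(2.0, 0.12) at 0.4%, no
  aneuploid component by default. The tetraploid is deliberately tighter
  than the reference mixture's σ=0.25, which describes an OSCC-adjacent
  sample: a broad tetraploid would put ~12% of its mass at DI ≥ 2.3 and
  make simulated healthy samples read "aneuploid", contradicting the
  uniformly negative conventional cytology of healthy cohorts.
* **olk** — dominant diploid plus satellite components at DI 1.25, 1.75,
  2.22 and 2.74 (a typical multi-peak premalignant pattern); the
  satellite weights are this package's choice — only the locations are
  given by the pattern being emulated.
* **oscc** — diploid (78%), tetraploid Norm(1.79, 0.25) (15%), and three
  aneuploid components near DI 3.25/3.57/3.99 (7% total).

Per-case cell counts are uniform on a configurable range, default
1000–4000 (the scale of a routine brush biopsy; only one real example
count, 3,590 cells, anchors this guess). Per-case seeds derive
deterministically from (cohort seed, case index) via `SeedSequence`, so
any single case is reproducible without regenerating the cohort.

What the generator does **not** emulate: measurement error structure
(debris, cut nuclei, stain variability produce heavy non-Gaussian tails
and the sub-diploid artifact peaks real samples show), correlation between
cells of one lesion, cohort heterogeneity within a diagnosis, or any of
the 130-odd non-DI cytologic parameters. Passing tests therefore show the
pipeline is a faithful, stable implementation of the stated procedure on
data satisfying its own model — not that the reported clinical accuracy
transfers to real cohorts. In particular the synthetic two-class cohort is
far cleaner than a clinical one, which is why near-perfect resampled
sensitivity/specificity is the expected outcome there.

## Numerical choices and degenerate inputs

* KDE grid step 0.01 DI (well below the 0.5 bin width); unit-integral
  check at 1e-3.
* Bandwidth floor 1e-3 DI for (near-)zero-variance input, applied with a
  warning, not an error; all-equal samples peak exactly at their value.
* Fewer than 10 cells: KDE refused (`SmallSampleError`); decomposition
  takes the fixed-window path.
* Extraction span 4·sd; population sd floor 1e-3 when a degenerate
  population must still provide a Gaussian shape for reconstruction.
* Weight identity R₁+R₂+R₃ = 1 enforced to 1e-9 at construction.
* Duplicating every cell leaves ratios exactly unchanged at a fixed
  bandwidth (the extraction geometry is scale-invariant); with the
  data-driven selector the bandwidth itself changes with n, moving peak
  bounds by O(1e-3) DI, so exact invariance is tested at fixed h.
* All randomness flows from explicit integer seeds; derived seeds stay
  below 2³¹.

## Problem sizes in tests and the acceptance script

Parameter-recovery runs use 4,000 cells × 20 seeds (recovered diploid mean
within ±0.05 of 1.001, tetraploid within ±0.08 of 2.002). The resampling
surrogate uses 100 normal + 90 OSCC simulated cases, EdTAR-transformed,
with the SVM evaluated over 50 resamples; unit tests use smaller cohorts
(tens of cases, 600–1500 cells) chosen to exercise every code path while
keeping the default suite fast.

## Known limitations

* The aneuploid population of the reference mixture (0.5% of cells at
  Norm(2.3, 0.5)) overlaps the tetraploid population heavily; after
  mirror extraction it is genuinely at the detection floor, so individual
  draws may yield no aneuploid residual. This is a property of the
  geometric method, not a defect of the implementation.
* Mirror extraction attributes to a population any higher-ploidy cells
  that fall inside its 4·sd reach; ratio-recovery guarantees hold for
  component separations ≥ 4 sd.
* The qualitative-call thresholds (DI ≥ 2.3, counts 0 / 1–5 / >5) and the
  amplification constants are fixed clinical/method constants, not tuned
  quantities; overriding them via config is possible but logged as a
  deviation.
* OCRI is a relative index calibrated on the training cohort; absolute
  probabilities depend on cohort composition and the 0.5 cutoff is
  nominal.
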