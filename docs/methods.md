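# Methods

This note records the modelling and numerical choices behind the package:
what each stage assumes, which knobs matter, and what the synthetic data
do and do not establish about real recordings.

## The pRRx family and threshold quantization

pRRx is the percentage of *valid* adjacent RR-interval pairs whose
absolute difference is at least x ms. Two conventions are fixed here:

- **Inclusive comparison.** "At least x" means ≥, so a difference exactly
  equal to the threshold counts. Since annotation-derived differences are
  integer multiples of the sampling period Δ = 1000/fs ms, the comparison
  is done in sample units (|ΔRR|/Δ ≥ k, with a 10⁻⁹ guard so an exact
  k-sample difference can never be lost to float rounding). For data not
  aligned to the sample grid — e.g. an RR table exported at 1 ms
  resolution — this reduces to the literal millisecond comparison.
- **Valid pairs only.** The denominator counts adjacent pairs not broken
  by a removal (`gap_after`), never n−1. A difference computed across a
  removed beat is not a physiological successive difference, and would
  otherwise fabricate spuriously large values in exactly the segments the
  filters edited most.

The grid x_k = k·Δ, k = 1…k_max (25 at 128 Hz → 7.8125…195.3125 ms)
enumerates every distinguishable threshold. Two distinct mappings from an
arbitrary x to the grid exist and serve different purposes:

- `equivalent_x` = ⌈x/Δ⌉·Δ — the grid member that classifies *identically*
  to x (all measurable differences in (kΔ−Δ, kΔ] behave like kΔ). This is
  why pRR54, not pRR46, is the pRR50 equivalent at 128 Hz, and it is the
  default partner in the pRR31 comparison.
- `nearest_x` — the numerically closest grid member (exact midpoints
  resolve toward the smaller x). Used when transporting a *cutoff* learned
  on one sampling rate to another grid, where no identically-classifying
  threshold exists in general.

## Segmentation and filtering

Windows are cut on cumulative RR time within each rhythm-pure fragment,
not wall-clock record time, so gaps between fragments never leak into
windows. An interval belongs to the window containing its terminating
beat; an interval ending exactly on a boundary closes the earlier window;
a trailing remainder shorter than the window is dropped.

Filter rules: remove intervals outside 240–3000 ms, artifact intervals,
ventricular-premature intervals under both labels, supraventricular-
premature intervals under SR only. The 6-s exclusion budget is strict
(6000 ms of removals passes, anything more rejects) and counts *all*
removals, including the out-of-range ones. Both choices where the
convention was open — interval attribution to the terminating beat, and
the budgeted-filter reading rather than rejecting any segment containing
an ectopic beat — are the defaults; the conservative all-or-nothing
reading is available as `strict_purity`.

## Diagnostic evaluation

AF is the positive class and the decision rule is pRRx ≥ cutoff ⇒ AF.
Youden's J is maximized over the observed score values with *exact
integer arithmetic* (J·n_AF·n_SR is an integer), so exactly tied
candidates cannot be misordered by floating-point noise; ties resolve to
the largest (most specific) cutoff. AUC is the rank statistic
(U/(n_AF·n_SR), ties counting ½), computed via scikit-learn and
cross-checked against an independent Mann–Whitney oracle in the tests.

Bootstrap CIs are percentile intervals (2.5th/97.5th at the default 95%
level) over resamples of whole segments, unstratified by default because
no stratification is part of the plain nonparametric bootstrap; a
replicate that loses a class entirely is redrawn (logged), and a
stratified mode exists for small or very unbalanced tables. 5000
resamples is the default; per-threshold streams are spawned from one seed
so sweep results do not depend on evaluation order and a sub-grid
reproduces the corresponding prefix of the full sweep bit for bit.

DOR uses the Haldane–Anscombe correction (add 0.5 to every cell) only
when some cell is zero, keeping the estimate finite in degenerate
replicates without biasing the regular case. PPV/NPV are undefined (NaN)
when nothing is predicted in the corresponding class; bootstrap summaries
are NaN-aware.

The two-threshold comparison shares one set of resample indices between
both thresholds (a paired design), then tests each metric's paired
difference: Shapiro–Wilk on both replicate distributions, paired t-test
if both look normal (p > 0.05), Wilcoxon signed-rank otherwise, all
two-sided. Shapiro–Wilk anywhere in the package runs on at most 5000
values (a seeded subsample above that), because its p-values are not
reliable for larger n.

## Descriptive statistics

Percentiles use linear interpolation between order statistics (the
common "type 7" rule). Limits of agreement are purely nonparametric —
the 2.5th and 97.5th percentiles of the pairwise differences — because
pRRx distributions are far from normal. Histograms use 25 equal bins over
0–100% (presentation only). The hundreds of pairwise tests are reported
raw, without multiplicity correction; consumers who need familywise
control should apply it downstream.

## The synthetic generator

`generate_series` emulates the statistical structure the analysis relies
on, not electrophysiology:

| parameter | SR default | AF default | meaning |
|---|---|---|---|
| `mean_rr` | 900 ms | 650 ms | mean interval (resting SR vs faster AF) |
| `sd_rr` | 50 ms | 150 ms | interval SD (initial draw for SR; gamma SD for AF) |
| `sd_diff` | 25 ms | — | SR successive-difference scale (RMSSD-like) |
| `ratio_bounds` | 0.8–1.2 | — | SR coupling band for successive intervals |
| `p_ventricular` etc. | 0 | 0 | per-beat disturbance probabilities |

SR is a Gaussian random walk with reflection at the ratio bounds and an
absolute 300–2000 ms clamp at every step — without the clamp the
multiplicative band lets the walk drift toward zero and the duration
target becomes unreachable. AF draws i.i.d. gamma intervals with the
configured mean and SD (right-skewed, strictly positive, successive
differences ~√2·sd_rr and nearly uncorrelated). Ectopic beats are a
shortened interval followed by a compensatory lengthened one (the pair
conserving time); artifacts are implausibly short detections. All
durations are rounded to the sample grid, and generation targets the
*quantized* cumulative sum so rounding can never force an out-of-model
top-up beat.

`generate_cohort` adds log-normal between-series dispersion around the
class defaults (σ of 0.12/0.3/0.5 on SR mean/sd/sd_diff; 0.15/0.5 on AF
mean/sd), reflecting population spread of resting rate, of short-term
sinus variability (adult RMSSD spans roughly 10–60 ms) and of AF
rate-control state. This heterogeneity is essential for realism: a cohort
in which every SR series shares one parameter set is perfectly separable
from AF at almost every threshold (SR successive differences are
ratio-bounded below ~180 ms while homogeneous-default AF segments always
have pRR195 ≫ 0), which no real cohort is. With dispersion, the
AUC-vs-threshold curve shows the expected shape — lower at the smallest
threshold, an interior maximum, decay toward the largest.

What the synthetic cohort does **not** emulate: respiratory and circadian
modulation of SR, rhythm transitions within a series, atrial-flutter-like
organized irregularity, and record-level annotation errors. Passing tests
therefore establish correctness of the *computations* and qualitative
behaviour of the *method*, not clinical performance figures; point values
such as optimal cutoffs or DORs on real Holter databases must be obtained
by running the pipeline on those recordings.

## Problem sizes

The test suite and the summary script use scaled-down designs chosen as
sensible defaults for a reproducible desk run: 10 000 random segments for
the monotonicity property, 500 instances per oracle-equivalence check,
200 outer replicates × 1000 bootstrap resamples for CI coverage, a
1000+1000-segment cohort for the AUC-shape check, and a 600+600 cohort
with 1000 bootstrap resamples in `scripts/acceptance.py`. Production runs
on real databases should keep the 5000-resample default.

## Known limitations

- The WFDB reader requires the optional `wfdb` package and a local copy
  of the records; only the annotation-array adapter is exercised by the
  tests.
- Multi-rhythm series are handled by fragment extraction, but a segment
  never spans a rhythm transition; borderline rhythms other than SR/AF
  are ignored wholesale.
- The bootstrap treats segments as exchangeable; it ignores within-record
  correlation (segments from one patient are resampled independently), as
  does the plain nonparametric bootstrap it implements.
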