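# Methods

## Signal model and quantification

A PamChip array reports, for each substrate peptide, a fluorescence
intensity at each pumping cycle (default times 0, 5, …, 60 min) and camera
exposure (default 10, 20, 50, 100 ms).  We model the expected intensity as

    I(t, e) = r · t · e/100

where `r` is the peptide's phosphorylation rate in intensity units per
minute at the 100 ms reference exposure.  Quantification is two-stage, the
standard convention for multi-exposure PamChip data: per cycle, OLS of
intensity on exposure (slope × 100 is the cycle signal, which removes
exposure dependence and recovers bright spots whose long exposures clip);
then OLS of the cycle signal on time, whose slope is the peptide's
phosphorylation intensity and whose R² measures kinetic linearity.  Both
fits carry a free intercept (instrument offsets exist); only the slope is
the signal.  A config switch (`two_stage=False`) uses the final cycle's
exposure regression alone for sensitivity analysis.

Numerical choices: readings at or above the detector ceiling are dropped
from the exposure fit (keeping them flattens slopes); cycles left with
fewer than two usable exposures contribute no signal, and a peptide with
fewer than three usable cycles is flagged `excluded_saturated`.  Negative
slopes are retained through quantification and floored only at fold-change
time.  R² is undefined (NaN) for zero-variance signals; such peptides are
undetectable.  The kinetic window defaults to the full record and is
configurable, since instrument cycle counts vary between PTK and STK runs.

QC thresholds: R² strictly below 0.80 excludes a peptide as nonlinear —
R² exactly 0.80 is included, matching the strict-inequality exclusion rule.
`detect_min` (default 2.0 intensity units) sets the undetectable floor on
the peptide's maximum raw intensity.

## Fold changes

Per chip, FC = max(case slope, floor)/max(control slope, floor) with floor
1.0 signal unit; per-chip FCs are then arithmetically averaged ("mean of
ratios").  Ratio-of-means and geometric averaging exist behind flags for
sensitivity analysis.  Differential calls are boundary-inclusive:
FC ≥ 1.30 or FC ≤ 0.70 (a ±30% change).  FC is scale invariant (both
groups multiplied by c > 0 leave it unchanged, floors aside), and swapping
case and control reciprocates per-chip FCs.

## Upstream kinase inference

The kinase–substrate map assigns each (kinase, peptide) pair a confidence
rank 0 (experimental evidence) through 12 (purely predicted).  Scoring
restricts the map to the peptides with defined fold changes, keeps entries
with rank ≤ 4 by default (experimentally supported mappings dominate; the
cutoff is configurable since no canonical value exists), and drops kinases
left with fewer than 3 substrates.

The null distribution of per-kinase hits is built by drawing, 2,000 times,
a differential-set-sized peptide subset uniformly without replacement from
the chip universe.  Draws are uniform and ignore ranks (a rank-weighted
variant exists behind a flag, off by default).  Because the draws are
uniform without replacement, the null hit count for a kinase with `m`
mapped substrates in a universe of `P` with `D` differential is exactly
hypergeometric (mean `D·m/P`); tests verify the sampled moments against
that closed form, and against full enumeration of all C(P, D) draws for
universes of at most ~16 peptides.

Derived statistics per kinase:

* `z = (observed − null mean)/null SD`, NaN-flagged when the null SD is 0;
* `Δ-confidence = observed/null mean`, NaN-flagged when the null mean is 0
  and marked `low_coverage` when the null mean is below 0.25 (the ratio is
  unbounded for tiny expected counts);
* `kinase_statistic` = median log2FC over **all** rank-filtered mapped
  substrates (not only differential ones) — the signed activity readout;
* `MEOW` = mean log2FC over the kinase's **differential** substrates ×
  Δ-confidence.  The scalar uses the mean over differential substrates;
  per-substrate terms (log2FC × Δ-confidence) are retained as the points
  of a MEOW plot, whose summary line is their mean.  MEOW's sign always
  equals the sign of the mean differential-substrate log2FC, since
  Δ-confidence is nonnegative.

The commercial instrument software's specificity/significance scoring is
proprietary; this package defines a transparent surrogate with the same
"final score = significance" semantics: the specificity score is −log10 of
the empirical one-sided tail probability of the observed hits under the
sampled null, the significance score is −log10 of a sign-permutation
p-value of the substrate log2FC median (2,000 sign flips), both with a
+1/(N+1) continuity correction (capping either score at log10(N+1) ≈ 3.30
at N = 2,000), and the final score is their mean.  This is the package's
largest interpretive decision and is documented as an approximation, not a
reimplementation.

All resampling derives from one seed with a fixed draw order (null
sampling first, then per-kinase sign permutations in sorted kinase order),
so stage-level reruns match pipeline-level runs.

## Synthetic data generator

The generator emulates the stated acquisition structure — readings every
5 min over 60 min at 10/20/50/100 ms exposures, technical-triplicate
chips, two groups — with planted per-kinase activity multipliers
(treatment/control rate ratio).  What it models, and what it deliberately
does not:

* **Kinetics** are linear (rate × time) by default, so slope-based
  quantification recovers planted rates exactly; an exponential-approach
  mode `V(1 − e^(−kt))` with matched initial slope stress-tests the R²
  filter.  Real arrays show washing artifacts, spot morphology effects and
  occasional non-monotone kinetics that are not simulated.
* **Effect propagation**: a peptide mapped by kinases `k` with multipliers
  `m_k` and ranks `r_k` gets the treatment/control rate ratio
  `∏ m_k^w(r_k)` with `w(rank) = 1 − rank/13`.  The exponent-weighted
  product keeps rates positive, is symmetric in kinases, reduces to `m^w`
  for a single mapping kinase (exactly `m` at rank 0), and gives rank-12
  mappings minimal influence.  A normalized geometric mean was considered
  and rejected: it divides each kinase's log-effect by the number of
  co-mapping kinases, so at realistic map density (~4 kinases per peptide)
  a genuine 2× activity change would be diluted below the 30% fold-change
  threshold on almost every substrate — a generator that structurally
  hides its own planted signal cannot validate the inference.
* **Noise** is multiplicative lognormal per reading, mean 1, with CV
  `noise_cv` (default 0.1, a typical across-chip technical CV); readings
  clip at a 65535-unit ceiling (16-bit CCD convention).  Noise is i.i.d.
  across readings: no spatial correlation, batch effects, or biological
  covariance between kinases.  The study design this emulates pools
  samples within treatment groups, so replication is technical, not
  biological — recovery results say nothing about biological variance.
* **Maps**: each of `n_kinases` draws a substrate count uniformly from
  (5, 20) — typical coverage for curated PamChip mapping files — without
  replacement from the peptide universe; ranks follow a geometric
  distribution ∝ 0.7^rank, mirroring the dominance of experimentally
  supported entries in curated files.  Baseline rates are log-uniform in
  [5, 200] units/min, spanning dim-but-detectable to bright-but-unsaturated
  spots.
* **Seeding**: one RNG stream per (chip, group) split from the master
  seed, so adding chips never perturbs earlier chips' draws.

Recovery experiments (`planted_experiment`) plant multipliers on kinases
that retain at least 5 substrates after the default rank ≤ 4 filter.  This
is an a-priori power consideration: a kinase with no high-confidence mapped
substrates on the chip is undetectable by any mapping-based method, so
planting on it would measure map coverage rather than inference quality.

## Group statistics

Welch's unequal-variance t-test is computed directly from printed
mean ± SD/n summaries, with the Welch–Satterthwaite degrees of freedom and
a two-sided p from the t distribution; a pooled-variance variant is
available behind a flag.  Welch is the default because it reproduces the
published weight-table p-values from their printed summaries (pancreas
0.0055 and BAT/BW 0.0006 exactly at printed precision; blood glucose to
within one unit of the last printed decimal, the residual reflecting that
the published value was computed from unrounded raw data).  Coarsely
rounded rows (e.g. spleen, 0.06 ± 0.01) cannot reproduce their printed
p-values from summaries alone; this is a rounding limitation of the
printed table, not of the test.  Ratio variables (organ/body-weight) are
treated as their own summarized variables, since per-animal ratios are not
reconstructible from group summaries.

## Atlas outputs

Waterfall tables normalize kinase statistics by the maximum absolute value
(idempotent, order preserving; ties break lexicographically).  Volcano
classification requires **both** cutoffs: |mean substrate log2FC| ≥
log2(1.30) and final score ≥ 1.3 (the score cutoff follows common
upstream-kinase-analysis practice and is config-exposed, since no printed
value exists).  Tree-node exports carry both the mean and the median final
score as size fields — conventions differ between descriptions of such
trees — plus the median kinase statistic as color; only scored kinases
appear, kinases missing from the family file fall back to family "other",
and value ranges are reported per run because display ranges are set per
tissue.  Top-kinase selection takes the 6 largest |MEOW| per assay class
among kinases passing both volcano cutoffs, flagging short selections.
Depot summaries use a ±0.1 dead band on the median kinase statistic to
separate hyperactive/hypoactive from genuinely mixed profiles (brown fat
shows diverse per-kinase changes that cancel in the median).

## Problem sizes in tests and the acceptance script

Recovery checks use the full stated conditions — 5 kinases planted at 2.0
among 50, 144 peptides, noise CV 0.1, triplicate chips, 2,000-iteration
nulls — for 50 seeded replicates; type-I checks use 10 all-null replicates
at the same size.  These sizes were chosen as the smallest at which the
hypergeometric standard-error bounds and the ≥90% recovery criterion are
statistically meaningful; a full run completes in well under a minute.

## Known limitations

* The specificity/significance/final scores are a transparent surrogate
  for proprietary vendor scoring; absolute values are not comparable to
  vendor reports, though rankings behave equivalently on synthetic data.
* The null draws are differential-set-size-matched but not
  signal-stratified; bright peptides are not over-represented in draws.
* Technical-replicate FCs from pooled samples are not independent across
  peptides mapped to the same kinase, so z-scores are enrichment
  statistics, not calibrated p-values.
* No spatial/spot-level QC, no between-batch normalization, no image
  processing: the pipeline starts at per-peptide intensity tables.
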