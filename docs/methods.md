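# Methods

## Scope and data model

The package re-implements, as a tested pipeline, an integrative analysis
of placental-bed expression in pregnancy complications. The measured
layers are (i) qPCR Ct tables for a miRNA panel and an mRNA panel,
(ii) a small-RNA read-count matrix, and (iii) a label-free protein
intensity matrix, joined by a miRNA→gene target map produced externally
by a sequence-based predictor and consumed here as an input file. The
original study's per-sample measurements were never deposited — only
group sizes, clinical outcome counts, group medians of ΔCt, and the log2
fold changes of 16 discriminating miRNA/protein rows are public (embedded
in `mirpair.reference`). All quantitative validation therefore runs on
synthetic cohorts with known planted effects.

## Relative quantification

ΔCt(target, sample) = Ct(target) − reference level, where the reference
level is the arithmetic mean of the layer's reference-assay Cts in the
same sample (one miRNA reference, SNORD68; two mRNA references, GAPDH and
ACTB). Averaging Cts corresponds to a geometric mean on the expression
scale, the standard way to combine multiple reference genes. ΔΔCt
subtracts the control group's *median* ΔCt per assay (robust at the n = 7
control size; mean vs median anchoring was an open choice). Amplification
efficiency is fixed at 2 — plain ΔΔCt without efficiency correction.
Undetermined Cts stay missing and propagate as absent cells; imputing
them to a maximum cycle would fabricate fold changes.

The discriminating statistic is the per-sample pair ratio
r = ΔCt(mRNA) − ΔCt(miRNA), algebraically equal to log2(2^(−ΔΔCt)) with
ΔΔCt = ΔCt(miRNA) − ΔCt(mRNA). It is shift-invariant (per-sample loading
offsets cancel) and antisymmetric under swapping the pair's roles; both
identities are enforced by tests at 1e-12.

## Differential expression

The count stage is a deliberately simple desk-scale procedure, not a
re-implementation of an NB-GLM framework: median-of-ratios size factors
(per sample, the median over positive-geomean features of
count/geometric mean), log2(normalized + 0.5), Welch's unequal-variance
t per feature, Benjamini–Hochberg adjustment. The 0.5 pseudocount avoids
log 0 without strongly biasing small counts. The protein stage applies
Welch + BH to log2 intensities after dropping features observed in fewer
than `min_present = 2` samples of either group (every drop is logged).
Significance defaults: adjusted p < 0.05 for counts, nominal p < 0.01
for proteins — both configurable, because the emulated analysis's own
inclusion rule is demonstrably looser than any single stated cutoff.
A consequence of Welch at n = 3 per arm is a hard power floor: the
Welch–Satterthwaite df is ~2–4, so nominal p rarely falls below ~1e-3
and BH families much larger than a validation panel (~20–50 features)
cannot yield adjusted significance regardless of effect size. Pipelines
at sequencing scale should expect this stage to be conservative relative
to dispersion-pooling NB models.

## Pairing

A mapped (miRNA, gene) row is retained "study-style" when both members
are differentially expressed and sign(log2FC_miRNA) × sign(log2FC_protein)
< 0; an exact zero has no direction and is excluded. Thresholds are
parameters, and both nominal-p and adjusted-p filtering are supported per
side; the pipeline exposes `mirna_adjusted`/`protein_adjusted` because
the published pair table's miRNA p-values are nominal. One miRNA may
pair with many genes and vice versa. Map rows whose members are absent
from the DE lists are counted in a coverage log, never silently dropped.

## Group statistics

Non-normal variables (Shapiro–Wilk gate at 0.05; constant input yields a
degenerate non-normal verdict) are summarized as Me (Q1; Q3) with
linear-interpolation quartiles and compared with the two-sided
Mann–Whitney U test: exact (full-enumeration null) when the smaller
sample has ≤ 8 values and there are no ties — which covers all group
sizes of the emulated cohort — otherwise the normal approximation with
tie and continuity correction. Spearman correlations carry Fisher-z 95%
intervals tanh(atanh ρ ± z·(n−3)^(−1/2)); |ρ| = 1 gives a degenerate
flagged interval. Chi-square is Pearson's without Yates correction by
default. p-values below 0.001 display as "<0.001". The correlation
matrix marks significance at raw p < 0.05 by default (the display
convention emulated), with an optional BH mode.

## PLS-DA and VIP

X is the samples × pairs ratio matrix, mean-imputed per feature for
absent cells (count logged), autoscaled; y is the −1/+1 class code,
centered. NIPALS with y-deflation extracts A = 2 components (the number
plotted in this kind of analysis; configurable); with a single response
the weight vector is the normalized covariance direction Xᵀy, so the fit
is deterministic. VIP uses the standard Wold form with per-component
class-variance weights SSY_a = q_a² t_aᵀt_a, giving Σ_j VIP_j² = p
exactly; VIP > 1 is the conventional importance cutoff. No
cross-validated classification error is computed by default — the model
is used descriptively. Scores and weights are verified against an
independent reference PLS implementation to 1e-6 up to per-component
sign, and score orthogonality is enforced at 1e-8.

## Synthetic cohorts

The generator emulates the measured layers at the study's group sizes
(10, 13, 12, 7, 8, 7, plus an optional n = 3 early-control group used as
the sequencing/proteomics control):

* **Ct layers**: target Ct = reference level + baseline ΔCt + group
  effect + per-sample loading offset + N(0, 0.5²) cycles; reference
  assays are group-independent with SD 0.25 (abundant, stable
  transcripts); the loading offset (SD 1.0) is shared by all assays of a
  layer and cancels exactly in ΔCt. Baselines and default group shifts
  are the published control medians and group-median differences.
* **Counts**: negative binomial, dispersion 0.1, per-sample library-size
  factors log-uniform on [0.5, 2]× so median-of-ratios can recover them;
  background features draw log2 means from U(5, 14) (the detected range
  of a ~1M-read small-RNA library). Planted effects are log2 fold
  changes; defaults are the 16 published miRNA log2FCs.
* **Proteins**: log-normal with SD 0.5 in log2 and
  missing-completely-at-random cells at rate 0.1; background log2
  intensities U(20, 30) (label-free quantification scale). Default
  planted effects are the published protein log2FCs.

Every planted effect is echoed in a truth table so tests never
reverse-engineer effects. Identical design + effects + seed give
byte-identical outputs.

What the generator does **not** emulate: clinical covariates,
batch/plate structure, count–protein correlation beyond the planted
effects, not-at-random proteomic missingness, amplification-efficiency
variation, and technical-replicate structure. Passing recovery and
calibration tests therefore demonstrate correctness and statistical
sanity of the pipeline under idealized noise, not performance on real
placental-bed data.

## Calibration and recovery checks

`mirpair.calibration` measures, at the study's own sample sizes and with
all randomness derived from one seed via spawned child seeds:

* null rejection rates of the Mann–Whitney stage (ΔCt layer, 12 assays ×
  200 replicate cohorts) and the count DE stage (100 features × 200
  cohorts, raw p at 0.05) — both should sit near the nominal level;
* sign recovery of a planted 2-SD ΔCt shift (1.0 cycle at noise SD 0.5)
  via the ΔΔCt estimator, and of a planted protein log2FC of published
  magnitude (−2.15, SD 0.3, n = 3 vs 3);
* recovery of a single discriminative pair among 10 at n = 10 + 7: the
  planted miRNA is shifted by two pair-ratio noise SDs
  (SD² = 2·0.5² + 0.25² + 0.25²/2 ≈ 0.77²) and the full chain
  (generator → ΔCt → pair ratios → PLS-DA → VIP) must rank it first with
  VIP > 1. Note this condition is intrinsically borderline: autoscaling
  shrinks a 2-SD mean separation to ~1.4 SD of total column spread, which
  leaves a ~5% chance that one of the nine null pairs out-ranks the
  planted one at n = 17; the long-run rate of the joint rank-1 ∧ VIP > 1
  event is ~0.95.

Monte-Carlo problem sizes (200 replicate cohorts for calibration and
sign recovery, 100 for the VIP check) were chosen to keep the full
validation suite under a minute while bounding the binomial standard
error of each rate near 1.5 percentage points.

## Numerical and design choices

* Quartiles: linear interpolation (the common default convention).
* Exact Mann–Whitney threshold min(n) ≤ 8: covers the cohort's group
  sizes at trivial cost; ties always take the corrected approximation.
* "Nonparametric Welch's t-test" in the emulated methods text is
  contradictory; the standard Welch test is implemented, with the
  rank-based Mann–Whitney available throughout as the nonparametric path.
* Direction of an exact-zero log2FC: undefined, pair excluded.
* TSV everywhere, `NA` for missing, full-precision writes (round trips
  lossless to 1e-12); group labels are filesystem-safe tokens
  (`IUGR_lt_34` for "IUGR < 34").
* Degenerate inputs fail loudly with typed errors naming the offending
  sample/assay/file; no silent drops (every exclusion reaches a drop log).

## Known limitations

The count DE stage trades power for simplicity (see above); published
per-sample quantities such as pair-ratio group medians and printed VIP
values depend on raw data that were never deposited and are consequently
out of reach of exact reproduction — the pipeline reproduces the
*procedure* and validates it on ground-truthed synthetic cohorts instead.
Enrichment and network analysis of the paired genes relies on external
web services and is out of scope.
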