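# Methods

## Risk score and status

The TP53-signature risk score of a sample is the ratio of the summed counts
of the 22 up-regulated signature genes to the summed counts of the 9
down-regulated genes.  No normalisation is applied before scoring: the score
is a within-sample ratio and therefore invariant to any per-sample scale
factor (library size, input RNA amount), which is what makes raw nCounter
and RNA-seq counts directly comparable as score inputs.  An optional
control-gene geometric-mean scaling is provided for cross-sample expression
displays only; it provably leaves scores unchanged.  A sample whose
down-gene counts sum to zero has no defined score and is rejected rather
than imputed, and a missing signature gene is a hard error rather than a
silent renormalisation — both choices avoid unnoticed score drift.

The gene identities themselves are configuration, not code: the package
validates a 22/9(/controls) panel from a YAML mapping and allows other sizes
only behind an explicit flag used by the synthetic panels.

## Cutoff calibration

Calibration against binary TP53 structural-mutation labels evaluates the
decision rule *score > cutoff ⇒ MT* at every threshold interval between
adjacent distinct observed scores (midpoint representatives, plus finite
sentinels beyond the extremes), and selects the accuracy-maximising
interval's midpoint.  Conventions the calibration fixes:

* **Cutoff placement** — the midpoint of the optimal open interval, for
  reproducibility; any point of the interval gives the same confusion table.
* **Ties in accuracy** — broken by higher sensitivity, then lower cutoff.
  Both favour calling mutants, matching the screening intent of the assay.
* **Boundary scores** — a score exactly equal to the cutoff is WT (the MT
  rule is strict inequality).
* **Reported rates** — rounded half-away-from-zero to two decimals, the
  convention of printed clinical operating characteristics.

The ROC curve uses the same thresholds; the trapezoidal AUC is checked (by
construction and by test) to equal the rank statistic: concordant
mutant/wild-type score pairs plus half the ties, over all pairs.

The 30-sample canonical learning fixture (16 wild-type, 14 mutant scores) is
frozen under a checksum.  Its values are artifact-defined — the study
cohorts behind the assay are not public — and were constructed so that the
calibration pipeline exercises a realistic operating point: a unique optimal
interval (0.75, 0.79), confusion TP 13 / FN 1 / FP 2 / TN 14, AUC 202/224.

## Survival analysis

Relapse-free survival is the time from operation to recurrence; samples
without recurrence are censored at last follow-up.  Kaplan–Meier curves and
the two-group log-rank test come from lifelines, as do Cox
proportional-hazards fits (Efron handling of tied event times — the less
biased default; Wald 95% intervals).  Multivariate models enter the
covariates with univariate p < 0.05 unless an explicit variable list is
given; collinear or separating designs are reported as errors, not silently
fitted.

Harrell's concordance index is implemented in-package: a pair is usable when
the sample with the shorter observed time had an event (tied times are
unusable), concordant when that sample carries the higher risk, with risk
ties counted one half.  Tests verify it against a plain O(n²) enumeration
and against lifelines' independent implementation.  `compare_signatures`
evaluates several named risk columns on the identical sample set so that
c-indices are directly comparable; external scores (OncotypeDX, Mammaprint,
PAM50 risk) are consumed as input columns, never computed here.

## Cohort statistics

Categorical clinical variables are tested against MT/WT status with the
chi-square test, routed to Fisher's exact test when a 2×2 table has an
expected count below 5 (the conventional rule); continuous variables (age)
go to Kruskal–Wallis.  Molecular burdens are compared with the two-sided
Mann–Whitney rank-sum test.  The mutated-gene screen retains genes mutated
in at least 6 signature-MT samples ("more than five"; the threshold is a
parameter), tests each 2×2 mutated × status table with a two-sided Fisher
exact test, and flags the direction of enrichment.  Raw p-values are the
default, matching common screening practice; Benjamini–Hochberg adjustment
is available behind a flag.  Somatic mutation number (SMN) counts distinct
mutated genes per sample by default, with a flag to count mutation records —
the distinction rarely matters but is made explicit.

## Cutoff-free classification

For cohorts without a calibration learning set, status is assigned from the
signature-gene expression directly.  Both routes standardise log2(x+1)
expression per gene (z-scores); the log transform is skippable for data that
is already on a log scale, and per-gene standardisation makes the SVM
invariant to per-gene affine rescaling of its input features.

* **Clustering** — agglomerative Ward linkage on Euclidean distances, cut at
  two clusters; the cluster with the higher fraction of TP53-mutant samples
  is MT.  An exact tie in fractions raises an error instead of guessing.
* **Linear SVM** — hinge loss, C = 1.0, trained on a balanced random subset
  (default 50 per mutation class) drawn with a mandatory seed; predictions
  are returned for held-out samples only, so downstream group statistics are
  not contaminated by training data.  Training sets that are constant in
  every gene are flagged as non-separable.

The somatic-variant filter keeps records with population frequency below 1%
in both SNP databases and read depth strictly above 20.  A frequency absent
from a database counts as 0 (novel variants are kept); a strict mode drops
unannotated records instead.  The filter is a pure subset operation and
idempotent.

## Synthetic data

The generators define the study conditions; their defaults are fixed and the
tests run at those settings.

* Cohort composition: 64 signature-mutant vs 110 wild-type samples, the
  composition of a stage I–II validation cohort.
* Expression: per-gene log-normal count baselines (natural-log mean 6.0,
  sd 1.0 — counts of a few hundred, heavy-tailed across genes) with
  per-sample log-normal noise sd 0.3; mutants multiply up-genes by 2.0 and
  down-genes by 0.5, separating group mean scores about fourfold.  A
  negative-binomial count layer was considered and not adopted: the score
  depends only on within-sample sums, for which the log-normal layer is
  sufficient and simpler.
* FFPE replicates: multiplicative log-normal noise (sd 0.1) on FF counts,
  rounded; at that noise the per-sample Pearson correlation of log counts
  across the 31 genes stays above 0.9.
* Survival: exponential proportional hazards, wild-type hazard 0.002 events
  per month, mutant hazard ratio 4.9, administrative censoring at 60 months
  (≈11% wild-type and ≈44% mutant event probability).
* Labels: structural TP53 mutation agrees with the generating status for
  90% of mutants and 10% of wild-types, so calibration sees realistic label
  noise; classifier-recovery tests switch to perfectly concordant labels
  (1.0/0.0) because they measure classifier behaviour, not label noise.
* Clinical covariates: Bernoulli/categorical draws with per-status rates
  reproducing the qualitative imbalances of an early-stage cohort (ER+ 44%
  MT vs 87% WT, PgR+ 25/72%, HER2+ 19/4%, grade-3 66/10%, node+ 39/27%,
  and stage/age/adjuvant-therapy distributions of the same flavour).
* TCGA-like bundle: background genes mutate at per-status Bernoulli rates
  (0.05/0.02 per gene), TP53 records follow the structural label (so the
  MT-without-TP53-mutation subgroup is non-empty), and CNV burden and
  PD-L1/CD8B levels are log-normal with a ×2 MT location shift.

What the generators do not emulate: whole-transcriptome covariance, batch
and fixation artefacts beyond i.i.d. multiplicative noise, subtype-specific
expression programs, non-proportional hazards, and informative censoring.
Tests passing on this synthetic structure therefore demonstrate the
correctness of the statistical machinery under the assumed model, not the
clinical performance of the assay on real tissue.

## Problem sizes and numerics

Simulation-based tests use cohorts of 300–2,000 samples and 12–20 replicate
seeds; oracle-equivalence tests use ≥100 random instances of size ≤60, where
brute-force enumeration is exact.  Hazard-ratio recovery is asserted within
±15% at n = 2000; log-rank type-I error within [0.03, 0.07] at nominal 0.05
over 1000 null replicates of 50 + 50 samples.  All randomness flows through
`numpy.random.default_rng` seeds; generators are pure functions of
(configuration, seed).  Floating-point conventions: score scale invariance
holds to 1e-12 relative tolerance; genes constant in a training set are
given unit variance during standardisation (they carry no information);
rates are rounded half-away-from-zero only at the reporting boundary, never
internally.

## Known limitations

* Hazard ratios reported by real cohorts depend on unpublished follow-up and
  censoring detail, so they serve here as simulation set-points, not as
  desk-reproducible targets.
* The cutoff convention (interval midpoint) is one of several defensible
  choices; any fixed point of the optimal interval yields identical
  classifications of the calibration data but can differ for future samples
  falling inside the interval.
* The concordance index uses Harrell's original pair rules; estimators that
  correct for censoring distribution (e.g. IPCW) are out of scope.
* The variant filter consumes an already-annotated variant table; calling
  and annotation are upstream of this package.
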