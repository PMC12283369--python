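# Methods

## The model

A synthetic-lethal interaction (SLI) is a gene pair where loss of both genes,
but neither alone, kills a cell. When the *anchor* gene of such a pair is
transcriptionally silenced in a tumor while remaining expressed in healthy
tissue, the *target* gene becomes a cancer-specific vulnerability: knocking
it out kills only the anchor-low cells. `sliminer` mines this structure from
public-style resources: a gene × cell-line expression matrix (log2(TPM+1))
and a matched gene × cell-line CRISPR gene-effect matrix (CERES or Chronos,
where −1 ≈ core-essential and 0 ≈ non-essential).

The scoring statistic is the Pearson correlation between anchor status and
target gene effect across cell lines. An RNA- or protein-anchored SLI
appears as a large **positive** r (low anchor ↔ negative gene effect). For
mutation and methylation anchors the sign of "less gene activity" is
reversed, so their ranking is flipped (`r_directional = −r`). P-values come
from the t-transform of r with n−2 degrees of freedom, two-sided, and are
Bonferroni-corrected by the number of valid tests in the scan — the
denominator is the count of pairs that actually produced a correlation
(pairs skipped for insufficient overlap or constant vectors are excluded and
reported in the scan metadata, so the denominator is auditable). A per-anchor
denominator is a defensible alternative; the per-scan choice is recorded in
the output metadata.

Hit lists are built in three steps: keep each anchor's best pair by the
directional key; rank those pairs; where two pairs share a target gene keep
only the better-ranked one. The de-duplication removes false positives from
anchor co-expression — a cluster of co-expressed anchors will all nominate
the same target, and only the strongest survives. Ties break on larger
sample count, then lexicographically smaller anchor symbol.

## Stage-by-stage notes

**Cancer specificity.** Reduction of anchor expression in tumors is
`max(0, 1 − mean_tumor/mean_healthy) × 100` on the **linear** TPM scale
(log inputs are de-logged first); increases are clipped to a 0% reduction.
Cross-dataset comparisons are put on one scale with housekeeping
("calibration") genes: each calibration gene is divided by its own
grand-mean expression over the union of all co-calibrated datasets (the
union, not per-dataset, because the point is one shared scale; a
per-dataset mode exists for sensitivity checks), the per-sample factor is
the arithmetic mean of those scaled values, and query genes are divided by
it. The proteome variant works on de-logged ratio data and uses the
geometric mean of the normalized calibration ratios. The arithmetic/
geometric asymmetry is deliberate: each variant follows the procedure its
data type conventionally uses. A frozen `reference_means` mapping can
replace the recomputed grand means; with a frozen reference the
normalization is *exactly* invariant to per-sample global rescaling (the
per-sample factor absorbs the constant), whereas with recomputed means the
invariance is only asymptotic in the number of samples — one rescaled
sample shifts every grand mean by O(1/n).

**Group comparison.** Two groups: Mann–Whitney U, two-sided. Three or more:
Kruskal–Wallis omnibus followed, only when significant at α, by pairwise
Dunn tests (z on mean ranks with tie correction) under Bonferroni. Dunn's
test is implemented in-package; percent change is computed on group means of
the linear normalized values.

**Escape scan.** The partial Pearson correlation
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) between each feature and
target lethality, controlling for anchor expression, with p from the
t-transform on n−3 df. Binary mutation features enter the same
product-moment formula (point-biserial). Features whose minor category has
fewer than 3 samples are skipped — partial correlations on near-constant
binaries are unstable. If the anchor fully explains lethality, no other
feature should survive Bonferroni; the test suite checks this type-I
property over 20 simulated cohorts.

**Dose–response.** Cell lines are split into 10 near-equal expression
deciles (stable sort; a tie block straddling a boundary moves wholly into
the earlier bin, so counts may deviate in heavily tied data; the remainder
of n/10 is spread from the lowest bin). Each bin contributes its median gene
effect and IQR at its mean expression. The Hill curve
`y = bottom + (top − bottom)/(1 + (d50/d)^h)` with dose `d = 2^x` is
least-squares fitted (Levenberg–Marquardt, deterministic initialization:
bottom = min median, top = max median, ec50 = midpoint of the steepest
adjacent-bin segment, slope = 1, iteration cap 20,000). The response
variable is the gene-effect score itself, so "maximum synthetic lethality"
is the fitted bottom asymptote and the half-max expression is ec50. The
expression axis uses pseudocount 0.0625, i.e. log2(TPM + 0.0625), with a
converter from log2(TPM+1) via linear TPM; median/IQR are the defaults
(a mean mode is available). The fraction of lines strictly below the
half-max expression measures how much of a panel shows at least half the
maximal lethality.

**Survival.** Patients are stratified into rank-based quartiles of anchor
expression (sizes differ by ≤1, remainder to the bottom quartiles, stable
order on patient id for ties). Lowest vs highest quartile are compared with
the standard two-group log-rank test: at each distinct event time the
expected events per group follow the risk-set proportions, the variance is
hypergeometric, and censoring at an event time keeps the subject in that
time's risk set. The hazard ratio is the Mantel–Haenszel observed/expected
ratio `(O_L/E_L)/(O_H/E_H)` with a 95% CI on the log scale using variance
`1/E_L + 1/E_H` — chosen over a Cox fit because it is the direct companion
of the log-rank statistic; a Cox-based HR (lifelines) is provided as a
cross-check and agrees within sampling error in tests.

**Bench assays.** Tracker lethality double-normalizes the tracked/tracker
count ratio to day 0 and to the control condition; negative values
(outgrowth) are reported as-is because outgrowth is a meaningful rescue
signal. Background correction subtracts `background_fraction ×
tracker_count`, clamping at zero with a flag. qPCR fold changes use −ΔΔCt
with replicates averaged arithmetically first and the per-sample calibration
baseline taken as the **geometric mean of the three calibration-gene Ct
values**. Since Ct is already a log-scale quantity, the arithmetic mean
would be the conventional baseline; the geometric-mean form is the default
here with an `arithmetic` mode flagging the difference.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, plus
ground truth, so every stage is testable without external downloads:

- **Expression**: per-gene baselines uniform on [1, 8] log2(TPM+1) with
  lineage shifts N(0, 0.3) and sample noise N(0, 0.4). Planted anchors are
  bimodal: a `low_fraction` of lines in a half-normal(0, 0.3) "absent" mode
  and the rest in a Normal(5, 0.7) "high" mode, matching the
  absent-vs-expressed bimodality real anchor genes show.
- **Dependency**: background genes get N(−0.2, 0.15) baselines plus
  N(0, 0.25) noise, independent of expression. Planted targets follow
  `−effect · w(anchor) + noise` with `w` a logistic in log2(TPM+1) centered
  at 2.5 (between the modes) with scale 0.35 — smooth enough that the
  dose–response stage can recover a Hill curve from it.
- **Decoys**: a cluster of anchors co-expressed with the first planted
  anchor (anchor + N(0, 0.5)). At this noise level the decoys remain
  strongly co-expressed (r ≈ 0.98 with the anchor) yet the true anchor
  reliably produces the stronger correlation, so the decoys stress the
  de-duplication step without displacing the planted pair.
- **Patients**: healthy means are lognormal per gene; tumor means for
  planted anchors are scaled by `(1 − tumor_reduction_fraction)` (default
  0.64, the magnitude a strongly cancer-specific anchor shows), with
  per-sample lognormal noise of unit mean so the planted reduction is exact
  in expectation and exact sample-by-sample at zero noise. Survival times
  are exponential at 1 event per 1,000 days, multiplied by
  `hazard_ratio_low_vs_high` (default 1.9) for the bottom anchor-expression
  quartile, with independent exponential censoring (30%).
- **Assays**: tracker counts are binomial draws at the planted survival
  fraction; Ct values follow `intercept − log2(expression) + noise`.

Default sizes are 300 genes × 250 cell lines with 5 planted pairs
(effects 0.8–1.1, low fractions 0.30–0.50) and 2,000 patients — large
enough that planted structure separates cleanly from background, small
enough that the full suite runs in seconds. All draws flow from one integer
seed split into named substreams (crc32 of the stream name), so adding a
generator never perturbs another's stream.

**What the generator does not emulate**: real gene–gene covariance beyond
the single co-expression cluster, lineage-specific dependency structure,
measurement batch effects, or non-linear expression–dependency
relationships other than the planted logistic. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure under idealized noise — not performance on real panels, where
confounding is richer.

## Numerical choices and degenerate inputs

- Correlations need ≥3 complete pairs (≥4 triples for partial correlation)
  and non-constant vectors; violations raise a degenerate-input error in the
  scalar API and become counted skips in the scans (no NaN contagion).
- The vectorized scan computes pairwise-complete sums via masked matrix
  products and must agree with the per-pair formula to 1e−10; |r| is clipped
  to 1 and a perfect correlation reports the smallest positive p rather
  than 0 so p ∈ (0, 1].
- `min_overlap` defaults to 30 shared samples; pairs below it are skipped,
  not errored, because different data modalities cover very different
  cell-line subsets.
- Dependency classification is strictly-less-than (−0.5 is *not* lethal);
  high-expression classification is ≥ the cutoff.
- The log-rank variance guard rejects degenerate risk sets (all events at a
  time with a risk set of one contribute no variance).

## Problem sizes

The bundled tests and the acceptance script use the default 300 × 250
cohort for discovery-stage checks, 1,000 cell lines for the dose–response
fraction, 2,000 patients for hazard-ratio recovery, 120 patients × 200
seeds for the log-rank type-I rate, and 10⁶ cells for binomial lethality
recovery — sizes at which Monte-Carlo error is comfortably inside the
asserted tolerances while the whole suite stays fast.

## Known limitations

- Bonferroni only; no FDR alternative (matching the discovery procedure the
  package implements).
- The calibration-gene set is an input; the package ships no curated
  housekeeping list.
- The Mantel–Haenszel HR is biased toward 1 under heavy censoring relative
  to a Cox fit; for the simulated censoring levels the two agree within a
  few percent.
- No downloading of DepMap/GTEx/TCGA releases; users supply files in the
  supported dialects (canonical TSV, DepMap-style CSV, GCT 1.2).
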