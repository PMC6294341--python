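# Methods

## Consensus aggregation

A transcriptional consensus signature (TCS) is meant to capture what a
compound does to the transcriptome *independently of the cell line*. The
two-stage aggregation assumes Level-4 style inputs: per-sample z-scores
that are roughly unit-scale under the null, so |z| > 1 is a meaningful
single-sample exceedance. Replicates and doses are pooled within a
(compound, cell line) group; a gene is called in a direction when the
count of exceeding samples is *strictly* more than `sample_fraction`
(default 0.2) of the group and that direction dominates. Across lines the
calls are summed (n_up − n_down) and zeroed unless the dominant direction
covers strictly more than `cell_fraction` (default 0.3) of the lines.
Both fractions are strict inequalities: 1 of 5 samples (20% exactly) does
not pass, 3 of 10 lines (30% exactly) does not pass. When the up and down
counts within a line tie exactly, the call is 0 — the signed count is
otherwise ill-defined, and a conservative zero avoids inventing signal.
The cross-line gate is applied to the dominant direction
(`max(n_up, n_down)/N`), the reading consistent with a single signed
score per gene. With a single cell line the TCS equals the per-line call
(1/1 > 0.3).

Treatment-time filtering (default 24 h) runs first; profiles with missing
or non-finite z-values are rejected outright, because the counting rules
have no meaningful behavior under missingness.

The high-confidence filter keeps genes with |score| ≥ ⌈f·N⌉ (default
f = 0.5, so 3 of 6 lines). Support-based exclusion drops compounds whose
TCS has fewer non-zero genes than half the reference signature's support
("fewer than" excludes, so equality retains).

## Scoring

Specificity, concordance ratio (CR) and discordance ratio (DR) depend
only on the signs of the three vectors; consensus magnitudes carry no
weight. Zero denominators are handled by policy, config-switchable:

- **Sentinel mode (default):** CR (or DR) with a zero denominator and a
  positive numerator is +∞; before unity normalization all sentinels are
  replaced by the cohort's largest *finite* value, so a perfectly
  concordant compound lands at CR_norm = 1. A 0/0 ratio (no informative
  overlap at all) is 0, with the audit counts (n_concordant,
  n_discordant, n_reversing, n_mimicking) retained in the output so the
  emptiness is visible.
- **Pseudocount mode:** `(num + c)/(den + c)` with c > 0, avoiding
  sentinels entirely.

Unity normalization maps a constant cohort to all-zeros. Ranking is
descending by orthogonality score, ties broken by higher raw DR and then
lexicographic compound id, so output order is deterministic.

A consequence of the sentinel policy worth knowing: in a cohort that
contains *no* genuinely reference-concordant compound other than the
reference itself, the "largest finite CR" is just the largest noise
value, and whichever compound holds it is mapped to CR_norm = 1 jointly
with the reference — occasionally the disease-reverser itself, which
then loses its rank-1 position. Real cohorts contain same-mechanism
analogs of the reference (several BET inhibitors accompany a
BET-inhibitor reference) whose concordance sits far above noise and pins
the top of the scale; the simulation scenario therefore includes one
such analog, and users scoring bespoke cohorts should keep at least one
known reference-concordant compound in them for the same reason.

The cell-line-specific discordance replaces the disease vector with a
ternarized baseline-expression signature of one line, giving a per-line
synergy predictor; the arithmetic is unchanged.

## Non-perturbational signatures

Baseline expression tables (RPKM-like) are normalized per gene as
log2((x + ε)/(median + ε)) with the median across lines and ε = 1 RPKM
(config-exposed; prevents log 0 and damps fold changes of barely
expressed genes). The median is the standard sample median (mean of the
central pair for even n), stated so tests can be exact. Ternarization of
log2 fold changes uses |lfc| > 1 by default, chosen for symmetry with the
z-threshold of 1 in consensus aggregation — an assumption, not a derived
value. Disease signatures take sign(lfc) where adjusted p < α (default
0.05) with an optional fold-change floor; the DE engine is pluggable
input, and the built-in two-sample test on log2(count+1) with
Benjamini–Hochberg adjustment exists for the synthetic pipeline, not as a
replacement for a dedicated count-model DE tool.

Sample correlation (Spearman by default: rank each sample, then Pearson
cross-products) joins tables by gene identifier and requires ≥ 3 shared
genes.

## MOA networks

Pairwise Pearson correlation is computed over the full gene-length TCS
vectors, shared zeros included — the TCS is a fixed-length object and
restricting to joint support would change the estimand; users comparing
against support-restricted variants should be aware of this choice. An
all-zero TCS has no defined correlation and is reported as missing, never
imputed. The network rule is inclusive (edge iff r ≥ 0.7); components are
labeled by their lexicographically smallest member so labels are
input-order invariant. Hierarchical clustering uses average linkage on
1 − r (a conventional choice for correlation-based compound clustering;
config-exposed), with missing correlations assigned the maximal distance
2 under a warning.

## Dose matrices

Plate normalization anchors 0% at the DMSO mean and 100% at the
positive-control mean; values outside [0, 100] (assay noise) are retained
and flagged. For Bliss, fraction-affected is clamped to [0, 1] first —
the independence model is undefined outside — while the raw surface stays
available for audit; the summary is the unweighted mean excess over
combination wells, with the per-well surface always emitted so other
summaries remain recomputable.

Monotherapy margins are fitted with a four-parameter logistic
(E0, Emax, EC50, slope) by least squares; the fit is accepted when it
converges with a positive slope and R² > 0.8, otherwise a monotone
isotonic interpolation takes over (recorded per curve). The Hill inverse
is closed-form and defined for effects in [E0, Emax); the isotonic
inverse interpolates within the achieved effect range only. The Loewe CI
is evaluated at each well's *own* observed effect; wells whose effect a
needed monotherapy curve cannot reach are undefined (NaN, logged) rather
than extrapolated. The isobologram fixes one effect level (default 50%),
locates the contour crossing along each dose axis by linear interpolation
between grid points, and reports doses normalized by the monotherapy
doses achieving the level; the grid interpolation leaves a small
deviation (≈2% on the default 7×7 grid) from the exact contour even for
sham combinations.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions: 978 genes, 6 cell lines,
6 pooled samples per compound-line (plus one 6-h sample exercised by the
time filter), planted signatures of 60 genes at mean |z| = 3 over a
unit-normal background, per-line Bernoulli dropout 0.2 (the feature that
makes the >30% cross-line rule non-trivial), a 132-gene disease
signature, negative-binomial counts (dispersion 0.1) for 153 tumor vs 5
control samples, and 7×7 dose grids of 0 plus 10→0.3125 µM at 1:2
dilutions with Hill margins (E0 = 0, Emax = 100, EC50 = 1 µM, slope 1)
and 2-point plate noise. The ranking scenario plants a hit whose
signature is disjoint from the reference's and reverses 60% of the
disease genes, among MOA-grouped decoys with random signatures.

What the generator does *not* emulate: LINCS marginal z distributions
beyond unit scale, plate/batch effects, dose-dependent signatures,
correlated gene modules, or library-size variation in counts. Passing
recovery tests therefore demonstrates correctness of the counting rules
and rankings under the assumed noise model, not performance on real
LINCS data.

## Problem sizes

The recovery checks use 100 simulated cohorts (17 compounds × 6 lines
× 7 samples each) for ranking, 100 low-noise cohorts (12 compounds) for
MOA recovery, 1,000 random 30-gene triples for the scoring oracle, and
a 3×3 Hill-parameter grid for the Loewe sham identity — sizes at which
the whole suite and the acceptance script each run in well under a
minute while keeping the binomial error of the recovery rates around
2–3 percentage points.

## Known limitations

- GCT support covers the 1.3 and 1.2 text formats; HDF5-backed GCTX
  files are not read.
- Gene identifiers are opaque strings; no symbol/probe mapping is
  attempted.
- Dose units are carried as strings and must already match between the
  two drugs of a matrix.
- The Loewe surface generator caps the combination effect at the weaker
  drug's plateau when the additivity equation has no solution below it;
  the analyzer correspondingly reports those wells as undefined.
- No statistical significance is attached to synergy scores or to the
  orthogonality ranking.
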