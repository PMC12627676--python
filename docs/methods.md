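# Methods

This note describes the models and procedures implemented in `splicemut`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Problem setting

In myelodysplastic syndromes (MDS) with *SF3B1* hotspot mutations, mutant
cells preferentially use cryptic 3' splice acceptors at a known set of
mis-splicing events (3' alternative splice sites and skipped exons).
Single-cell RNA-seq does not observe the mutation directly in most cells —
junction-spanning coverage is sparse — but the aggregate cryptic-usage
signal across many events carries enough information to genotype
individual cells. Once cells are assigned to the mutant clone or its
wild-type counterpart, clone-aware analyses follow: pseudobulk
differential expression between clones, niche signature scores and their
coupling, cell-type composition shifts, and ligand-receptor interaction
usage between stromal and hematopoietic populations.

## Per-cell genotype inference

**Feature.** For event *e* in cell *c* with cryptic junction reads
*k* and canonical reads *n*, the usage fraction is *u = k / (k + n)*,
defined only where *k + n > 0*. An uncovered event is missing, never
zero: absence of junction reads is not evidence for canonical splicing.
The bounded fraction (rather than the signed contrast
*(k − n)/(k + n)*, an affine transform of it) keeps the feature in
[0, 1], which simplifies threshold calibration; the two parametrizations
are equivalent for a linear classifier.

**Coverage filter.** A cell is classifiable when at least `min_events = 2`
events are covered. Cells below the threshold are still scored but always
reported `unclassified`, keeping the score distribution inspectable.

**Imputation.** Missing usage entries are filled with the per-event mean
over covered cells (computed over all cells, not per donor — the simplest
reading of mean imputation). Events covered in zero cells have no
defensible fill value and are dropped with a warning.

**Classifier.** Cell-level genotypes are unobserved, so each cell
inherits its donor's mutation status as a *weak label*: labels are clean
for wild-type donors (their cells are all truly wild type) and noisy for
mutant donors (a fraction 1 − *f* of cells are wild type, *f* the clone
fraction). An L2-penalized logistic regression (penalty λ, default 1.0;
L-BFGS, tolerance 1e-8) is fitted on the imputed usage features against
these weak labels.

**Cross-fitted scores.** In-sample logistic scores are biased toward the
training labels: under the null (no splicing signal), cells of
mutant-labeled donors would still score systematically higher than
wild-type-donor cells, and a threshold calibrated on wild-type cells
would not transfer. The classifier therefore reports out-of-fold scores
for every cell seen during fitting (5-fold stratified cross-fitting,
seeded); matrices not seen during fitting are scored with the full
model. This keeps all cells exchangeable with the calibration set, which
is the property the error-rate contract relies on.

**FPR calibration.** The decision threshold τ is the (1 − α) empirical
quantile (ties resolved upward, hence conservative) of the scores of a
calibration split of wild-type-donor cells, with target false-positive
rate α = 0.10 by default. Wild-type-donor cells are split 50/50
(seeded) into a calibration half and a held-out half; the held-out half
provides an honest estimate of the realized FPR. Both halves
participate in fitting under their weak labels, which preserves their
exchangeability; a `holdout_calibration` option excludes the calibration
half from fitting instead. Calibration pools cells across wild-type
donors; a per-donor variant was considered and rejected as the default
because per-donor quantiles at a few hundred cells are noisy. A cell is
called mutant iff its score is *strictly* above τ, so a score exactly at
the threshold stays wild type.

## Pseudobulk differential expression

Raw counts of the selected cells (by default erythroid progenitors with a
definite genotype call) are summed per donor × predicted genotype.
Genes are pre-filtered on fragments per million (FPM = count / group
library size × 1e6): a gene is kept if it reaches ≥ 2 FPM in at least
⌈half⌉ of the donors of either contrast side (ceiling, the stricter
reading for odd donor counts).

Size factors are median-of-ratios against the geometric-mean reference
over genes with no zero counts, falling back to library-size factors when
fewer than 10 such genes exist.

Each gene is tested with a negative-binomial GLM (log link, log
size-factor offset, donor as fixed-effect indicator covariate, genotype
as the tested coefficient), fitted by IRLS. The dispersion model respects
the pseudobulk construction: a group summing *n* cells whose counts are
NB2 with per-cell dispersion α is exactly NB with dispersion α/*n* (a sum
of iid NB(μ, α) draws is NB(*n*μ, α/*n*)), so the per-group variance is
μ_j + (α/*n*_j) μ_j². Ignoring the group-size scaling (one shared α
across groups of unequal cell number) measurably miscalibrates the Wald
test when clone splits make group sizes uneven. α is estimated per gene
by solving the Pearson χ² moment equation
Σ (y − μ)²/(μ + α μ²/n) = n_groups − p at the residual degrees of
freedom (floored at 1e-8 for under-dispersed genes), from a Poisson
pilot fit. The genotype coefficient is tested with a two-sided Wald z
statistic, and p values are Benjamini–Hochberg adjusted over the tested
genes. No effect-size shrinkage is applied; acceptance of the module is
parameter recovery on simulated truth, not numerical parity with any
external engine. Under within-donor permutation of genotype labels the
resulting p values are uniform (checked by KS in the test suite).

Degenerate cases: all-zero genes report LFC 0, p 1; a rank-deficient
design (e.g. genotype confounded with donor) raises an error naming the
collinear columns; a Wald SE of zero (identical groups) reports p 1.

## Niche signature scores

Scoring uses a counts-per-10k log transform, ln(1 + count/libsize × 1e4).
The scoring algorithm — not the normalization — is the object under test
here, so the heavier variance-stabilizing normalization used upstream of
the original scores is out of scope.

The module score follows the control-gene-binned definition: all genes
are ranked by mean expression across cells and cut into `n_bins = 24`
equal-frequency bins (ties broken by stable gene order); for each
signature gene, `n_ctrl = 100` control genes are drawn with replacement
from its bin (seeded); a cell's score is the mean expression of the
signature genes minus the mean over the pooled control draw. Controls
are pooled across the signature rather than averaged per gene, matching
the canonical definition. The bin/control defaults are the canonical
ones; the upstream analysis does not state its values.

Score coupling between two signatures (inflammation and HSPC support) is
summarized per condition by the Pearson correlation coefficient, with a
two-sided p value from t = r√(n−2)/√(1−r²) on n−2 degrees of freedom.
Zero-variance score vectors leave r undefined rather than zero.

## Composition analysis

Cell-type counts are tabulated per condition (optionally per donor).
For display and downstream linear analysis, proportions are
probit-transformed, Φ⁻¹(p) with p clamped to [ε, 1−ε], ε = 1/(2N) for
group size N, keeping empty and full categories finite.

Enrichment of each cell type in a condition versus Control is a
one-vs-rest two-sided Fisher exact test on [type, rest] × [condition,
Control], pooling cells across donors (matching the upstream cell-level
test), with BH adjustment across the cell types of the population and
the sample odds ratio reported (zero margins map to ∞ by convention).
Pooling cells pseudoreplicates donors; a donor-aggregate variant
(Mann–Whitney on donor-level proportions) is provided for users who
prefer rigor over fidelity.

## Ligand-receptor interactions

For a ligand-receptor entry (L, R), the score of a sender cell s and
receiver cell r is expr_L(s) · expr_R(r) on the log-normalized matrix.
Cell pairs are formed within donors only (sender-type × receiver-type),
exhaustively by default with a configurable cap and seeded uniform
subsampling beyond it. A pair's interaction count is the number of LR
entries with strictly positive score; pairs with fewer than
`min_interactions = 5` are removed. Retained-pair counts are normalized
by the possible pairs of the donor, n_senders × n_receivers; a zero-cell
denominator leaves the value missing. Condition-level values pool donors
as a ratio of sums. Condition shifts for a sender–receiver pair are
tested by Fisher's exact test on [retained, possible − retained] ×
[condition A, condition B].

## Synthetic cohort generator

The generator emulates the analyzed cohort structure with full ground
truth. Defaults: 3 wild-type-labeled donors (condition Control) and 4
mutant-labeled donors (condition MDS), 400 cells per donor, 50
mis-splicing events; `SimConfig.full_cohort()` adds 3 CHIP donors
(wild type for the splice factor) for three-condition analyses. Per
cell of donor d the genotype is Bernoulli(f_d) with clone fraction
f_d = 0.6 for mutant donors and 0 otherwise. Per event, total reads are
Poisson(0.6) — plain Poisson, no extra zero inflation; the rate alone
controls the sparsity the ≥2-event filter acts on — and cryptic reads
are Binomial(total, ψ), with ψ0 = 0.02 for wild-type and ψ1 = 0.35 for
mutant cells (optionally jittered per event around these values by a
Beta concentration parameter, off by default). The event count is a
configurable stand-in (the upstream event list is distributed
separately and its size unstated); 50 gives a median of ~22 covered
events per cell at the default coverage, so the coverage filter binds
only in sparser configurations.

Expression is NB2 (Gamma–Poisson) with lognormal base means, lognormal
per-cell size factors (σ = 0.3), per-cell dispersion α = 0.1, and 100 of
2000 genes at true log2 fold change 1.0 in mutant cells. Cell types are
multinomial draws from condition-specific proportion vectors (MDS
erythroid-skewed, stromal fraction constant across conditions).
Two disjoint signature gene sets (inflammation-like and support-like, 30
genes each) are modulated in stromal cells by per-cell latent factors
with condition-dependent correlation (0 in Control, −0.9 CHIP-like,
+0.9 MDS-like, scale 0.5 in log2 units), reproducing the anti-coupled
vs coupled contrast between conditions.

All randomness flows from one root seed through named substreams; runs
are byte-identical given the configuration.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about patient data: ambient RNA, doublets, batch and
chemistry effects, UMI duplication, donor-level expression heterogeneity
beyond the donor covariate, event-to-event linkage along transcripts,
mean-dependent dispersion trends, and realistic gene-gene correlation
outside the injected signature programmes. Headline numbers from the
motivating study (total cell counts, specific DE gene counts, specific
correlation magnitudes and odds ratios) require the deposited patient
data and are not reproduced here; the tests check procedural constants,
parameter recovery and qualitative contrasts instead.

## Problem sizes and numerical choices

The test and acceptance workloads use the default cohort (2,800 cells,
50 events, 2,000 genes) for single-run checks, a 300-gene variant for
replicated permutation-null checks, and 10 seeded replicates for
power/null-control claims; these sizes give the binomial/KS tolerances
quoted in the tests while keeping each suite run in tens of seconds.
Logistic fits use L-BFGS at tolerance 1e-8; IRLS uses step tolerance
1e-10 with η clipped to ±30; dispersion root-finding brackets upward
from 1 by decades. Quantile calibration uses the "higher" method
(upward tie resolution). Brute-force oracles in the tests (loop
recomputation, exhaustive hypergeometric enumeration, step-up BH) are
written independently of the library paths they check.

## Known limitations

- The weak-label logistic model assumes events are exchangeable carriers
  of one global signal; it does not model event-specific effect sizes
  (beyond what the weights learn from data) or transcript-level linkage.
- FPR calibration is pooled across wild-type donors; per-donor error
  rates may vary around the target.
- The DE model treats donors as fixed effects and groups as independent
  given the design; it is not a mixed model and does not shrink effect
  sizes.
- Composition and interaction Fisher tests pool cells (or cell pairs)
  across donors and therefore inherit pseudoreplication; the donor-level
  variants are provided but less powerful at small donor counts.
- The module-score bins depend on the background matrix supplied; scores
  fitted on one population should not be compared across differently
  composed backgrounds.
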