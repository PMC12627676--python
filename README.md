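# splicemut

Per-cell *SF3B1* mutant-clone inference from cryptic splice-site usage in
single-cell RNA-seq, with clone-aware downstream analytics for bone
marrow cohorts: pseudobulk differential expression between predicted
clones, niche signature scores and their coupling, cell-type composition
tests, and ligand-receptor interaction scoring. A seeded synthetic
cohort generator with full ground truth drives every analysis, so no
patient data is required to develop against or validate the pipeline.

## Who this is for

Computational biologists analyzing myeloid-neoplasm (CHIP / MDS)
single-cell data who want to split cells of *SF3B1*-mutant donors into
mutant and wild-type clones using transcriptome-intrinsic evidence, and
to carry that clone assignment through standard niche analyses with
controlled error rates.

## The model

*SF3B1* hotspot mutations cause usage of cryptic 3' splice acceptors at
a catalog of mis-splicing events. For event *e* in cell *c* the usage
fraction is

    u_ce = cryptic_ce / (cryptic_ce + canonical_ce)

defined only where the event is covered. Cells covering ≥ 2 events are
classifiable; missing entries are mean-imputed per event. Because
per-cell genotypes are unobserved, a weak-label L2-penalized logistic
regression is fitted with the *donor's* mutation status as each cell's
response; scores are cross-fitted (out-of-fold) so that no cell is
scored by a model that saw it. The decision threshold τ is calibrated on
cells of wild-type donors to a target false-positive rate α = 0.10: τ is
the (1 − α) empirical quantile of their scores (ties upward), and a cell
is called mutant iff score > τ.

Downstream, predicted clones feed a donor × genotype pseudobulk NB GLM
Wald test with a ≥ 2 fragments-per-million gene filter, control-binned
module scores (score = mean signature expression − mean of
expression-matched controls), probit-transformed composition tables with
one-vs-rest Fisher tests (BH-corrected), and ligand × receptor cell-pair
scores filtered at ≥ 5 interactions and normalized by possible pairs per
donor. `docs/methods.md` has the full specification of each step.

## Worked example

Run the full pipeline on the default synthetic cohort (3 wild-type and 4
mutant donors, 400 cells each, 50 events, clone fraction 0.6):

```bash
splicemut run --out run1 --seed 7
```

which prints (abridged) the per-stage report:

```json
{
  "simulate":  {"n_cells": 2800, "n_genes": 2000, "n_events": 50, "n_donors": 7},
  "classify":  {"n_calls": 2800, "n_mut": 1182, "n_unclassified": 0,
                "auc_vs_truth": 0.99956},
  "de":        {"n_groups": 14, "n_genes_tested": 2000, "n_sig": 120},
  "score":     {"pcc": {"Control": -0.0238, "MDS": 0.7404}},
  "interactions": {"n_pairs_scored": 131645, "n_pairs_retained": 122060}
}
```

Reading the numbers: of 2,800 cells all pass the ≥2-event coverage
filter at the default coverage rate; 1,182 are called mutant (the truth
is 4 donors × 400 cells × clone fraction 0.6 ≈ 960 mutant cells plus the
calibrated 10% false-positive allowance among wild-type cells), and the
continuous scores separate true genotypes at AUC 0.9996. The pseudobulk
test flags 120 genes at padj < 0.05 — the 100 genes simulated at log2FC
= 1 plus a controlled remainder. The inflammation / HSPC-support score
correlation is near zero in Control stromal cells and strongly positive
in MDS ones, matching the simulated coupling.

Every stage is also available as a library call
(`splicemut.simulate_cohort`, `compute_usage`, `CloneClassifier`,
`pseudobulk`/`nb_de_test`, `module_score`, `one_vs_rest_fisher`,
`lr_scores`, …) and as individual CLI subcommands (`simulate`, `usage`,
`classify`, `de`, `score`, `composition`, `interactions`).

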