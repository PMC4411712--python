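# sistf — transcription-factor and maternal-factor prediction

`sistf` identifies **transcription factors (TFs)** among proteins by
supervised classification on binary Pfam-domain / GO-term feature vectors,
and calls **strictly maternal factors (MFs)** — egg-specific transcripts —
from normalized expression matrices. It is aimed at regulatory and
developmental genomics work where DNA-binding-domain scans alone over- or
under-call TFs: some non-TF proteins carry TF-like domains (e.g. C2H2 zinc
fingers in RNA-binding proteins), while weakly conserved TFs escape pure
homology searches.

## The method

Each protein *m* is a binary vector `v_m ∈ {0,1}^N` over an alphabetically
sorted universe of `N` features (Pfam accessions and GO terms). Training
proteins carry one or more of four categories: `TFS` (transcription
factors), `MEM` (transmembrane proteins), `ENZ` (enzymes), `OTS` (other).

**Statistical information weights.** For feature *i* and category *j*, with
`C_ij` the count of category-*j* proteins carrying the feature, `N_j` the
category size and `C_i = Σ_j C_ij`:

    P_ij  = C_ij² / (N_j · C_i)        joint occurrence probability
    IC_ij = −log₂ P_ij                 information content
    w_ij  = 1 / IC_ij   (0 if P_ij=0)  weight (capped at W_MAX for P_ij→1)

**Feature selection by mutual weight difference (MWD).** Sorting each
feature's four weights descending as `w_(1) ≥ … ≥ w_(4)`:

    MWD_i = w_(1) − (w_(2) + w_(3) + w_(4)) / 3

Features with `w_(1) < w_(2)+w_(3)+w_(4)` are pruned; the rest are ranked
by `MWD_i`. Leave-one-out cross-validation (LOOCV) over a grid of top-*k*
cutoffs selects the *k* with the best TF-vs-rest accuracy.

**Classification.** A query *a* is scored against every training protein
*b* in every category *j* that *b* belongs to:

    SCORE(a,b,j) = cos(v_a, v_b) · Σ_{k ∈ a∧b} w_kj

and takes the category of the maximum score (nearest-neighbor rule).
Performance is reported as sensitivity, specificity, accuracy, precision
and Matthews correlation coefficient.

Around the classifier the package implements the full data path: sequence
pre-filters (length 50–5000, regular amino-acid alphabet), hmmscan
`--domtblout` and 12-column BLAST readers, conservative GO-term transfer
(E ≤ 1e-10, top 10 hits, ≥ 50% majority), corpus filters (features in < 20
genes removed, featureless genes dropped), rule-based training-label
construction with a cofactor veto and homology propagation, and the MF
caller (egg expression ≥ 4-fold over *every* late-stage somatic sample,
with early embryos / gonads / ES cells excluded from the comparison and an
any-probe gene-collapse rule).

## Worked example

Fit the classifier on a synthetic gene set with planted category
signatures (100 genes per category; 10 signature features per category
present with probability 0.9 in their own category and leaking at 0.05
elsewhere; 60 background features):

```python
from sistf import SISModel
from sistf.fixtures import SignatureSpec, generate_geneset

spec = SignatureSpec(seed=7)          # 100 genes/category, 10 signatures each
geneset, truth, signatures = generate_geneset(spec)
results = SISModel(geneset, truth).fit()
print(results.summary())
```

prints

```
Statistical information similarity classifier (NNA, LOOCV-selected features)
============================================================================
Training samples: 400    Features: 100 (pruned: 60, ranked: 40)
Category sizes:   TFS 100  MEM 100  ENZ 100  OTS 100
Selected top-k:   16

LOOCV, TF vs rest, at the selected k:
  TP 100  FP 0  TN 300  FN 0
  sensitivity 1.0000  specificity 1.0000  accuracy 1.0000
  precision 1.0000  MCC 1.0000
  four-way accuracy 1.0000
```

All 60 background features are pruned by the MWD rule, the 40 planted
signatures make up the ranking, and LOOCV at the selected cutoff (k = 16)
separates TFs from the rest perfectly under these planted conditions.
`results.predict(...)`, `results.plot_performance()`, `results.save(dir)`
and the `sistf` command-line tool (`annotate`, `sis`, `mf`, `fixtures`,
`run` subcommands) build on the same two objects.

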