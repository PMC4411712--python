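# Methods notes

This note records the model assumptions, parameter meanings, numerical
choices and known limitations of `sistf`. It documents how results are
computed; every number quoted in the README is printed by the code itself.

## Model and assumptions

The classifier treats protein function assignment as nearest-neighbor
search in a binary feature space. Its premises:

* A protein's Pfam domains and transferred GO terms are informative about
  membership in one of four coarse categories — transcription factors
  (TFS), transmembrane proteins (MEM), enzymes (ENZ), other (OTS). A
  protein may hold several categories (e.g. a membrane-bound enzyme); a
  multi-label training protein contributes its features to `C_ij` and
  itself to `N_j` for *every* category it holds, and a prediction is
  counted correct when it matches *any* held label.
* Feature informativeness is category-specific. The joint probability
  `P_ij = C_ij²/(N_j·C_i)` balances intra-category prevalence
  (`C_ij/N_j`) against inter-category specificity (`C_ij/C_i`); its
  information content `−log₂P` is large for rare-in-category or shared
  features, so the weight `w = 1/IC` is large exactly for features that
  are both common within and exclusive to a category.
* The headline evaluation is TF-vs-rest (TFS predictions are positives);
  the four-way assignment accuracy is reported alongside in the LOOCV
  curve (`fourway_accuracy`) because the best-k choice by TF-vs-rest
  accuracy alone can, on easy data, settle on a small k at which non-TF
  categories are left unclassifiable.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| Pfam E-value | 1e-3 | full-sequence hmmscan E-value cutoff (inclusive) |
| GO E-value / top hits / majority | 1e-10 / 10 / 0.5 | BLAST-based GO transfer: filter, truncate, then adopt terms on ≥ half the kept hits (denominator = kept hits, not 10) |
| min gene count | 20 | features seen in fewer genes are removed, then featureless genes dropped — in that order, once |
| homology labeling | ≥2 hits, top 10, ≥ half, identity ≥25%, E ≤1e-20 | label propagation for rule-silent genes; categories TFS/MEM/ENZ only, residual = OTS |
| `w_max` | 1e6 | weight cap where `IC → 0` (a category-exclusive, category-universal feature has `P = 1` and an otherwise infinite weight); also caps `1/IC` for `P` just below 1, preserving the "more informative ⇒ larger weight" ordering without infinities |
| MF fold | 4 (inclusive) | egg statistic vs every somatic sample, linear scale |
| egg statistic | mean (min available) | aggregate over egg replicates |
| k grid | 1, 2, 4, … , full ranking | LOOCV sweep ladder; each LOOCV pass is O(M²·k), so the default grid is logarithmic; any explicit grid (including k = 0) is accepted |

All thresholds written as "no less than"/"threshold of x" are implemented
inclusively (`≤` for E-values, `≥` for counts and fractions).

## Numerical choices

* **Sorted order.** "Alphabetical" feature order is ascending byte-wise
  order of feature ID strings; training samples are held in ascending
  gene-id order so tie-breaking is reproducible.
* **Tie-breaks.** Nearest-neighbor ties resolve by category priority
  TFS > ENZ > MEM > OTS, then neighbor id ascending; MWD ranking ties by
  feature id ascending; equal-accuracy k values resolve to the smaller k.
* **Exact, order-independent scoring.** For scoring, weights are quantized
  once to multiples of 2⁻²⁰ and shared-feature sums are accumulated in
  int64. Sums are then exactly associative, so the vectorized
  implementation, a naive per-pair double loop, and chunked/threaded
  evaluation produce bit-identical scores and identical tie decisions. The
  ~1e-6 grid is orders of magnitude below any decision margin;
  full-precision weights are what the model stores and reports. Cosine
  norms are computed as `sqrt(|a|·|b|)` — one square root of an exact
  integer — so identical supports give similarity exactly 1.
* **Weights are not re-estimated per k.** `P_ij` depends only on feature
  *i*'s own counts, so restricting the feature set cannot change any
  surviving feature's weight; a per-k re-estimation switch would be a
  mathematical no-op and is deliberately not offered.
* **Degenerate inputs.** Queries with no selected feature, or whose best
  score is 0, are reported unclassifiable and counted as negative (non-TF)
  predictions. Evaluation measures with zero denominators are reported as
  undefined (NaN) rather than 0; MCC with a zero factor under the root is
  reported as 0 with an explicit flag.
* **MF scale check.** The caller refuses matrices that look
  log2-transformed (no value above 30) unless the linear scale is
  asserted, because the fold rule is a linear-scale ratio.

## Labeling rules

TFS fires on a configurable "transcription factor activity" phrase list
matched against GO/Pfam term descriptions, or on "transcription factor" /
"transcription initiation factor" in the name or description. The shipped
phrase list is a documented stand-in for the original curated list, which
is not recoverable; it is a plain text input (`--tf-phrases`) so users can
substitute their own. Cofactor wording (cofactor, coregulator,
coactivator, corepressor) **vetoes** TFS and forces OTS — precedence chosen
so that "transcriptional coactivator" never counts as a TF. Enzyme
detection from free text uses an EC-number pattern plus an "-ase"-word
heuristic with an English-word stoplist, since the original RefSeq-based
rule is unspecified. TMHMM is not run; a precomputed flag is accepted.
CD-HIT redundancy removal is likewise consumed as a precomputed cluster
table (longest member kept) rather than re-implemented.

## What the synthetic data emulates — and what it does not

`fixtures` plants category-specific feature signatures (presence
probability 0.9 in the own category, leakage 0.05 elsewhere, background
features at 0.1 — the background rate is this package's choice of a
realistic nuisance-annotation level) and, for the MF caller, egg-specific
genes at or above the fold boundary. The generators are deterministic per
seed, with one RNG substream per category consumed in a documented order
so tests can re-simulate them independently.

Noiseless expression fixtures draw integer egg levels and set somatic
values to exactly `egg/fold`, making the inclusive boundary exact in
floating point; noisy fixtures clip log2 noise at 3 sd and keep a
`6·σ + 0.25` construction margin (hence the `σ < 1/3` limit) so
planted/non-planted status stays unambiguous. Samples of "excluded"
classes are generated high in planted genes, so a caller that forgets the
exclusion rule visibly fails.

What passing these tests does **not** show: real Pfam/GO annotations are
correlated (domains imply GO terms), category sizes are strongly
unbalanced at corpus scale, feature counts are in the thousands, and
microarray noise is not i.i.d. log-normal. The fixtures validate the
algorithmic machinery, not the attainable accuracy on real proteomes.

## Problem sizes used in tests and the acceptance script

Formula-level checks run ≥ 1000 random instances of ≤ ~22 genes × ≤ 10
features against brute-force references; LOOCV equivalence runs a
60-gene × 20-feature planted instance against a full O(M²N) double-loop
oracle; the classifier benchmark uses the 400-gene / 100-feature planted
design; the MF benchmark 500 genes × 2 probes. These sizes exercise every
code path while keeping the whole suite in seconds; the implementation
itself is vectorized and comfortably handles thousands of genes.

## Known limitations

* The ontology is not traversed: GO terms are used exactly as transferred,
  with no ancestor propagation (term merging belongs to browsing, not to
  the feature space).
* `P_ij` close to 1 maps to the `w_max` cap, collapsing the ordering among
  near-universal exclusive features; with four balanced categories this is
  rare, but heavily skewed training sets could hit it.
* The best-k rule optimizes TF-vs-rest accuracy only; use the stored curve
  (`fourway_accuracy` column) if four-way resolution matters.
* The MF caller compares against each somatic sample individually — the
  strictest reading of "every late-stage somatic sample"; a per-class-mean
  comparison would be laxer and is not offered.
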