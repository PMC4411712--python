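"""Statistical-information-similarity (SIS) classification.

The method encodes each gene as a binary vector over an alphabetically
ordered feature space, estimates a per-feature, per-category weight from an
information-content statistic, ranks features by their mutual weight
difference (MWD), and classifies queries with a nearest-neighbor rule on a
weighted cosine score. Leave-one-out cross-validation over a grid of top-k
feature cutoffs selects the feature subset with the best TF-vs-rest
accuracy.

Statistics
----------
For feature *i* and category *j* (TFS/MEM/ENZ/OTS), with ``C_ij`` the number
of category-*j* training genes carrying the feature, ``N_j`` the category
size and ``C_i = sum_j C_ij``:

    P_ij  = C_ij^2 / (N_j * C_i)          (joint occurrence probability)
    IC_ij = -log2 P_ij                     (information content)
    w_ij  = 1 / IC_ij  (0 when P_ij = 0)   (weight, capped at ``w_max``)

MWD_i = w_(1) - (w_(2)+w_(3)+w_(4))/3 over the four category weights sorted
descending; features with w_(1) < w_(2)+w_(3)+w_(4) are pruned. The score of
query *a* against training gene *b* in category *j* is

    SCORE(a,b,j) = cos(a,b) * sum_{k in a AND b} w_kj

and the query is assigned the category of the (b, j) pair with the maximum
score (ties: category order TFS > ENZ > MEM > OTS, then neighbor id
ascending; training genes are kept in ascending id order).

Numerical note: for scoring, weights are quantized once to a dyadic grid
(multiples of 2^-20) and the shared-feature sums are accumulated in exact
int64 arithmetic. Sums are therefore order-independent, so the vectorized
implementation, any naive per-pair re-implementation of the formulas, and
chunked/threaded evaluation all produce bit-identical scores and identical
tie-breaking. The quantization (~1e-6 resolution) is far below any decision
margin; the full-precision weights are what the model reports.
"""

from __future__ import annotations

import json
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CATEGORIES, NNA_TIE_ORDER, AnnotatedGeneSet, FeatureSpace
from .errors import ConfigurationError, ConsistencyError, InputError
from . import metrics as _metrics

#: Dyadic quantization scale for score arithmetic (resolution 2^-20 ~ 1e-6).
SCORE_SCALE = 1 << 20

#: Default cap for the weight of a category-exclusive, category-universal
#: feature (P = 1 makes IC = 0 and 1/IC infinite).
W_MAX_DEFAULT = 1e6

MODEL_FORMAT_VERSION = "sistf-model-1"

LabelMap = Mapping[str, frozenset[str]]


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode(geneset: AnnotatedGeneSet) -> tuple[list[str], np.ndarray]:
    """Binary encoding of a gene set.

    Returns ``(gene_ids, matrix)`` where row *m* of the uint8 matrix is the
    indicator vector of gene *m* over the sorted feature space.
    """
    return geneset.gene_ids, geneset.to_matrix()


# ---------------------------------------------------------------------------
# weight estimation
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Per-feature, per-category counts and weights.

    Columns follow :data:`~sistf.datatypes.CATEGORIES` order. ``W`` holds the
    full-precision weights; ``w_int`` the dyadic quantization used by the
    scoring arithmetic.
    """

    feature_ids: tuple[str, ...]
    C: np.ndarray          # (N, 4) int64 — C_ij
    n_j: np.ndarray        # (4,)   int64 — N_j
    c_i: np.ndarray        # (N,)   int64 — C_i
    P: np.ndarray          # (N, 4) float64
    IC: np.ndarray         # (N, 4) float64 (inf where P = 0)
    W: np.ndarray          # (N, 4) float64
    w_max: float = W_MAX_DEFAULT

    @property
    def w_int(self) -> np.ndarray:
        return np.rint(self.W * SCORE_SCALE).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature_id": self.feature_ids})
        for k, cat in enumerate(CATEGORIES):
            df[f"C_{cat}"] = self.C[:, k]
        df["C_total"] = self.c_i
        for k, cat in enumerate(CATEGORIES):
            df[f"w_{cat}"] = self.W[:, k]
        return df


def _label_matrix(labels: Sequence[frozenset[str]]) -> np.ndarray:
    Y = np.zeros((len(labels), len(CATEGORIES)), dtype=bool)
    for m, cats in enumerate(labels):
        if not cats:
            raise InputError(f"sample {m} has no category")
        bad = set(cats) - set(CATEGORIES)
        if bad:
            raise InputError(f"sample {m} has unknown categories {sorted(bad)}")
        for c in cats:
            Y[m, CATEGORIES.index(c)] = True
    return Y


def estimate_weights(
    matrix: np.ndarray,
    labels: Sequence[frozenset[str]],
    feature_ids: Sequence[str],
    w_max: float = W_MAX_DEFAULT,
) -> WeightTable:
    """Estimate the information-content weight table from training data.

    A multi-label sample contributes its features to ``C_ij`` and itself to
    ``N_j`` for every category it belongs to. Raises
    :class:`ConfigurationError` when a category has no samples and
    :class:`ConsistencyError` for an in-space feature carried by no sample.
    """
    if w_max <= 0:
        raise ConfigurationError(f"w_max must be positive, got {w_max}")
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != len(labels):
        raise InputError("matrix rows must align with labels")
    if matrix.shape[1] != len(feature_ids):
        raise InputError("matrix columns must align with feature_ids")
    Y = _label_matrix(labels)
    n_j = Y.sum(axis=0).astype(np.int64)
    if (n_j == 0).any():
        empty = [c for c, n in zip(CATEGORIES, n_j) if n == 0]
        raise ConfigurationError(f"categories with no training samples: {empty}")
    C = matrix.astype(np.int64).T @ Y.astype(np.int64)      # (N, 4)
    c_i = C.sum(axis=1)
    if (c_i == 0).any():
        bad = [feature_ids[i] for i in np.flatnonzero(c_i == 0)[:3]]
        raise ConsistencyError(f"features with zero total count, e.g. {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(C > 0, (C.astype(float) ** 2) / (n_j.astype(float) * c_i[:, None].astype(float)), 0.0)
        IC = np.where(P > 0, -np.log2(np.where(P > 0, P, 1.0)), np.inf)
        W = np.where(P > 0, np.where(IC > 0, np.minimum(1.0 / np.where(IC > 0, IC, 1.0), w_max), w_max), 0.0)
    return WeightTable(tuple(feature_ids), C, n_j, c_i, P, IC, W, w_max)


# ---------------------------------------------------------------------------
# MWD feature ranking
# ---------------------------------------------------------------------------

@dataclass
class MWDRanking:
    """Features ranked by mutual weight difference, pruned set aside.

    ``order`` holds indices into the weight table's feature list, sorted by
    MWD descending (ties: feature id ascending). ``pruned`` holds the indices
    removed because the top weight was below the sum of the other three.
    """

    order: np.ndarray
    mwd: np.ndarray                 # aligned with ``order``
    pruned: np.ndarray
    feature_ids: tuple[str, ...]    # full table order, for index resolution

    def __len__(self) -> int:
        return len(self.order)

    @property
    def ranked_feature_ids(self) -> list[str]:
        return [self.feature_ids[i] for i in self.order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.ranked_feature_ids, "mwd": self.mwd}
        )


def rank_features_mwd(weights: WeightTable) -> MWDRanking:
    """Rank features by MWD and prune weakly category-specific ones."""
    srt = np.sort(weights.W, axis=1)[:, ::-1]            # per-feature descending
    mwd = srt[:, 0] - (srt[:, 1] + srt[:, 2] + srt[:, 3]) / 3.0
    keep_mask = srt[:, 0] >= (srt[:, 1] + srt[:, 2] + srt[:, 3])
    kept = np.flatnonzero(keep_mask)
    order = sorted(kept, key=lambda i: (-mwd[i], weights.feature_ids[i]))
    order = np.asarray(order, dtype=np.int64)
    return MWDRanking(order, mwd[order], np.flatnonzero(~keep_mask), weights.feature_ids)


# ---------------------------------------------------------------------------
# similarity and score
# ---------------------------------------------------------------------------

def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two binary vectors; error on a zero vector.

    The norm product is evaluated as ``sqrt(|a| * |b|)`` (a single exact
    integer product under one square root) so identical supports give
    exactly 1.0.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise InputError("similarity undefined for a zero vector")
    return float(int(a @ b) / math.sqrt(na * nb))


def score(a: np.ndarray, b: np.ndarray, weights: WeightTable, category: str) -> float:
    """Weighted cosine score of ``a`` vs ``b`` for one category.

    The weight sum runs over features present in *both* vectors, using the
    quantized weights (see module docstring).
    """
    j = CATEGORIES.index(category)
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    shared = a * b
    sw = int(shared @ weights.w_int[:, j])
    return similarity(a, b) * (sw / SCORE_SCALE)


# ---------------------------------------------------------------------------
# nearest-neighbor classification
# ---------------------------------------------------------------------------

def _score_block(
    Q: np.ndarray,
    T: np.ndarray,
    w_int: np.ndarray,
    train_label_mask: np.ndarray,
    diag_offset: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized NNA over a block of queries.

    Returns ``(pred_tie_idx, best_score, best_train_idx)`` where
    ``pred_tie_idx`` indexes :data:`NNA_TIE_ORDER` and is -1 for
    unclassifiable queries. ``diag_offset`` excludes query *q* from its own
    neighbor pool at training index ``diag_offset + q`` (LOOCV).
    """
    nq, nt = Q.shape[0], T.shape[0]
    Qi = Q.astype(np.int64)
    Ti = T.astype(np.int64)
    D = Qi @ Ti.T
    qn2 = Qi.sum(axis=1)
    tn2 = Ti.sum(axis=1)
    denom = np.sqrt((qn2[:, None] * tn2[None, :]).astype(np.float64))
    safe = denom > 0
    sim = np.zeros((nq, nt))
    np.divide(D, denom, out=sim, where=safe)

    S = np.empty((nq, len(NNA_TIE_ORDER), nt))
    for p, cat in enumerate(NNA_TIE_ORDER):
        j = CATEGORIES.index(cat)
        SWint = Qi @ (Ti * w_int[:, j][None, :]).T
        S[:, p, :] = sim * (SWint / SCORE_SCALE)
        S[:, p, ~train_label_mask[:, j]] = -np.inf
    S[:, :, tn2 == 0] = -np.inf
    if diag_offset is not None:
        rows = np.arange(nq)
        cols = diag_offset + rows
        S[rows, :, cols] = -np.inf

    flat = S.reshape(nq, -1)
    best = flat.argmax(axis=1)
    best_val = flat[np.arange(nq), best]
    pred_p = (best // nt).astype(np.int64)
    pred_t = (best % nt).astype(np.int64)
    unclass = (qn2 == 0) | ~np.isfinite(best_val) | (best_val <= 0)
    pred_p[unclass] = -1
    pred_t[unclass] = -1
    best_val = np.where(unclass, np.nan, best_val)
    return pred_p, best_val, pred_t


def _nna_predict(
    Q: np.ndarray,
    T: np.ndarray,
    w_int: np.ndarray,
    train_label_mask: np.ndarray,
    loocv: bool = False,
    threads: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chunked NNA driver; results are independent of the chunking."""
    nq = Q.shape[0]
    chunk = max(1, math.ceil(nq / max(1, threads)))
    blocks = [(s, min(s + chunk, nq)) for s in range(0, nq, chunk)]

    def run(span: tuple[int, int]):
        s, e = span
        return _score_block(Q[s:e], T, w_int, train_label_mask, diag_offset=s if loocv else None)

    if threads > 1 and len(blocks) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            parts = list(pool.map(run, blocks))
    else:
        parts = [run(b) for b in blocks]
    pred_p = np.concatenate([p[0] for p in parts])
    best = np.concatenate([p[1] for p in parts])
    pred_t = np.concatenate([p[2] for p in parts])
    return pred_p, best, pred_t


@dataclass
class NNAPrediction:
    gene_id: str
    category: str | None
    best_score: float
    neighbor_id: str | None

    @property
    def tf_flag(self) -> bool:
        return self.category == "TFS"


def classify_nna(
    query: np.ndarray,
    train_matrix: np.ndarray,
    train_ids: Sequence[str],
    train_labels: Sequence[frozenset[str]],
    weights: WeightTable,
    selected: Sequence[int] | None = None,
    exclude_id: str | None = None,
) -> NNAPrediction:
    """Classify one query vector against the training set.

    ``selected`` restricts the feature coordinates (indices into the weight
    table's feature order); ``exclude_id`` omits one training sample (LOOCV).
    Training samples must be (and are checked to be) in ascending id order so
    that tie-breaking is well defined.
    """
    ids = list(train_ids)
    if ids != sorted(ids):
        raise InputError("training samples must be sorted by gene_id")
    sel = np.arange(train_matrix.shape[1]) if selected is None else np.asarray(selected, dtype=np.int64)
    Q = np.asarray(query, dtype=np.uint8)[None, sel]
    T = np.asarray(train_matrix, dtype=np.uint8)[:, sel]
    Y = _label_matrix(train_labels)
    if exclude_id is not None and exclude_id in ids:
        keep = [i for i, g in enumerate(ids) if g != exclude_id]
        T, Y = T[keep], Y[keep]
        ids = [ids[i] for i in keep]
    pred_p, best, pred_t = _score_block(Q, T, weights.w_int[sel], Y)
    if pred_p[0] < 0:
        return NNAPrediction("query", None, float("nan"), None)
    return NNAPrediction("query", NNA_TIE_ORDER[pred_p[0]], float(best[0]), ids[pred_t[0]])


# ---------------------------------------------------------------------------
# LOOCV top-k sweep
# ---------------------------------------------------------------------------

def default_k_grid(n_ranked: int) -> tuple[int, ...]:
    """Powers-of-two ladder up to the full pruned ranking, plus the full k."""
    ks: list[int] = []
    k = 1
    while k < n_ranked:
        ks.append(k)
        k *= 2
    if n_ranked >= 1:
        ks.append(n_ranked)
    return tuple(ks)


@dataclass
class LoocvResult:
    curve: pd.DataFrame
    best_k: int
    predictions: pd.DataFrame    # per-sample predictions at best_k


def _curve_row(
    k: int,
    pred_p: np.ndarray,
    truth_tf: np.ndarray,
    labels: Sequence[frozenset[str]],
) -> dict:
    pred_tf = pred_p == NNA_TIE_ORDER.index("TFS")
    conf = _metrics.confusion(pred_tf.tolist(), truth_tf.tolist())
    res = _metrics.compute_metrics(conf)
    fourway = sum(
        1 for p, cats in zip(pred_p, labels) if p >= 0 and NNA_TIE_ORDER[p] in cats
    ) / len(labels)
    row = {"k": k, "TP": conf.tp, "FP": conf.fp, "TN": conf.tn, "FN": conf.fn}
    row.update(res.as_dict())
    row["fourway_accuracy"] = fourway
    return row


def loocv(
    matrix: np.ndarray,
    gene_ids: Sequence[str],
    labels: Sequence[frozenset[str]],
    weights: WeightTable,
    ranking: MWDRanking,
    k_grid: Sequence[int] | None = None,
    threads: int = 1,
) -> LoocvResult:
    """Leave-one-out sweep over top-k feature cutoffs.

    Weights are estimated once on the full feature set and restricted to the
    top-k ranked features for each cutoff (per-feature statistics do not
    change under restriction, so this is exact). The best k maximizes the
    TF-vs-rest LOOCV accuracy; ties go to the smaller k. Samples must be in
    ascending gene_id order.
    """
    ids = list(gene_ids)
    if ids != sorted(ids):
        raise InputError("samples must be sorted by gene_id for LOOCV")
    if k_grid is None:
        k_grid = default_k_grid(len(ranking))
    k_grid = list(k_grid)
    if not k_grid:
        raise ConfigurationError("k_grid must not be empty")
    if max(k_grid) > len(ranking):
        raise ConfigurationError(
            f"k_grid value {max(k_grid)} exceeds ranking length {len(ranking)}"
        )
    Y = _label_matrix(labels)
    truth_tf = Y[:, CATEGORIES.index("TFS")]
    matrix = np.asarray(matrix, dtype=np.uint8)

    rows = []
    preds_by_k: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for k in sorted(set(int(k) for k in k_grid)):
        if k < 0:
            raise ConfigurationError("k must be >= 0")
        sel = ranking.order[:k]
        if k == 0:
            pred_p = np.full(len(ids), -1, dtype=np.int64)
            best = np.full(len(ids), np.nan)
            pred_t = np.full(len(ids), -1, dtype=np.int64)
        else:
            B = matrix[:, sel]
            pred_p, best, pred_t = _nna_predict(
                B, B, weights.w_int[sel], Y, loocv=True, threads=threads
            )
        preds_by_k[k] = (pred_p, best, pred_t)
        rows.append(_curve_row(k, pred_p, truth_tf, labels))
    curve = pd.DataFrame(rows)

    best_k = None
    best_acc = -np.inf
    for _, row in curve.iterrows():   # ascending k: strict > keeps smaller k on ties
        if row["accuracy"] > best_acc:
            best_acc = row["accuracy"]
            best_k = int(row["k"])
    pred_p, best, pred_t = preds_by_k[best_k]
    predictions = pd.DataFrame(
        {
            "gene_id": ids,
            "category": [NNA_TIE_ORDER[p] if p >= 0 else None for p in pred_p],
            "score": best,
            "neighbor": [ids[t] if t >= 0 else None for t in pred_t],
            "tf_flag": pred_p == NNA_TIE_ORDER.index("TFS"),
        }
    )
    return LoocvResult(curve, best_k, predictions)


# ---------------------------------------------------------------------------
# model objects (statsmodels-style Model / Results)
# ---------------------------------------------------------------------------

class SISModel:
    """Statistical-information-similarity classifier specification.

    Built from an :class:`~sistf.datatypes.AnnotatedGeneSet` and a
    ``gene_id -> categories`` mapping; :meth:`fit` runs the full training
    pipeline (encode, weight estimation, MWD ranking, LOOCV top-k sweep) and
    returns a :class:`SISResults`.
    """

    def __init__(self, geneset: AnnotatedGeneSet, labels: LabelMap):
        geneset = geneset.sorted_by_id()
        missing = [g for g in geneset.gene_ids if g not in labels]
        if missing:
            raise InputError(f"{len(missing)} gene(s) without labels, e.g. {missing[:3]}")
        self.geneset = geneset
        self.gene_ids, self.matrix = encode(geneset)
        self.labels = [frozenset(labels[g]) for g in self.gene_ids]
        self.feature_ids = geneset.feature_space.ids

    @classmethod
    def from_feature_table(cls, features: pd.DataFrame, labels: pd.DataFrame) -> "SISModel":
        """Build from the TSV-shaped frames (gene_id + comma-joined columns)."""
        feats = {
            str(r["gene_id"]): frozenset(str(r["features"]).split(","))
            for _, r in features.iterrows()
        }
        labs = {
            str(r["gene_id"]): frozenset(str(r["categories"]).split(","))
            for _, r in labels.iterrows()
        }
        return cls(AnnotatedGeneSet.from_mapping(feats), labs)

    def fit(
        self,
        k_grid: Sequence[int] | None = None,
        w_max: float = W_MAX_DEFAULT,
        threads: int = 1,
    ) -> "SISResults":
        weights = estimate_weights(self.matrix, self.labels, self.feature_ids, w_max=w_max)
        ranking = rank_features_mwd(weights)
        cv = loocv(self.matrix, self.gene_ids, self.labels, weights, ranking,
                   k_grid=k_grid, threads=threads)
        return SISResults(self, weights, ranking, cv)


class SISResults:
    """Fitted classifier bundle: weights, ranking, LOOCV curve, selection."""

    def __init__(self, model: SISModel, weights: WeightTable, ranking: MWDRanking,
                 cv: LoocvResult):
        self.model = model
        self.weights = weights
        self.ranking = ranking
        self.curve = cv.curve
        self.best_k = cv.best_k
        self.loocv_predictions = cv.predictions
        self.selected = ranking.order[: self.best_k]

    # -- introspection ------------------------------------------------------

    @property
    def selected_feature_ids(self) -> list[str]:
        return [self.weights.feature_ids[i] for i in self.selected]

    @property
    def best_row(self) -> pd.Series:
        return self.curve.loc[self.curve["k"] == self.best_k].iloc[0]

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        m = self.model
        counts = {c: sum(1 for l in m.labels if c in l) for c in CATEGORIES}
        b = self.best_row
        lines = [
            "Statistical information similarity classifier (NNA, LOOCV-selected features)",
            "=" * 76,
            f"Training samples: {len(m.gene_ids)}    Features: {len(m.feature_ids)}"
            f" (pruned: {len(self.ranking.pruned)}, ranked: {len(self.ranking)})",
            "Category sizes:   " + "  ".join(f"{c} {counts[c]}" for c in CATEGORIES),
            f"Selected top-k:   {self.best_k}",
            "",
            "LOOCV, TF vs rest, at the selected k:",
            f"  TP {int(b['TP'])}  FP {int(b['FP'])}  TN {int(b['TN'])}  FN {int(b['FN'])}",
            f"  sensitivity {b['sensitivity']:.4f}  specificity {b['specificity']:.4f}"
            f"  accuracy {b['accuracy']:.4f}",
            f"  precision {b['precision']:.4f}  MCC {b['mcc']:.4f}",
            f"  four-way accuracy {b['fourway_accuracy']:.4f}",
        ]
        return "\n".join(lines)

    # -- prediction ---------------------------------------------------------

    def predict(self, geneset: AnnotatedGeneSet | Mapping[str, Iterable[str]],
                threads: int = 1) -> pd.DataFrame:
        """Classify new genes against the full training set at the best k.

        Features outside the model's space are ignored; genes with no
        selected feature come back unclassifiable (category None, tf_flag
        False).
        """
        if isinstance(geneset, AnnotatedGeneSet):
            mapping = geneset.as_mapping()
        else:
            mapping = {g: frozenset(fs) for g, fs in geneset.items()}
        if not mapping:
            return pd.DataFrame(columns=["gene_id", "category", "score", "neighbor", "tf_flag"])
        qids = list(mapping)
        sel = self.selected
        sel_pos = {self.weights.feature_ids[i]: p for p, i in enumerate(sel)}
        Q = np.zeros((len(qids), len(sel)), dtype=np.uint8)
        for r, g in enumerate(qids):
            for f in mapping[g]:
                p = sel_pos.get(f)
                if p is not None:
                    Q[r, p] = 1
        T = self.model.matrix[:, sel]
        Y = _label_matrix(self.model.labels)
        pred_p, best, pred_t = _nna_predict(Q, T, self.weights.w_int[sel], Y, threads=threads)
        return pd.DataFrame(
            {
                "gene_id": qids,
                "category": [NNA_TIE_ORDER[p] if p >= 0 else None for p in pred_p],
                "score": best,
                "neighbor": [self.model.gene_ids[t] if t >= 0 else None for t in pred_t],
                "tf_flag": pred_p == NNA_TIE_ORDER.index("TFS"),
            }
        )

    # -- plotting -----------------------------------------------------------

    def plot_performance(self, ax=None):
        """LOOCV performance curve over the k grid (one line per measure)."""
        import matplotlib
        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt
            _, ax = plt.subplots(figsize=(6, 4))
        for col in ("sensitivity", "specificity", "accuracy", "precision", "mcc"):
            ax.plot(self.curve["k"], self.curve[col], marker="o", label=col)
        ax.axvline(self.best_k, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("top-k MWD-ranked features")
        ax.set_ylabel("LOOCV measure (TF vs rest)")
        ax.set_xscale("symlog")
        ax.legend(fontsize=8)
        return ax

    # -- serialization ------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write the model as flat text files under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = {
            "format": MODEL_FORMAT_VERSION,
            "categories": list(CATEGORIES),
            "n_features": len(self.weights.feature_ids),
            "best_k": int(self.best_k),
            "w_max": self.weights.w_max,
            "selected_feature_ids": self.selected_feature_ids,
            "ranked_feature_ids": self.ranking.ranked_feature_ids,
        }
        (outdir / "model.json").write_text(json.dumps(header, indent=1) + "\n")
        wdf = self.weights.to_frame()
        wdf.to_csv(outdir / "weights.tsv", sep="\t", index=False, float_format="%.17g")
        with open(outdir / "training.tsv", "w") as fh:
            fh.write("gene_id\tcategories\tfeatures\n")
            for gid, cats, row in zip(self.model.gene_ids, self.model.labels,
                                      self.model.matrix):
                feats = ",".join(
                    self.weights.feature_ids[i] for i in np.flatnonzero(row)
                )
                fh.write(f"{gid}\t{','.join(sorted(cats))}\t{feats}\n")
        self.curve.to_csv(outdir / "curve.tsv", sep="\t", index=False, float_format="%.12g")

    @classmethod
    def load(cls, outdir: str | Path) -> "SISResults":
        outdir = Path(outdir)
        header = json.loads((outdir / "model.json").read_text())
        if header.get("format") != MODEL_FORMAT_VERSION:
            raise InputError(f"unsupported model format {header.get('format')!r}")
        train = pd.read_csv(outdir / "training.tsv", sep="\t", dtype=str)
        feats = {r["gene_id"]: frozenset(r["features"].split(",")) for _, r in train.iterrows()}
        labels = {r["gene_id"]: frozenset(r["categories"].split(",")) for _, r in train.iterrows()}
        model = SISModel(AnnotatedGeneSet.from_mapping(feats), labels)
        weights = estimate_weights(model.matrix, model.labels, model.feature_ids,
                                   w_max=float(header["w_max"]))
        ranking = rank_features_mwd(weights)
        curve = pd.read_csv(outdir / "curve.tsv", sep="\t")
        best_k = int(header["best_k"])
        # LOOCV predictions are not persisted; recompute only the best-k row lazily.
        cv = LoocvResult(curve, best_k, pd.DataFrame())
        res = cls(model, weights, ranking, cv)
        if res.selected_feature_ids != header["selected_feature_ids"]:
            raise ConsistencyError("stored selected features disagree with recomputed ranking")
        return res
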