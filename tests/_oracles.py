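"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written as plain double loops over Python
scalars — no shared code with the package beyond the published constants
(category order, tie order, the dyadic weight-quantization scale that is
part of the scoring definition).
"""

from __future__ import annotations

import math

CATEGORIES = ("TFS", "MEM", "ENZ", "OTS")
NNA_TIE_ORDER = ("TFS", "ENZ", "MEM", "OTS")
SCORE_SCALE = 1 << 20


def naive_weights(bits, labels, w_max=1e6):
    """Brute-force counting implementation of the weight formulas.

    ``bits``: list of 0/1 lists; ``labels``: list of category sets.
    Returns (C, n_j, c_i, P, W) as nested Python lists/dicts.
    """
    m_total = len(bits)
    n_feat = len(bits[0]) if bits else 0
    n_j = [sum(1 for l in labels if cat in l) for cat in CATEGORIES]
    C = [[0] * len(CATEGORIES) for _ in range(n_feat)]
    for m in range(m_total):
        for j, cat in enumerate(CATEGORIES):
            if cat in labels[m]:
                for i in range(n_feat):
                    if bits[m][i]:
                        C[i][j] += 1
    c_i = [sum(C[i]) for i in range(n_feat)]
    P = [[0.0] * len(CATEGORIES) for _ in range(n_feat)]
    W = [[0.0] * len(CATEGORIES) for _ in range(n_feat)]
    for i in range(n_feat):
        for j in range(len(CATEGORIES)):
            if C[i][j] > 0:
                p = (float(C[i][j]) ** 2) / (float(n_j[j]) * float(c_i[i]))
                P[i][j] = p
                ic = -math.log2(p)
                W[i][j] = w_max if ic <= 0 else min(1.0 / ic, w_max)
    return C, n_j, c_i, P, W


def naive_mwd(W, feature_ids):
    """Rank by mutual weight difference; returns (ranked ids, mwd, pruned ids)."""
    rows = []
    pruned = []
    for i, fid in enumerate(feature_ids):
        ws = sorted(W[i], reverse=True)
        mwd = ws[0] - (ws[1] + ws[2] + ws[3]) / 3.0
        if ws[0] >= ws[1] + ws[2] + ws[3]:
            rows.append((fid, mwd))
        else:
            pruned.append(fid)
    rows.sort(key=lambda r: (-r[1], r[0]))
    return [r[0] for r in rows], [r[1] for r in rows], pruned


def naive_similarity(a, b):
    d = sum(x * y for x, y in zip(a, b))
    na = sum(a)
    nb = sum(b)
    return d / math.sqrt(na * nb)


def _quantize(w):
    return round(w * float(SCORE_SCALE))


def naive_score(a, b, W, category):
    j = CATEGORIES.index(category)
    swint = 0
    for k in range(len(a)):
        if a[k] and b[k]:
            swint += _quantize(W[k][j])
    return naive_similarity(a, b) * (float(swint) / SCORE_SCALE)


def naive_classify(q_bits, train_bits, train_ids, train_labels, W, exclude_idx=None):
    """Per-pair nearest-neighbor classification with explicit tie rules.

    Returns (category or None, best score or None, neighbor id or None).
    Training samples must be in ascending id order.
    """
    nq = sum(q_bits)
    best = -math.inf
    best_cat = None
    best_id = None
    if nq > 0:
        for cat in NNA_TIE_ORDER:
            for t in range(len(train_bits)):
                if t == exclude_idx:
                    continue
                if cat not in train_labels[t]:
                    continue
                if sum(train_bits[t]) == 0:
                    continue
                s = naive_score(q_bits, train_bits[t], W, cat)
                if s > best:
                    best = s
                    best_cat = cat
                    best_id = train_ids[t]
    if best_cat is None or best <= 0:
        return None, None, None
    return best_cat, best, best_id


def naive_metrics(tp, fp, tn, fn):
    out = {}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    out["accuracy"] = (tp + tn) / (tp + fp + tn + fn)
    out["precision"] = tp / (tp + fp) if tp + fp else math.nan
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return out


def naive_loocv_curve(bits, ids, labels, W, ranked_indices, k_grid):
    """Full O(M^2 N) LOOCV sweep; returns {k: (metrics row, predictions)}.

    ``predictions`` is a list of (category or None, neighbor id or None)
    per sample, in sample order.
    """
    out = {}
    for k in sorted(set(k_grid)):
        sel = ranked_indices[:k]
        sub = [[row[i] for i in sel] for row in bits]
        preds = []
        for m in range(len(sub)):
            cat, s, nid = naive_classify(sub[m], sub, ids, labels, [W[i] for i in sel],
                                         exclude_idx=m)
            preds.append((cat, s, nid))
        tp = fp = tn = fn = 0
        four = 0
        for (cat, _, _), labs in zip(preds, labels):
            pred_tf = cat == "TFS"
            true_tf = "TFS" in labs
            if pred_tf and true_tf:
                tp += 1
            elif pred_tf:
                fp += 1
            elif true_tf:
                fn += 1
            else:
                tn += 1
            if cat is not None and cat in labs:
                four += 1
        row = {"k": k, "TP": tp, "FP": fp, "TN": tn, "FN": fn}
        row.update(naive_metrics(tp, fp, tn, fn))
        row["fourway_accuracy"] = four / len(sub)
        out[k] = (row, preds)
    return out


def naive_best_k(curve_by_k):
    best_k, best_acc = None, -math.inf
    for k in sorted(curve_by_k):
        acc = curve_by_k[k][0]["accuracy"]
        if acc > best_acc:
            best_acc = acc
            best_k = k
    return best_k
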