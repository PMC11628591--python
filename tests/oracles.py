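"""Independent brute-force metric oracles used only by the tests.

Everything here is written as plain loops over pixels/thresholds, sharing no
code with the package implementation, so agreement is a genuine cross-check.
"""

import math

import numpy as np


def oracle_dsc(pred, gt, cls):
    p = 0
    g = 0
    both = 0
    for a, b in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        if a == cls:
            p += 1
        if b == cls:
            g += 1
        if a == cls and b == cls:
            both += 1
    if p + g == 0:
        return 1.0
    return 2.0 * both / (p + g)


def oracle_acc(pred, gt, cls):
    correct = 0
    total = 0
    for a, b in zip(np.asarray(pred).ravel(), np.asarray(gt).ravel()):
        total += 1
        if (a == cls) == (b == cls):
            correct += 1
    return correct / total


def oracle_weighted_acc(pred, gt, n_classes=5):
    gt = np.asarray(gt)
    total = gt.size
    out = 0.0
    for c in range(n_classes):
        share = int((gt == c).sum()) / total
        if share > 0:
            out += share * oracle_acc(pred, gt, c)
    return out


def _oracle_boundary(mask, cls):
    """Class pixels with a 4-neighbor of another class; off-image counts as
    another class."""
    mask = np.asarray(mask)
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] != cls:
                continue
            boundary = False
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or mask[ni, nj] != cls:
                    boundary = True
            if boundary:
                pts.append((i, j))
    return pts


def oracle_bf1(pred, gt, cls, tol):
    pb = _oracle_boundary(pred, cls)
    gb = _oracle_boundary(gt, cls)
    if not pb and not gb:
        return 1.0
    if not pb or not gb:
        return 0.0

    def match_frac(src, dst):
        hits = 0
        for (i, j) in src:
            dmin = min(math.hypot(i - a, j - b) for (a, b) in dst)
            if dmin <= tol:
                hits += 1
        return hits / len(src)

    precision = match_frac(pb, gb)
    recall = match_frac(gb, pb)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def oracle_ap(scores, labels):
    """Area under the precision-recall curve by threshold enumeration.

    Step-sum AP: sum over distinct thresholds (descending) of
    (recall_i - recall_{i-1}) * precision_i, with ties grouped.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n_pos = int(labels.sum())
    assert n_pos > 0
    thresholds = sorted(set(scores.tolist()), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        sel = scores >= t
        tp = int((labels & sel).sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
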