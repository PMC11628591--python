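"""Segmentation performance metrics and method-agreement statistics.

Segmentation side: per-class Dice similarity coefficient (DSC), one-vs-rest
pixel accuracy (ACC) with a pixel-share-weighted overall ACC, boundary F1
(bF1) within a pixel tolerance, and average precision (AP, area under the
pixel-ranking precision–recall curve) with its unweighted mean (mAP).

Agreement side, for comparing two infarct-size quantification routes:
Pearson correlation with least-squares regression, Bland–Altman bias with
±1.96·SD limits of agreement, an ANCOVA-style F-test of the regression line
against the line of identity, and a Kolmogorov–Smirnov normality check.

Conventions for degenerate classes: a class absent from both masks scores
DSC = 1 and bF1 = 1 (correct absence — e.g. infarct-free slices); absent
from exactly one mask scores 0.  A class with no positive ground-truth pixel
anywhere in the evaluation set is excluded from mAP with a warning.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import binary_erosion, distance_transform_edt
from sklearn.metrics import average_precision_score

from .scheme import CLASS_NAMES, N_CLASSES

__all__ = [
    "dsc", "acc", "weighted_acc", "boundary_f1",
    "average_precision", "mean_ap", "metrics_report", "MetricsReport",
    "pearson_linreg", "bland_altman", "ancova_identity", "ks_normality",
    "AgreementReport", "agreement_report",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dsc(pred: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """Dice similarity coefficient 2|P∩G| / (|P|+|G|) for one class."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    p = pred == cls
    g = gt == cls
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def acc(pred: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """One-vs-rest binary pixel accuracy (TP+TN)/total for one class."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    return float(np.mean((pred == cls) == (gt == cls)))


def weighted_acc(pred: np.ndarray, gt: np.ndarray) -> float:
    """Overall accuracy: per-class ACC weighted by ground-truth pixel share."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    total = gt.size
    out = 0.0
    for c in range(N_CLASSES):
        share = np.sum(gt == c) / total
        if share > 0:
            out += share * acc(pred, gt, c)
    return float(out)


def _boundary(binary: np.ndarray) -> np.ndarray:
    """Pixels of the region adjacent (4-connectivity) to a different class.

    The image border counts as "different", so a region touching the edge
    has boundary pixels there.
    """
    if not binary.any():
        return np.zeros_like(binary)
    interior = binary_erosion(
        binary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
        border_value=0,
    )
    return binary & ~interior


def boundary_f1(pred: np.ndarray, gt: np.ndarray, cls: int,
                tolerance_px: float = 2.0) -> float:
    """Boundary F1: harmonic mean of boundary precision and recall.

    A boundary pixel matches if it lies within ``tolerance_px`` (Euclidean)
    of any boundary pixel of the other mask.
    """
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    _check_shapes(pred, gt)
    if tolerance_px < 0:
        raise ValueError("tolerance must be >= 0")
    pb = _boundary(pred == cls)
    gb = _boundary(gt == cls)
    if not pb.any() and not gb.any():
        return 1.0
    if not pb.any() or not gb.any():
        return 0.0
    dist_to_g = distance_transform_edt(~gb)
    dist_to_p = distance_transform_edt(~pb)
    precision = np.mean(dist_to_g[pb] <= tolerance_px)
    recall = np.mean(dist_to_p[gb] <= tolerance_px)
    if precision + recall == 0:
        return 0.0
    return float(2 * precision * recall / (precision + recall))


def average_precision(probs: np.ndarray, gt: np.ndarray, cls: int) -> float:
    """Area under the pixel-ranking precision–recall curve for one class.

    ``probs`` holds the class-``cls`` probability per pixel (any shape
    aligned to ``gt``); pixels are pooled and ranked by that score.
    """
    probs = np.asarray(probs, dtype=float)
    gt = np.asarray(gt)
    _check_shapes(probs, gt)
    y = (gt == cls).ravel()
    if not y.any():
        raise ValueError(f"class {cls} has no positive pixel in the ground truth")
    return float(average_precision_score(y, probs.ravel()))


def mean_ap(prob_maps: np.ndarray, gt: np.ndarray) -> float:
    """Unweighted mean AP over the classes present in the ground truth.

    ``prob_maps`` is (C, ...) aligned with ``gt``; classes without any
    positive pixel are excluded with a warning.
    """
    prob_maps = np.asarray(prob_maps, dtype=float)
    gt = np.asarray(gt)
    aps = []
    for c in range(N_CLASSES):
        if not np.any(gt == c):
            warnings.warn(
                f"class {CLASS_NAMES[c]} absent from ground truth; excluded from mAP",
                stacklevel=2,
            )
            continue
        aps.append(average_precision(prob_maps[c], gt, c))
    if not aps:
        raise ValueError("no class has positive pixels; mAP undefined")
    return float(np.mean(aps))


@dataclasses.dataclass
class MetricsReport:
    """Per-class and overall segmentation metrics (Table-shaped)."""

    per_class: pd.DataFrame      # rows: 5 classes; columns DSC ACC bF1 AP
    overall_dsc: float
    weighted_acc: float
    overall_bf1: float
    map: float

    def to_frame(self) -> pd.DataFrame:
        overall = pd.DataFrame(
            [[self.overall_dsc, self.weighted_acc, self.overall_bf1, self.map]],
            index=["overall"], columns=["DSC", "ACC", "bF1", "AP"],
        )
        return pd.concat([self.per_class, overall])


def metrics_report(
    predictions,
    annotations,
    prob_maps=None,
    tolerance_px: float = 2.0,
) -> MetricsReport:
    """Full evaluation of a prediction set against its annotations.

    DSC, ACC and bF1 are computed per image and averaged; AP pools all
    pixels of the evaluation set before ranking (so rare classes are scored
    across the whole set, not per image).  When probability maps are not
    supplied, one-hot encodings of the predicted masks are ranked instead.

    Overall row: mean per-class DSC, pixel-share-weighted ACC (averaged over
    images), mean per-class bF1, and mAP.
    """
    predictions = list(predictions)
    annotations = list(annotations)
    if not predictions or len(predictions) != len(annotations):
        raise ValueError("need equally many (>=1) predictions and annotations")
    if prob_maps is None:
        prob_maps = [
            np.stack([(np.asarray(p) == c) for c in range(N_CLASSES)]).astype(float)
            for p in predictions
        ]
    else:
        prob_maps = list(prob_maps)

    per_image = {m: np.zeros((len(predictions), N_CLASSES))
                 for m in ("dsc", "acc", "bf1")}
    wacc = np.zeros(len(predictions))
    for i, (p, g) in enumerate(zip(predictions, annotations)):
        for c in range(N_CLASSES):
            per_image["dsc"][i, c] = dsc(p, g, c)
            per_image["acc"][i, c] = acc(p, g, c)
            per_image["bf1"][i, c] = boundary_f1(p, g, c, tolerance_px)
        wacc[i] = weighted_acc(p, g)

    pooled_gt = np.concatenate([np.asarray(g).ravel() for g in annotations])
    ap = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        if np.any(pooled_gt == c):
            pooled_scores = np.concatenate(
                [np.asarray(m[c], dtype=float).ravel() for m in prob_maps])
            ap[c] = average_precision_score(pooled_gt == c, pooled_scores)
        else:
            warnings.warn(
                f"class {CLASS_NAMES[c]} absent from the evaluation set",
                stacklevel=2,
            )

    per_class = pd.DataFrame(
        {
            "DSC": per_image["dsc"].mean(axis=0),
            "ACC": per_image["acc"].mean(axis=0),
            "bF1": per_image["bf1"].mean(axis=0),
            "AP": ap,
        },
        index=list(CLASS_NAMES),
    )
    return MetricsReport(
        per_class=per_class,
        overall_dsc=float(per_class["DSC"].mean()),
        weighted_acc=float(wacc.mean()),
        overall_bf1=float(per_class["bF1"].mean()),
        map=float(np.nanmean(ap)),
    )


# -- agreement statistics -----------------------------------------------------

def pearson_linreg(x, y) -> tuple[float, float, float]:
    """Pearson r plus least-squares slope and intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def bland_altman(method_a, method_b) -> tuple[float, float, float]:
    """Bias and ±1.96·SD limits of agreement of paired differences a − b.

    Returns ``(bias, loa_low, loa_high)``; SD is the sample standard
    deviation (n − 1).
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired methods must have equal length")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def ancova_identity(x, y) -> tuple[float, float]:
    """F-test of the regression line of y on x against the identity line.

    Extra-sum-of-squares comparison of the fixed model y = x (0 free
    parameters) with the fitted line (2 parameters):
    ``F = ((SSE_id − SSE_fit)/2) / (SSE_fit/(n−2))``.  A perfect identity
    fit returns the fail-to-reject sentinel p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    sse_id = float(np.sum((y - x) ** 2))
    scale = max(float(np.sum(y**2)), 1.0)
    if sse_id <= 1e-12 * scale:
        return 0.0, 1.0
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    sse_fit = float(np.sum(resid**2))
    dof = x.size - 2
    if sse_fit <= 1e-12 * scale:
        return float("inf"), 0.0
    f_stat = ((sse_id - sse_fit) / 2.0) / (sse_fit / dof)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 2, dof))
    return float(f_stat), p


def ks_normality(sample) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Parameters are estimated from the data (Lilliefors caveat: the p-value
    is anti-conservative); SD uses n − 1.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), float(np.std(x, ddof=1))))
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class AgreementReport:
    """Agreement between two IS quantification methods (a vs b)."""

    n: int
    r: float
    slope: float
    intercept: float
    bias: float
    loa_low: float
    loa_high: float
    ancova_f: float
    ancova_p: float
    ks_p_a: float
    ks_p_b: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def agreement_report(method_a, method_b) -> AgreementReport:
    """Assemble the full agreement panel for two paired IS series."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    r, slope, intercept = pearson_linreg(b, a)
    bias, lo, hi = bland_altman(a, b)
    f_stat, p = ancova_identity(b, a)
    try:
        _, ks_a = ks_normality(a)
        _, ks_b = ks_normality(b)
    except ValueError:
        ks_a = ks_b = float("nan")
    return AgreementReport(
        n=int(a.size), r=r, slope=slope, intercept=intercept,
        bias=bias, loa_low=lo, loa_high=hi,
        ancova_f=f_stat, ancova_p=p, ks_p_a=ks_a, ks_p_b=ks_b,
    )
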