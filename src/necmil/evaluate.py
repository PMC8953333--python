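"""Evaluation surfaces: ROC/PR curves, confusion matrices, threshold sweeps,
cumulative detection curves, Gaussian KDE and two-sample KS comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from necmil.trajectory import RiskTrajectory, classify_risk, lead_time

__all__ = [
    "Curve",
    "DensityEstimate",
    "ConfusionRates",
    "roc_pr",
    "confusion_and_rates",
    "threshold_sweep",
    "cumulative_detection",
    "silverman_bandwidth",
    "kde_gaussian",
    "ks_two_sample",
]


@dataclass
class Curve:
    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray
    auc: float


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass
class ConfusionRates:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]


def roc_pr(scores: Sequence[float], labels: Sequence[int]) -> Tuple[Curve, Curve]:
    """ROC and precision-recall curves with trapezoidal AUCs.

    The ROC AUC equals the tie-corrected rank statistic; the PR curve uses
    the precision = 1 at recall = 0 convention.  Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/PR need both classes present")
    fpr, tpr, thr = skm.roc_curve(labels, scores)
    roc = Curve(thresholds=thr, x=fpr, y=tpr, auc=float(skm.auc(fpr, tpr)))
    prec, rec, pthr = skm.precision_recall_curve(labels, scores)
    # sklearn returns recall descending, ending at (recall 0, precision 1);
    # keep the attainable envelope (best precision per recall) for the
    # trapezoid so dominated operating points do not deflate the area
    order = np.argsort(rec, kind="mergesort")
    r_sorted, p_sorted = rec[order], prec[order]
    uniq, inverse = np.unique(r_sorted, return_inverse=True)
    envelope = np.zeros_like(uniq)
    np.maximum.at(envelope, inverse, p_sorted)
    pr_auc = float(np.trapezoid(envelope, uniq))
    pr = Curve(thresholds=pthr, x=rec, y=prec, auc=pr_auc)
    return roc, pr


def confusion_and_rates(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionRates:
    """Confusion counts plus sensitivity/specificity (absent on 0 denominators)."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum((p == 1) & (y == 1)))
    fp = int(np.sum((p == 1) & (y == 0)))
    tn = int(np.sum((p == 0) & (y == 0)))
    fn = int(np.sum((p == 0) & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return ConfusionRates(tp, fp, tn, fn, sens, spec)


def threshold_sweep(
    trajectories: Sequence[RiskTrajectory],
    grid: Sequence[float],
) -> Tuple[pd.DataFrame, float]:
    """Sensitivity/specificity/mean lead time over a grid of risk cutoffs.

    Returns the table and the cutoff maximizing balanced accuracy
    (ties broken toward the lower cutoff).  Lead times are averaged over
    true positives with non-negative lead only.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    labels = np.array([t.label for t in trajectories])
    rows = []
    for cutoff in grid:
        preds, leads = [], []
        for t in trajectories:
            pred, crossing = classify_risk(t, cutoff)
            preds.append(pred)
            if pred == 1 and t.label == 1:
                lt = lead_time(crossing, t.onset_day)
                if lt is not None and lt >= 0:
                    leads.append(lt)
        cm = confusion_and_rates(np.array(preds), labels)
        sens = cm.sensitivity if cm.sensitivity is not None else np.nan
        spec = cm.specificity if cm.specificity is not None else np.nan
        rows.append({
            "cutoff": cutoff,
            "sensitivity": sens,
            "specificity": spec,
            "balanced_accuracy": np.nanmean([sens, spec]),
            "mean_lead_time": float(np.mean(leads)) if leads else np.nan,
            "n_lead": len(leads),
        })
    df = pd.DataFrame(rows)
    best = float(df.loc[df["balanced_accuracy"].idxmax(), "cutoff"])
    return df, best


def cumulative_detection(
    trajectories: Sequence[RiskTrajectory],
    cutoff: float = 0.35,
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-group fraction of patients whose risk first crossed ``cutoff`` by day d.

    Returns, for groups "affected" and "unaffected", a (days, fraction)
    step function; fractions are nondecreasing and bounded by 1.
    """
    crossings: Dict[str, List[Optional[int]]] = {"affected": [], "unaffected": []}
    for t in trajectories:
        _, day = classify_risk(t, cutoff)
        crossings["affected" if t.label == 1 else "unaffected"].append(day)
    out = {}
    for group, days in crossings.items():
        n = len(days)
        observed = sorted(d for d in days if d is not None)
        grid = np.unique(observed) if observed else np.array([0.0])
        frac = np.array([sum(d <= g for d in observed) / n for g in grid]) if n else np.array([0.0])
        out[group] = (grid.astype(float), frac)
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 1.0
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.34
    scale = min(s for s in (sd, iqr) if s > 0) if (sd > 0 or iqr > 0) else 1.0
    return float(0.9 * scale * n ** (-0.2))


def kde_gaussian(
    values: Sequence[float],
    bandwidth: Optional[float] = None,
    grid: Optional[np.ndarray] = None,
) -> DensityEstimate:
    """Gaussian kernel density estimate f(x) = (1/nh) sum K((x - x_i)/h).

    ``bandwidth`` defaults to Silverman's rule; ``grid`` defaults to 512
    points spanning the data +/- 5 bandwidths (over which the density
    integrates to 1 up to quadrature error).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        grid = np.linspace(x.min() - 5 * h, x.max() + 5 * h, 512)
    grid = np.asarray(grid, dtype=float)
    dens = stats.norm.pdf((grid[:, None] - x[None, :]) / h).sum(axis=1) / (len(x) * h)
    return DensityEstimate(grid=grid, density=dens, bandwidth=h)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a - ECDF_b|.

    Applied to the underlying sample values (the distributions a kernel
    density plot depicts), with the asymptotic p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs nonempty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
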