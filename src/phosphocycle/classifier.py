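"""miRNA cell-classifier evaluation.

Sensitivity/specificity/accuracy of a threshold classifier on per-cell
output fluorescence, ROC curves over a fixed threshold schedule with
trapezoidal AUC, the bi-normal ROC model (negative class N(0,1),
positive class N(mu2, sigma2^2)) with its closed-form AUC
Phi(mu2 / sqrt(1 + sigma2^2)), the biexponential (arcsinh-like)
fluorescence transform, and the component-ratio trajectory scan that
locates the kinase:phosphatase:output plasmid ratio maximising
classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import least_squares
from scipy.stats import norm

__all__ = [
    "ROCCurve",
    "BinormalFit",
    "RatioScanResult",
    "classification_metrics",
    "roc_thresholds",
    "roc_curve",
    "auc_trapezoid",
    "fit_binormal",
    "binormal_auc",
    "biexponential",
    "trajectory_points",
    "ratio_scan",
    "default_ratio_grid",
]


# ---------------------------------------------------------------------------
# Threshold metrics and ROC
# ---------------------------------------------------------------------------

def _values(events, channel):
    if isinstance(events, pd.DataFrame):
        return events[channel].to_numpy(dtype=float)
    return np.asarray(events, dtype=float)


def classification_metrics(pos_events, neg_events, channel: str | None = None,
                           threshold: float = 0.0) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) at one threshold.

    Sensitivity is the percent of positive-class cells above the
    threshold; specificity is 100 minus the percent of negative-class
    cells above it; accuracy is their arithmetic mean.  Inputs are value
    arrays or event tables with ``channel``.
    """
    pos = _values(pos_events, channel)
    neg = _values(neg_events, channel)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both populations must be non-empty")
    sens = 100.0 * np.mean(pos > threshold)
    spec = 100.0 - 100.0 * np.mean(neg > threshold)
    return float(sens), float(spec), float((sens + spec) / 2.0)


def roc_thresholds() -> np.ndarray:
    """The fixed 17-value threshold schedule.

    -1e8, then 0, then 15 log-spaced values from 1e3 to 1e8 inclusive
    (steps of 5/14 dex).
    """
    return np.concatenate(([-1e8, 0.0], np.logspace(3.0, 8.0, 15)))


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float = np.nan


def auc_trapezoid(fpr, tpr) -> float:
    """Trapezoidal AUC over points sorted by FPR, anchored at (0,0), (1,1)."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    order = np.lexsort((tpr, fpr))  # FPR ascending, ties by TPR
    x = np.concatenate(([0.0], fpr[order], [1.0]))
    y = np.concatenate(([0.0], tpr[order], [1.0]))
    return float(np.trapezoid(y, x))


def roc_curve(pos_events, neg_events, channel: str | None = None) -> ROCCurve:
    """ROC over the fixed threshold schedule with trapezoidal AUC."""
    pos = _values(pos_events, channel)
    neg = _values(neg_events, channel)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both populations must be non-empty")
    thr = roc_thresholds()
    tpr = np.array([np.mean(pos > t) for t in thr])
    fpr = np.array([np.mean(neg > t) for t in thr])
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc_trapezoid(fpr, tpr))


# ---------------------------------------------------------------------------
# Bi-normal ROC model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinormalFit:
    """Positive-class parameters of the bi-normal ROC model.

    The negative class is fixed at the standard normal (mu1 = 0,
    sigma1 = 1); TPR(FPR) = Phi((mu2 + Phi^-1(FPR)) / sigma2).
    """

    mu2: float
    sigma2: float
    auc_closed_form: float


def binormal_auc(mu2: float, sigma2: float) -> float:
    """Closed-form AUC of the bi-normal model: Phi(mu2 / sqrt(1 + sigma2^2))."""
    return float(norm.cdf(mu2 / np.sqrt(1.0 + sigma2**2)))


def binormal_tpr(fpr, mu2: float, sigma2: float):
    fpr = np.asarray(fpr, dtype=float)
    return norm.cdf((mu2 + norm.ppf(fpr)) / sigma2)


def fit_binormal(curve: ROCCurve) -> BinormalFit:
    """Least-squares bi-normal fit to the interior (FPR, TPR) points.

    Endpoints with FPR in {0, 1} are excluded (infinite probit values);
    at least 3 interior points are required.  The fit minimises squared
    TPR residuals over (mu2, log sigma2).
    """
    interior = (curve.fpr > 0.0) & (curve.fpr < 1.0)
    if interior.sum() < 3:
        raise ValueError("need >= 3 interior ROC points with 0 < FPR < 1")
    fpr = curve.fpr[interior]
    tpr = np.clip(curve.tpr[interior], 0.0, 1.0)

    def resid(p):
        mu2, log_s2 = p
        return binormal_tpr(fpr, mu2, np.exp(log_s2)) - tpr

    best = None
    for mu0 in (0.5, 1.0, 2.0, 4.0):
        res = least_squares(resid, [mu0, 0.0], xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    mu2, sigma2 = float(best.x[0]), float(np.exp(best.x[1]))
    return BinormalFit(mu2=mu2, sigma2=sigma2, auc_closed_form=binormal_auc(mu2, sigma2))


def binormal_auc_quadrature(mu2: float, sigma2: float) -> float:
    """AUC by numerical integration of the bi-normal ROC (oracle for tests)."""
    val, _ = quad(lambda f: binormal_tpr(f, mu2, sigma2), 0.0, 1.0, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Biexponential transform and ratio-trajectory scan
# ---------------------------------------------------------------------------

DEFAULT_BIEXP_WIDTH = 150.0  # MEFL


def biexponential(x, width: float = DEFAULT_BIEXP_WIDTH):
    """Arcsinh-based biexponential transform, b(x) = asinh(x/(2w)) / ln 10.

    Odd in x, approximately linear near zero and log10(x / width) for
    x >> width, so distances in transformed units behave like decades of
    fluorescence for bright cells while tolerating negative values.
    """
    if not width > 0:
        raise ValueError("width must be > 0")
    x = np.asarray(x, dtype=float)
    out = np.arcsinh(x / (2.0 * width)) / np.log(10.0)
    return out if out.ndim else float(out)


def default_ratio_grid() -> np.ndarray:
    """Powers of 2 from ~1024:1 down to 1:1024 ("roughly halving" steps)."""
    return 2.0 ** np.arange(10, -11, -1)


def trajectory_points(
    component_weights: Sequence[float],
    width: float = DEFAULT_BIEXP_WIDTH,
    t_range: tuple[float, float] = (1e2, 1e7),
    n_points: int = 120,
) -> np.ndarray:
    """Biexponential-transformed dosage trajectory for one component ratio.

    Parametrises the ray of per-cell total dosage t scaled by the
    component weights (one per marker channel), transformed channel-wise;
    the result is an (n_points x n_channels) polyline.
    """
    w = np.asarray(component_weights, dtype=float)
    t = np.logspace(np.log10(t_range[0]), np.log10(t_range[1]), n_points)
    return biexponential(t[:, None] * w[None, :], width)


@dataclass(frozen=True)
class RatioScanResult:
    ratios: np.ndarray = field(repr=False)  # (n_combos, n_ratio_dims)
    accuracy: np.ndarray = field(repr=False)  # percent, NaN where undefined
    n_selected_pos: np.ndarray = field(repr=False)
    n_selected_neg: np.ndarray = field(repr=False)
    best_index: int = -1
    trajectory_width: float = 0.25

    @property
    def best_ratio(self) -> np.ndarray:
        return self.ratios[self.best_index]

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy[self.best_index])


def _select_near_trajectory(transformed: np.ndarray, traj: np.ndarray, width: float) -> np.ndarray:
    """Cells whose transformed marker vector is within ``width`` of the polyline."""
    # squared distances cell x trajectory-point, min over points
    d2 = ((transformed[:, None, :] - traj[None, :, :]) ** 2).sum(axis=2)
    return d2.min(axis=1) <= width**2


def ratio_scan(
    pos_events: pd.DataFrame,
    neg_events: pd.DataFrame,
    marker_channels: Sequence[str],
    output_channel: str,
    threshold: float = 1e3,
    trajectory_width: float = 0.25,
    kp_ratios: np.ndarray | None = None,
    output_ratios: np.ndarray | None = None,
    biexp_width: float = DEFAULT_BIEXP_WIDTH,
    t_range: tuple[float, float] = (1e2, 1e7),
) -> RatioScanResult:
    """Scan kinase:phosphatase (and output) plasmid ratios for accuracy.

    For each candidate ratio, cells of both classes whose
    biexponential-transformed marker vectors lie within
    ``trajectory_width`` (Euclidean, in biexponential units) of the
    dosage trajectory set by the ratio are selected, and classification
    accuracy at ``threshold`` on the output channel is computed on the
    subsample.  Ratios where either selected class is empty are excluded
    from the argmax.

    With two marker channels the ratio is K:P; with three, the grid is
    the product of K:P ratios and output:(K/P) ratios (weights
    (r, 1, r_out)).
    """
    marker_channels = list(marker_channels)
    if len(marker_channels) < 2:
        raise ValueError("need >= 2 marker channels")
    kp = default_ratio_grid() if kp_ratios is None else np.asarray(kp_ratios, float)
    if len(marker_channels) >= 3:
        out_r = (default_ratio_grid() if output_ratios is None
                 else np.asarray(output_ratios, float))
        combos = [(r1, r2) for r1 in kp for r2 in out_r]
    else:
        combos = [(r1,) for r1 in kp]

    tp = biexponential(pos_events[marker_channels].to_numpy(dtype=float), biexp_width)
    tn = biexponential(neg_events[marker_channels].to_numpy(dtype=float), biexp_width)
    vp = pos_events[output_channel].to_numpy(dtype=float)
    vn = neg_events[output_channel].to_numpy(dtype=float)

    acc = np.full(len(combos), np.nan)
    n_pos = np.zeros(len(combos), dtype=int)
    n_neg = np.zeros(len(combos), dtype=int)
    for i, combo in enumerate(combos):
        if len(combo) == 1:
            weights = [combo[0], 1.0]
        else:
            weights = [combo[0], 1.0, combo[1]]
        traj = trajectory_points(weights, biexp_width, t_range)
        mp = _select_near_trajectory(tp, traj, trajectory_width)
        mn = _select_near_trajectory(tn, traj, trajectory_width)
        n_pos[i], n_neg[i] = int(mp.sum()), int(mn.sum())
        if n_pos[i] == 0 or n_neg[i] == 0:
            continue
        _, _, acc[i] = classification_metrics(vp[mp], vn[mn], threshold=threshold)

    if np.all(np.isnan(acc)):
        raise ValueError("no ratio yielded a non-empty subsample in both classes")
    best = int(np.nanargmax(acc))
    return RatioScanResult(
        ratios=np.asarray(combos, dtype=float),
        accuracy=acc,
        n_selected_pos=n_pos,
        n_selected_neg=n_neg,
        best_index=best,
        trajectory_width=trajectory_width,
    )
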