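"""Hill dose-response curves and least-squares fitting.

Dose-response of OmpR-VP64-driven output to a kinase (activation) or a
phosphatase (deactivation) is modelled with Hill functions of fixed
cooperativity n = 2 (phosphorylated OmpR binds DNA as a dimer):

    activation:  y = a0 + (a - a0) * x^2 / (K^2 + x^2)
    repression:  y = a0 + (a - a0) * K^2 / (K^2 + x^2)

Fits minimise the sum of squared residuals on the linear output scale.
Goodness of fit is reported as CV(RMSE) in two labelled variants:
sqrt((1/ybar) * sum r^2) / ybar, a normalisation seen in existing
analysis toolkits and kept as the primary value for comparability, and
the conventional normalised RMSE, sqrt((1/n) * sum r^2) / ybar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HillFit",
    "FitQuality",
    "hill_activation",
    "hill_repression",
    "fit_hill",
    "cv_rmse",
]

HILL_N = 2.0


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters: basal a0, maximal a, half-effect K, n = 2."""

    alpha0: float
    alpha: float
    K_half: float
    mode: str  # "activation" | "repression"
    n: float = HILL_N
    identifiable: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "repression"):
            raise ValueError(f"mode must be activation|repression, got {self.mode!r}")
        if not self.K_half > 0:
            raise ValueError("K_half must be > 0")

    def __call__(self, x):
        if self.mode == "activation":
            return hill_activation(x, self)
        return hill_repression(x, self)


@dataclass(frozen=True)
class FitQuality:
    """CV(RMSE) in both conventions, plus residuals (y - f)."""

    cv_rmse_printed: float
    cv_rmse_conventional: float
    residuals: np.ndarray = field(repr=False, default=None)


def hill_activation(x, fit: HillFit):
    """y = a0 + (a - a0) x^2/(K^2 + x^2); nondecreasing in x >= 0."""
    x = np.asarray(x, dtype=float)
    y = fit.alpha0 + (fit.alpha - fit.alpha0) * x**2 / (fit.K_half**2 + x**2)
    return y if y.ndim else float(y)


def hill_repression(x, fit: HillFit):
    """y = a0 + (a - a0) K^2/(K^2 + x^2); nonincreasing in x >= 0."""
    x = np.asarray(x, dtype=float)
    y = fit.alpha0 + (fit.alpha - fit.alpha0) * fit.K_half**2 / (fit.K_half**2 + x**2)
    return y if y.ndim else float(y)


def cv_rmse(y, f) -> FitQuality:
    """Normalised root-mean-square error of fit f against data y.

    ``cv_rmse_printed`` uses 1/ybar inside the root (the normalisation
    some analysis toolkits report, kept verbatim for comparability);
    ``cv_rmse_conventional`` uses the standard 1/n.  Requires ybar > 0.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or y.size < 1:
        raise ValueError("y and f must be same-length, non-empty vectors")
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError(f"mean of y must be > 0, got {ybar!r}")
    resid = y - f
    ss = float(np.sum(resid**2))
    return FitQuality(
        cv_rmse_printed=float(np.sqrt(ss / ybar) / ybar),
        cv_rmse_conventional=float(np.sqrt(ss / y.size) / ybar),
        residuals=resid,
    )


def _hill_model(params, x, mode):
    a0, a, K = params
    fit = HillFit(alpha0=a0, alpha=a, K_half=max(K, 1e-300), mode=mode)
    return fit(x)


def fit_hill(x, y, mode: str = "activation") -> tuple[HillFit, FitQuality]:
    """Least-squares Hill fit with n pinned at 2, multi-start in K.

    Non-positive y values are excluded with a warning (mirroring the
    flow-pipeline discard rule); at least 4 usable points are required.
    Initialisation: a0 = min(y), a = max(y), K = geometric mean of the
    positive doses, with 5 starts jittered over +/- 0.5 dex in K.  When
    the data carry no dose-dependence the fit degenerates to a flat line
    and ``identifiable`` is False.
    """
    if mode not in ("activation", "repression"):
        raise ValueError(f"mode must be activation|repression, got {mode!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y) & (x >= 0)
    npos = keep & (y > 0)
    if npos.sum() < keep.sum():
        warnings.warn(
            f"excluding {int(keep.sum() - npos.sum())} non-positive y values from fit",
            stacklevel=2,
        )
    x, y = x[npos], y[npos]
    if x.size < 4:
        raise ValueError(f"need >= 4 usable (x, y) pairs, have {x.size}")

    a0_init = float(y.min())
    a_init = float(y.max())
    xpos = x[x > 0]
    K_init = float(np.exp(np.mean(np.log(xpos)))) if xpos.size else 1.0

    yspan = a_init - a0_init
    if yspan == 0.0:
        # plateau-only data: alpha = alpha0, K unidentifiable
        fit = HillFit(alpha0=a0_init, alpha=a_init, K_half=K_init, mode=mode,
                      identifiable=False)
        return fit, cv_rmse(y, fit(x))

    best = None
    for jitter in (-0.5, -0.25, 0.0, 0.25, 0.5):
        p0 = np.array([a0_init, a_init, K_init * 10.0**jitter])
        try:
            res = least_squares(
                lambda p: _hill_model(p, x, mode) - y,
                p0,
                bounds=([0.0, 0.0, 1e-12 * K_init], [np.inf, np.inf, 1e12 * K_init]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("Hill fit failed from every start")

    a0_hat, a_hat, K_hat = best.x
    # K is unidentifiable when the fitted transition sits entirely outside
    # the sampled dose range or the fitted amplitude collapsed
    identifiable = (
        abs(a_hat - a0_hat) > 1e-9 * max(abs(a_hat), 1.0)
        and xpos.min() / 10 <= K_hat <= xpos.max() * 10
    )
    fit = HillFit(alpha0=float(a0_hat), alpha=float(a_hat), K_half=float(K_hat),
                  mode=mode, identifiable=bool(identifiable))
    return fit, cv_rmse(y, fit(x))
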