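"""Hill dose-response models of islet hormone secretion and correlations.

Islet insulin content serves as a surrogate for beta-cell mass. Glucagon
secretion at low glucose rises sigmoidally with content (positive Hill
coefficient), somatostatin secretion falls (negative Hill coefficient), and
the two are negatively correlated across islet groups. The canonical model is

    y(x) = A / (1 + (EC50 / x)^h)

with amplitude ``A`` (asymptotic secretion, arbitrary units), half-maximal
content ``EC50`` (nmol per islet group) and Hill coefficient ``h`` whose sign
sets the direction: h > 0 gives a curve increasing in content (glucagon-type),
h < 0 a decreasing one (somatostatin-type). At x = EC50 the model evaluates to
A/2 for any h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class HillModel:
    """Hill dose-response model y = A / (1 + (EC50/x)^h)."""

    amplitude: float
    ec50: float
    h: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.h == 0:
            raise ValueError("Hill coefficient must be nonzero")


@dataclass(frozen=True)
class HillFitResult:
    """Nonlinear least-squares fit of a :class:`HillModel`.

    ``stderr`` holds the standard errors of (amplitude, ec50, h) from the
    local quadratic approximation (Jacobian-based covariance) at the optimum.
    """

    model: HillModel
    stderr: tuple[float, float, float]
    rss: float
    converged: bool
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the least-squares line."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def hill_eval(model: HillModel, content) -> np.ndarray | float:
    """Evaluate the Hill model at the given insulin content (> 0, nmol)."""
    x = np.asarray(content, dtype=float)
    if np.any(x <= 0):
        raise ValueError("insulin content must be positive")
    y = model.amplitude / (1.0 + (model.ec50 / x) ** model.h)
    return float(y) if np.isscalar(content) else y


def _hill_curve(x, a, ec50, h):
    return a / (1.0 + (ec50 / x) ** h)


def fit_hill(
    content,
    secretion,
    init: HillModel | None = None,
    bounds: tuple | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> HillFitResult:
    """Fit a Hill model to secretion-versus-content data.

    Minimises the residual sum of squares with ``scipy.optimize.curve_fit``
    from multiple jittered starting points (local minima are common when the
    data barely span the EC50). The default initialisation sets the amplitude
    to max(y), the EC50 to the median content, and the sign of h from the
    observed monotonic trend.

    Parameters
    ----------
    content, secretion:
        Matched 1-D arrays; content strictly positive.
    init:
        Optional explicit starting model; jittered starts are added around it.
    bounds:
        ``(lower, upper)`` triples for (A, EC50, h); defaults keep A and EC50
        positive and h sign-free.
    """
    x = np.asarray(content, dtype=float)
    y = np.asarray(secretion, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("content and secretion must be matched 1-D arrays")
    if len(x) < 4:
        raise ValueError("need at least 4 points to fit three parameters")
    if np.any(x <= 0):
        raise ValueError("insulin content must be positive")
    if np.ptp(y) == 0:
        return HillFitResult(
            model=HillModel(max(float(y[0]), 1e-12) or 1e-12, float(np.median(x)), 1.0),
            stderr=(np.inf, np.inf, np.inf),
            rss=0.0,
            converged=False,
            n=len(x),
        )

    if init is None:
        # slope of y against log-content fixes the sign of h
        trend = np.polyfit(np.log(x), y, 1)[0]
        init = HillModel(
            amplitude=max(float(np.max(y)), 1e-9),
            ec50=float(np.median(x)),
            h=1.0 if trend >= 0 else -1.0,
        )
    if bounds is None:
        bounds = ([1e-12, 1e-12, -50.0], [np.inf, np.inf, 50.0])

    rng = np.random.default_rng(seed)
    p0s = [(init.amplitude, init.ec50, init.h)]
    for _ in range(max(n_starts - 1, 0)):
        p0s.append(
            (
                init.amplitude * np.exp(rng.normal(0, 0.3)),
                init.ec50 * np.exp(rng.normal(0, 0.5)),
                init.h * np.exp(rng.normal(0, 0.3)),
            )
        )

    best = None
    for p0 in p0s:
        try:
            popt, pcov = optimize.curve_fit(
                _hill_curve, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        rss = float(np.sum((y - _hill_curve(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        return HillFitResult(
            model=init, stderr=(np.inf,) * 3, rss=np.inf, converged=False, n=len(x)
        )
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return HillFitResult(
        model=HillModel(float(popt[0]), float(popt[1]), float(popt[2])),
        stderr=tuple(float(s) for s in se),
        rss=rss,
        converged=True,
        n=len(x),
    )


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation and least-squares line between two secretion series.

    The two-sided p-value uses the exact t-transform of r under the null of
    bivariate normal independence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need matched 1-D arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.linregress(x, y)
    return CorrelationResult(
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
    )
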