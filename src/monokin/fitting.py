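"""Curve families used to summarize protocol outputs.

Rectangular hyperbola (concentration–response), Boltzmann sigmoid
(voltage dependence), straight line, and mono-exponential recovery, plus a
nested-model F-test for comparing line fits and normalization helpers.

All fitters are deterministic: initial values follow fixed rules derived
from the data (no random restarts), so identical inputs give identical
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "HyperbolaFit",
    "BoltzmannFit",
    "LineFit",
    "MonoExpFit",
    "FTestResult",
    "fit_hyperbola",
    "fit_boltzmann",
    "fit_line",
    "fit_monoexp",
    "compare_lines_ftest",
    "normalize_to_reference",
]


def _residual_summary(y: np.ndarray, y_hat: np.ndarray) -> dict:
    resid = y - y_hat
    return {
        "rss": float(np.sum(resid**2)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n": int(y.size),
    }


@dataclass
class HyperbolaFit:
    """y = Ymax·x / (x + K_M)."""

    Ymax: float
    K_M: float
    stderr: dict[str, float] = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)

    def predict(self, x):
        x = np.asarray(x, float)
        return self.Ymax * x / (x + self.K_M)


@dataclass
class BoltzmannFit:
    """y = Bottom + (Top − Bottom) / (1 + exp((V50 − x)/Slope))."""

    Top: float
    Bottom: float
    V50: float
    Slope: float
    stderr: dict[str, float] = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def predict(self, x):
        x = np.asarray(x, float)
        return self.Bottom + (self.Top - self.Bottom) / (
            1.0 + np.exp((self.V50 - x) / self.Slope)
        )


@dataclass
class LineFit:
    slope: float
    intercept: float
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    residuals: dict = field(default_factory=dict)

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


@dataclass
class MonoExpFit:
    """y = offset + amplitude·(1 − exp(−rate·t))."""

    rate: float
    amplitude: float
    offset: float
    stderr: dict[str, float] = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)

    @property
    def tau(self) -> float:
        return 1.0 / self.rate

    def predict(self, t):
        t = np.asarray(t, float)
        return self.offset + self.amplitude * (1.0 - np.exp(-self.rate * t))


@dataclass
class FTestResult:
    F: float
    p_value: float
    df_num: int
    df_den: int
    comparison: str  # "slope" or "intercept"


def fit_hyperbola(x, y) -> HyperbolaFit:
    """Least-squares rectangular hyperbola.

    Initialization rule: Ymax = max|y|·sign, K_M = x value where y first
    crosses half of Ymax (or the median x).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("hyperbola fit needs at least 3 distinct concentrations")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate data: responses are all equal")

    ymax0 = y[np.argmax(np.abs(y))]
    half = 0.5 * ymax0
    crossing = np.where(np.sign(y - half) != np.sign(y[0] - half))[0]
    km0 = float(x[crossing[0]]) if crossing.size else float(np.median(x))

    def model(xx, ymax, km):
        return ymax * xx / (xx + km)

    popt, pcov = curve_fit(
        model, x, y, p0=[ymax0, km0], bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
        maxfev=10000,
    )
    perr = np.sqrt(np.diag(pcov))
    return HyperbolaFit(
        Ymax=float(popt[0]),
        K_M=float(popt[1]),
        stderr={"Ymax": float(perr[0]), "K_M": float(perr[1])},
        residuals=_residual_summary(y, model(x, *popt)),
    )


def fit_boltzmann(x, y) -> BoltzmannFit:
    """Least-squares Boltzmann sigmoid over voltage.

    Initialization: Top/Bottom from the data range, V50 from the
    half-range crossing, Slope from a quarter of the x span. Degenerate
    (flat) data fall back to Top = Bottom = mean with a warning diagnostic
    instead of an exception.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("Boltzmann fit needs at least 4 points")

    span = np.ptp(y)
    if span < 1e-12 * max(1.0, np.max(np.abs(y))):
        mean = float(np.mean(y))
        return BoltzmannFit(
            Top=mean, Bottom=mean, V50=float(np.mean(x)),
            Slope=float(np.ptp(x) / 4 or 1.0),
            residuals=_residual_summary(y, np.full_like(y, mean)),
            warnings=["flat data: Top == Bottom, sigmoid parameters unidentified"],
        )

    order = np.argsort(x)
    xs, ys = x[order], y[order]
    top0, bot0 = float(ys[-1]), float(ys[0])
    half = 0.5 * (top0 + bot0)
    idx = int(np.argmin(np.abs(ys - half)))
    v50_0 = float(xs[idx])
    slope0 = float(np.ptp(x) / 4.0) or 1.0

    def model(vv, top, bottom, v50, slope):
        return bottom + (top - bottom) / (1.0 + np.exp((v50 - vv) / slope))

    warnings: list[str] = []
    try:
        popt, pcov = curve_fit(
            model, x, y, p0=[top0, bot0, v50_0, slope0], maxfev=20000
        )
        perr = np.sqrt(np.diag(pcov))
    except RuntimeError:
        popt = [top0, bot0, v50_0, slope0]
        perr = [np.nan] * 4
        warnings.append("Boltzmann fit did not converge; returning initial estimates")
    return BoltzmannFit(
        Top=float(popt[0]),
        Bottom=float(popt[1]),
        V50=float(popt[2]),
        Slope=float(popt[3]),
        stderr=dict(zip(("Top", "Bottom", "V50", "Slope"), map(float, perr))),
        residuals=_residual_summary(y, model(x, *popt)),
        warnings=warnings,
    )


def fit_line(x, y) -> LineFit:
    """Closed-form ordinary least squares line with parameter covariance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("line fit needs at least 2 points")
    X = np.column_stack([x, np.ones_like(x)])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < 2:
        raise ValueError("singular design: x values are all equal")
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    return LineFit(
        slope=float(beta[0]),
        intercept=float(beta[1]),
        covariance=cov,
        residuals=_residual_summary(y, X @ beta),
    )


def fit_monoexp(t, y) -> MonoExpFit:
    """Mono-exponential approach y = offset + amplitude·(1 − e^{−rate·t}).

    Initialization: plateau from the latest samples, rate from a log-linear
    regression of the residual approach to plateau. A non-positive fitted
    rate raises.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 4:
        raise ValueError("mono-exponential fit needs at least 4 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite observations")

    plateau0 = float(np.mean(y[np.argsort(t)][-2:]))
    y0 = float(y[np.argsort(t)][0])
    resid = plateau0 - y
    pos = resid > 1e-12 * max(1.0, abs(plateau0))
    if pos.sum() >= 2:
        k0 = max(-np.polyfit(t[pos], np.log(resid[pos]), 1)[0], 1e-6)
    else:
        k0 = 1.0 / max(np.ptp(t), 1e-6)

    def model(tt, rate, amplitude, offset):
        return offset + amplitude * (1.0 - np.exp(-rate * tt))

    popt, pcov = curve_fit(
        model, t, y, p0=[k0, plateau0 - y0, y0], maxfev=20000
    )
    rate = float(popt[0])
    if rate <= 0:
        raise ValueError(f"fitted rate is non-positive ({rate:.3g} s^-1)")
    perr = np.sqrt(np.diag(pcov))
    return MonoExpFit(
        rate=rate,
        amplitude=float(popt[1]),
        offset=float(popt[2]),
        stderr=dict(zip(("rate", "amplitude", "offset"), map(float, perr))),
        residuals=_residual_summary(y, model(t, *popt)),
    )


def compare_lines_ftest(
    data_a: tuple[np.ndarray, np.ndarray],
    data_b: tuple[np.ndarray, np.ndarray],
    comparison: str = "slope",
) -> FTestResult:
    """Nested-model F-test between two line-fit datasets.

    ``comparison='slope'`` tests whether a shared slope (separate
    intercepts) describes both datasets as well as fully separate lines.
    ``comparison='intercept'`` tests a shared intercept given a shared
    slope, against separate intercepts with a shared slope.
    """
    xa, ya = (np.asarray(v, float) for v in data_a)
    xb, yb = (np.asarray(v, float) for v in data_b)
    n = xa.size + xb.size

    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros_like(xa), np.ones_like(xb)])

    def rss(design: np.ndarray) -> tuple[float, int]:
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r = y - design @ beta
        return float(r @ r), design.shape[1]

    ones = np.ones_like(x)
    full = np.column_stack([ones, g, x, g * x])  # separate slopes & intercepts
    shared_slope = np.column_stack([ones, g, x])  # separate intercepts
    shared_both = np.column_stack([ones, x])  # one line

    if comparison == "slope":
        rss0, p0 = rss(shared_slope)
        rss1, p1 = rss(full)
    elif comparison == "intercept":
        rss0, p0 = rss(shared_both)
        rss1, p1 = rss(shared_slope)
    else:
        raise ValueError("comparison must be 'slope' or 'intercept'")

    df_num = p1 - p0
    df_den = n - p1
    if df_den <= 0:
        raise ValueError("insufficient degrees of freedom for the F-test")
    # perfectly collinear data: both models are exact, no evidence either way
    if rss1 <= 1e-12 * (float(y @ y) + 1.0):
        return FTestResult(0.0, 1.0, df_num, df_den, comparison)
    F = max((rss0 - rss1) / df_num / (rss1 / df_den), 0.0)
    p_value = float(stats.f.sf(F, df_num, df_den))
    return FTestResult(float(F), p_value, df_num, df_den, comparison)


def normalize_to_reference(series: dict, reference_key) -> dict:
    """Divide every value by the reference entry (which maps exactly to 1)."""
    if reference_key not in series:
        raise KeyError(f"reference key {reference_key!r} not in series")
    ref = series[reference_key]
    if ref == 0:
        raise ZeroDivisionError("reference value is zero")
    return {k: v / ref for k, v in series.items()}
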