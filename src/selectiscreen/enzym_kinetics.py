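"""Enzyme inhibition assay mathematics.

Covers the activity-assay pipeline: percent inhibition from absorbances,
IC50 by the logit method, Michaelis-Menten kinetics via Lineweaver-Burk
double-reciprocal fits, the inhibition constant Ki from the secondary
slope-vs-[I] replot, inhibition-mode classification, and the trapezoidal
area under blood-glucose curves.

Models
------
Percent inhibition:        (Abs_control - Abs_sample) / Abs_control * 100
Logit dose-response:       logit(p) = b (ln c - ln IC50), p = inhibition/100
Lineweaver-Burk:           1/v = (Km/Vmax) (1/[S]) + 1/Vmax
Competitive inhibition:    v = Vmax [S] / (Km (1 + [I]/Ki) + [S]);
                           the LB slope is linear in [I]:
                           slope([I]) = Km/Vmax + (Km/(Vmax Ki)) [I]
                           so Ki = intercept / gradient of the replot.

Concentrations are mol/L throughout; rates are in whatever units the input
uses (they cancel in Km and Ki).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def inhibition_rate(abs_control: float, abs_sample: float) -> float:
    """Percent inhibition from control and sample absorbances.

    Negative values (activation) are returned as-is; callers may flag them.

    Raises
    ------
    ValueError
        If the control absorbance is not positive.
    """
    if abs_control <= 0:
        raise ValueError("control absorbance must be positive")
    return (abs_control - abs_sample) / abs_control * 100.0


@dataclass
class DoseResponse:
    """Logit-fitted dose-response: IC50 (mol/L) and slope b, with SEs."""

    concentrations: np.ndarray
    inhibition: np.ndarray
    ic50: float
    slope: float
    ic50_se: float = math.nan
    slope_se: float = math.nan
    covariance: np.ndarray | None = None
    extrapolated: bool = False

    def predict(self, conc) -> np.ndarray:
        """Predicted percent inhibition at the given concentrations."""
        c = np.asarray(conc, dtype=float)
        z = self.slope * (np.log(c) - math.log(self.ic50))
        return 100.0 / (1.0 + np.exp(-z))


LOGIT_EPS = 1e-4


def fit_ic50(concentrations, inhibition_percent) -> DoseResponse:
    """Fit IC50 by the logit method.

    Fractions p = inhibition/100 are clipped to (eps, 1-eps) with
    eps = 1e-4, transformed to logit(p), and regressed on ln(concentration)
    by ordinary least squares: slope b and intercept a give
    IC50 = exp(-a/b).  The regression is weighted: plate-reader percent
    readings carry noise roughly proportional to the signal (constant
    coefficient of variation), and propagating var(y) = sigma^2 y^2 through
    the logit transform gives var(logit p) = sigma^2 / (1-p)^2, so points
    are weighted by (1-p)^2 with p re-estimated from the fitted curve
    (iteratively reweighted least squares).  Standard errors come from the
    weighted-OLS covariance by the delta method.  If the observed
    inhibition never crosses 50% the fit is flagged ``extrapolated``.

    Raises
    ------
    ValueError
        On fewer than 4 positive concentration levels.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(inhibition_percent, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive for the log transform")
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 concentration levels spanning the transition")
    p = np.clip(y / 100.0, LOGIT_EPS, 1.0 - LOGIT_EPS)
    logit = np.log(p / (1.0 - p))
    x = np.log(c)

    # weighted least squares in logit space: constant-CV noise on the
    # percent scale becomes var(logit p) = sigma^2/(1-p)^2 after the
    # transform, so weight by (1-p)^2, re-estimating the weights from the
    # fitted curve (IRLS)
    w = (1.0 - p) ** 2
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    coef = None
    for _ in range(10):
        sw = np.sqrt(w)
        new_coef, *_ = np.linalg.lstsq(X * sw[:, None], logit * sw, rcond=None)
        if coef is not None and np.allclose(new_coef, coef, rtol=1e-12, atol=0):
            coef = new_coef
            break
        coef = new_coef
        p_fit = 1.0 / (1.0 + np.exp(-(X @ coef)))
        w = (1.0 - p_fit) ** 2
    b, a = coef
    if b == 0:
        raise ValueError("degenerate fit: zero slope in logit space")
    ic50 = math.exp(-a / b)

    # weighted-OLS covariance of (b, a), then delta method for IC50
    dof = max(n - 2, 1)
    resid = (logit - X @ coef) * sw
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    b_se = math.sqrt(cov[0, 0])
    # IC50 = exp(-a/b): grad = (a/b^2, -1/b) * IC50 w.r.t. (b, a)
    grad = np.array([a / b**2, -1.0 / b]) * ic50
    ic50_se = float(math.sqrt(grad @ cov @ grad))

    extrapolated = not (y.min() <= 50.0 <= y.max())
    return DoseResponse(
        concentrations=c,
        inhibition=y,
        ic50=ic50,
        slope=float(b),
        ic50_se=ic50_se,
        slope_se=b_se,
        covariance=cov,
        extrapolated=extrapolated,
    )


@dataclass
class LineweaverBurkFit:
    """Double-reciprocal fit at a single inhibitor level."""

    inhibitor: float
    slope: float
    intercept: float
    km_app: float
    vmax_app: float
    r_squared: float


@dataclass
class InhibitionKineticsFit:
    """Kinetic constants and inhibition mode from multi-[I] rate data."""

    km: float
    vmax: float
    ki: float
    mode: str
    lb_fits: list[LineweaverBurkFit] = field(default_factory=list)
    replot_intercept: float = math.nan
    replot_gradient: float = math.nan


def fit_lineweaver_burk(substrate, rate, inhibitor_level: float = 0.0) -> LineweaverBurkFit:
    """Ordinary least squares of 1/v on 1/[S] at one inhibitor level.

    Vmax_app = 1/intercept and Km_app = slope/intercept.

    Raises
    ------
    ValueError
        On fewer than 3 substrate levels, non-positive inputs, or a
        non-positive fitted intercept (invalid kinetics).
    """
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if len(np.unique(s)) < 3:
        raise ValueError("need >= 3 substrate levels")
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("substrate concentrations and rates must be positive")
    x = 1.0 / s
    y = 1.0 / v
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    if intercept <= 0:
        raise ValueError("non-positive 1/Vmax intercept: invalid kinetics")
    yhat = X @ np.array([slope, intercept])
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LineweaverBurkFit(
        inhibitor=float(inhibitor_level),
        slope=float(slope),
        intercept=float(intercept),
        km_app=float(slope / intercept),
        vmax_app=float(1.0 / intercept),
        r_squared=r2,
    )


KI_INFINITE = math.inf


def fit_ki_slope_replot(lb_fits: list[LineweaverBurkFit]) -> InhibitionKineticsFit:
    """Ki from the secondary replot of Lineweaver-Burk slope against [I].

    For competitive inhibition slope([I]) = Km/Vmax + (Km/(Vmax Ki)) [I],
    so Ki = intercept/gradient.  A (near-)zero gradient means no measurable
    inhibition: Ki is reported as the +infinity sentinel.  A negative
    gradient is inconsistent with competitive inhibition and raises.

    Raises
    ------
    ValueError
        On fewer than 3 inhibitor levels or a missing [I]=0 level.
    """
    if len(lb_fits) < 3:
        raise ValueError("need >= 3 inhibitor levels for the replot")
    conc = np.array([f.inhibitor for f in lb_fits], dtype=float)
    if not np.any(conc == 0):
        raise ValueError("the [I]=0 (no-inhibitor) level is required")
    slopes = np.array([f.slope for f in lb_fits], dtype=float)
    X = np.column_stack([conc, np.ones_like(conc)])
    (gradient, intercept), *_ = np.linalg.lstsq(X, slopes, rcond=None)

    base = next(f for f in lb_fits if f.inhibitor == 0)
    scale = abs(intercept) if intercept != 0 else 1.0
    if abs(gradient) * (conc.max() if conc.max() > 0 else 1.0) <= 1e-12 * scale:
        ki = KI_INFINITE
    elif gradient < 0:
        raise ValueError("negative replot gradient: inconsistent with competitive inhibition")
    else:
        ki = float(intercept / gradient)
    mode = classify_inhibition_mode(lb_fits) if len(lb_fits) >= 2 else "unknown"
    return InhibitionKineticsFit(
        km=base.km_app,
        vmax=base.vmax_app,
        ki=ki,
        mode=mode,
        lb_fits=list(lb_fits),
        replot_intercept=float(intercept),
        replot_gradient=float(gradient),
    )


def classify_inhibition_mode(lb_fits: list[LineweaverBurkFit], tol: float = 0.05) -> str:
    """Classify the inhibition mode from apparent constants across [I].

    competitive:    Vmax_app constant (within relative ``tol``), Km_app
                    strictly increasing with [I]
    noncompetitive: Km_app constant, Vmax_app decreasing
    uncompetitive:  Km_app and Vmax_app both decrease proportionally
                    (constant LB slope)
    mixed:          anything else

    Raises
    ------
    ValueError
        If no nonzero inhibitor level is present.
    """
    fits = sorted(lb_fits, key=lambda f: f.inhibitor)
    conc = np.array([f.inhibitor for f in fits])
    if np.all(conc == 0) or len(fits) < 2:
        raise ValueError("mode undefined without a nonzero inhibitor level")
    km = np.array([f.km_app for f in fits])
    vmax = np.array([f.vmax_app for f in fits])
    slopes = np.array([f.slope for f in fits])

    def const(a: np.ndarray) -> bool:
        return (a.max() - a.min()) <= tol * abs(a.mean())

    def increasing(a: np.ndarray) -> bool:
        return bool(np.all(np.diff(a) > tol * 1e-3 * abs(a[0])) and a[-1] > a[0] * (1 + tol))

    def decreasing(a: np.ndarray) -> bool:
        return bool(np.all(np.diff(a) < 0) and a[-1] < a[0] * (1 - tol))

    if const(vmax) and increasing(km):
        return "competitive"
    if const(km) and decreasing(vmax):
        return "noncompetitive"
    if const(slopes) and decreasing(vmax) and decreasing(km):
        return "uncompetitive"
    return "mixed"


def fit_kinetics(data: pd.DataFrame, tol: float = 0.05) -> InhibitionKineticsFit:
    """Full kinetics analysis from a long-format (substrate, inhibitor, rate)
    table: per-[I] Lineweaver-Burk fits, Ki by slope replot, mode call.

    Expected columns: ``substrate``, ``inhibitor``, ``rate``.
    """
    fits = []
    for i_level, grp in data.groupby("inhibitor", sort=True):
        fits.append(fit_lineweaver_burk(grp["substrate"], grp["rate"], float(i_level)))
    result = fit_ki_slope_replot(fits)
    result.mode = classify_inhibition_mode(fits, tol=tol)
    return result


def fit_kinetics_global(data: pd.DataFrame) -> tuple[float, float, float]:
    """Direct nonlinear global fit of the competitive model
    v = Vmax [S] / (Km (1 + [I]/Ki) + [S]); cross-check for the
    double-reciprocal route.  Returns (Km, Vmax, Ki)."""
    s = data["substrate"].to_numpy(dtype=float)
    i = data["inhibitor"].to_numpy(dtype=float)
    v = data["rate"].to_numpy(dtype=float)

    def model(x, km, vmax, ki):
        ss, ii = x
        return vmax * ss / (km * (1.0 + ii / ki) + ss)

    km0 = np.median(s)
    vmax0 = v.max() * 1.2
    ki0 = max(np.median(i[i > 0]), 1e-9) if np.any(i > 0) else 1.0
    popt, _ = curve_fit(model, (s, i), v, p0=[km0, vmax0, ki0], maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def trapezoid_auc(timepoints, values) -> float:
    """Area under a curve by the trapezoidal rule: sum of
    (y_i + y_{i+1})/2 * dt_i.  Timepoints must be strictly increasing.

    Raises
    ------
    ValueError
        On fewer than 2 timepoints or non-increasing times.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    return float(np.trapezoid(y, t))
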