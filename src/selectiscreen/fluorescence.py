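"""Fluorescence quenching analysis: Stern-Volmer, double-log binding,
van't Hoff thermodynamics, and synchronous-fluorescence RSQF profiles.

Models (base-10 logarithms throughout, matching the 2.303 = ln 10 factors):

    Stern-Volmer:  F0/F = 1 + Ksv [Q],  Kq = Ksv / tau0
    Mechanism:     static iff Kq > 2.0e10 L/(mol s), the diffusion-limited
                   collisional quenching bound for biopolymers; Ksv
                   decreasing with temperature is corroborating (secondary)
                   evidence for static quenching.
    Double-log:    log10((F0-F)/F) = log10 Ka + n log10 [Q]
    van't Hoff:    log10 Ka = -dH/(2.303 R T) + dS/(2.303 R)
    Free energy:   dG(T) = dH - T dS
    RSQF:          1 - F/F0 from synchronous-spectrum peak intensities.

Quencher concentrations are mol/L, temperatures kelvin, tau0 seconds,
dH/dG J/mol and dS J/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: universal gas constant, J/(mol K)
R_GAS = 8.314

#: diffusion-limited maximum collisional quenching constant, L/(mol s)
KQ_DIFFUSION_LIMIT = 2.0e10

#: default fluorophore lifetime for biopolymers, seconds
TAU0_DEFAULT = 1.0e-8


@dataclass
class QuenchSeries:
    """Fluorescence intensities versus quencher concentration at one
    temperature.  F0 defaults to the intensity at [Q] = 0."""

    quencher: np.ndarray  # mol/L
    intensity: np.ndarray  # a.u.
    temperature: float  # kelvin
    tau0: float = TAU0_DEFAULT
    f0: float | None = None

    def __post_init__(self) -> None:
        self.quencher = np.asarray(self.quencher, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.quencher < 0):
            raise ValueError("quencher concentrations must be >= 0")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be kelvin > 0")
        if self.f0 is None:
            at_zero = self.intensity[self.quencher == 0]
            if len(at_zero) == 0:
                raise ValueError("F0 not given and no [Q]=0 measurement present")
            self.f0 = float(at_zero.mean())
        if self.f0 <= 0:
            raise ValueError("F0 must be positive")


@dataclass
class SternVolmerFit:
    ksv: float  # L/mol
    kq: float  # L/(mol s)
    r_squared: float
    mechanism: str  # "static" | "dynamic"
    temperature: float


def fit_stern_volmer(series: QuenchSeries) -> SternVolmerFit:
    """Least squares of F0/F - 1 on [Q] through the origin; Ksv is the slope.

    The regression is forced through the origin because the Stern-Volmer
    relation has no free intercept.  Kq = Ksv/tau0; the mechanism is called
    static iff Kq strictly exceeds the 2.0e10 L/(mol s) diffusion bound.

    Raises
    ------
    ValueError
        On fewer than 3 nonzero quencher levels, or if any F exceeds F0
        (fluorescence enhancement, outside the quenching model).
    """
    q = series.quencher
    f = series.intensity
    nz = q > 0
    if nz.sum() < 2 or len(np.unique(q)) < 3:
        raise ValueError("need >= 3 quencher levels (including [Q]=0)")
    if np.any(f > series.f0 * (1 + 1e-12)):
        raise ValueError(
            "intensity above F0 detected: fluorescence enhancement, not quenching; "
            "check F0 or the titration series"
        )
    y = series.f0 / f[nz] - 1.0
    x = q[nz]
    ksv = float(np.dot(x, y) / np.dot(x, x))
    yhat = ksv * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    kq = ksv / series.tau0
    mechanism = "static" if kq > KQ_DIFFUSION_LIMIT else "dynamic"
    return SternVolmerFit(
        ksv=ksv, kq=kq, r_squared=r2, mechanism=mechanism, temperature=series.temperature
    )


def classify_quench_mechanism(fits: list[SternVolmerFit]) -> dict:
    """Combine per-temperature Stern-Volmer fits into a mechanism call.

    Primary rule: static iff Kq strictly exceeds the diffusion-limited bound
    (a Kq exactly at the bound is called dynamic).  Secondary, corroborating
    evidence: Ksv decreasing with rising temperature supports static
    quenching (complex dissociation at higher T); it is reported but does not
    override the primary rule.
    """
    if not fits:
        raise ValueError("no fits given")
    static_votes = [f.kq > KQ_DIFFUSION_LIMIT for f in fits]
    mechanism = "static" if all(static_votes) else "dynamic"
    by_t = sorted(fits, key=lambda f: f.temperature)
    ksv_decreasing = (
        all(a.ksv > b.ksv for a, b in zip(by_t, by_t[1:])) if len(by_t) >= 2 else None
    )
    return {
        "mechanism": mechanism,
        "kq_by_temperature": {f.temperature: f.kq for f in fits},
        "ksv_decreasing_with_temperature": ksv_decreasing,
    }


@dataclass
class BindingFit:
    ka: float  # L/mol
    n_sites: float
    r_squared: float
    temperature: float
    n_points_used: int = 0
    excluded_points: int = 0


def fit_binding_constant(series: QuenchSeries) -> BindingFit:
    """Binding constant Ka and site number n from the double-log plot.

    Least squares of log10((F0-F)/F) on log10 [Q]: slope = n, intercept =
    log10 Ka.  Valid for static quenching.  Points with F >= F0 (no
    measurable quench) are excluded with a count.

    The fit is invariant to rescaling all intensities, since only the
    ratio (F0-F)/F enters.
    """
    q = series.quencher
    f = series.intensity
    mask = (q > 0) & (f < series.f0)
    excluded = int((q > 0).sum() - mask.sum())
    if mask.sum() < 2:
        raise ValueError("need >= 2 usable points with F < F0 at [Q] > 0")
    x = np.log10(q[mask])
    y = np.log10((series.f0 - f[mask]) / f[mask])
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    yhat = X @ np.array([slope, intercept])
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BindingFit(
        ka=float(10.0**intercept),
        n_sites=float(slope),
        r_squared=r2,
        temperature=series.temperature,
        n_points_used=int(mask.sum()),
        excluded_points=excluded,
    )


@dataclass
class ThermoFit:
    dh: float  # J/mol
    ds: float  # J/(mol K)
    dg_by_t: dict[float, float] = field(default_factory=dict)  # kelvin -> J/mol
    r_squared: float = math.nan

    def dg(self, temperature: float) -> float:
        """Gibbs free energy dG = dH - T dS at the given temperature."""
        return self.dh - temperature * self.ds


def fit_vant_hoff(ka_by_temperature: Mapping[float, float]) -> ThermoFit:
    """van't Hoff regression of log10 Ka on 1/T.

    slope = -dH/(2.303 R)  =>  dH = -2.303 R slope
    intercept = dS/(2.303 R)  =>  dS = 2.303 R intercept
    dG is evaluated at every input temperature via dG = dH - T dS.

    Raises
    ------
    ValueError
        On fewer than 2 distinct temperatures or non-positive Ka.
    """
    temps = np.array(sorted(ka_by_temperature), dtype=float)
    if len(np.unique(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    kas = np.array([ka_by_temperature[t] for t in temps], dtype=float)
    if np.any(kas <= 0):
        raise ValueError("Ka values must be positive")
    x = 1.0 / temps
    y = np.log10(kas)
    X = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(X, y, rcond=None)
    ln10 = math.log(10.0)  # the 2.303 factor
    dh = -ln10 * R_GAS * float(slope)
    ds = ln10 * R_GAS * float(intercept)
    yhat = X @ np.array([slope, intercept])
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = ThermoFit(dh=dh, ds=ds, r_squared=r2)
    fit.dg_by_t = {float(t): fit.dg(float(t)) for t in temps}
    return fit


@dataclass
class SyncSpectrumSeries:
    """Synchronous spectra at one excitation-emission offset.

    delta_lambda 15 nm probes tyrosine, 60 nm tryptophan.  ``spectra`` maps
    quencher concentration (mol/L) -> intensity array on the shared
    ``wavelengths`` grid; the [Q]=0 spectrum is the reference.
    """

    delta_lambda: float  # nm, 15 or 60
    wavelengths: np.ndarray  # nm, shared grid
    spectra: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n = len(self.wavelengths)
        for q, s in list(self.spectra.items()):
            s = np.asarray(s, dtype=float)
            if len(s) != n:
                raise ValueError("spectra must share the wavelength grid")
            self.spectra[q] = s
        if 0.0 not in self.spectra:
            raise ValueError("the [Q]=0 reference spectrum is required")


def _parabolic_peak(wavelengths: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """Peak position and height by parabolic refinement around the grid
    maximum; falls back to the grid point at the edges."""
    i = int(np.argmax(intensity))
    if i == 0 or i == len(intensity) - 1:
        return float(wavelengths[i]), float(intensity[i])
    y0, y1, y2 = intensity[i - 1], intensity[i], intensity[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wavelengths[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    step = wavelengths[i + 1] - wavelengths[i]
    lam = float(wavelengths[i] + delta * step)
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return lam, height


@dataclass
class SyncAnalysis:
    delta_lambda: float
    lambda_max: dict[float, float]  # [Q] -> peak wavelength, nm
    shift: dict[float, float]  # [Q] -> lambda_max([Q]) - lambda_max(0), nm
    rsqf: dict[float, float]  # [Q] -> 1 - F/F0 at the peak
    red_shift_detected: bool = False


def analyze_sync_spectra(series: SyncSpectrumSeries, shift_tol: float = 0.5) -> SyncAnalysis:
    """Peak wavelengths, red shifts and the RSQF quench profile.

    The peak per concentration is located by parabolic refinement around the
    grid maximum; RSQF = 1 - F_peak([Q]) / F_peak(0).  A red shift is flagged
    when the highest-concentration peak moved more than ``shift_tol`` nm to
    longer wavelength.
    """
    lam0, f0 = _parabolic_peak(series.wavelengths, series.spectra[0.0])
    lambda_max: dict[float, float] = {}
    shift: dict[float, float] = {}
    rsqf: dict[float, float] = {}
    for q in sorted(series.spectra):
        lam, fpk = _parabolic_peak(series.wavelengths, series.spectra[q])
        lambda_max[q] = lam
        shift[q] = lam - lam0
        rsqf[q] = 1.0 - fpk / f0
    qmax = max(series.spectra)
    return SyncAnalysis(
        delta_lambda=series.delta_lambda,
        lambda_max=lambda_max,
        shift=shift,
        rsqf=rsqf,
        red_shift_detected=shift[qmax] > shift_tol,
    )
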