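"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions end to end: a 300-compound
training set (151 actives / 149 inactives) whose 1562 descriptors fall into
block-correlated groups (two noisy copies of each latent factor) split across
the rdkit/drugtax/fingerprint families (208/163/1191); bimodal docking-score
distributions per protein target with a designed fraction of selective
compounds; logistic dose-response curves; competitive-inhibition rate
surfaces; 1:1 static-quenching intensity series with a van't Hoff
temperature-dependent association constant; and Gaussian-peak synchronous
spectra with a concentration-dependent quench and red shift.

Every generator takes an explicit seed (one fresh RNG stream per call, no
global state) and returns its table together with a ``truth`` dict holding
the generating parameters, sufficient to compute expected fit outputs in
closed form at zero noise.  Zero noise is first-class: ``noise_sd=0``
produces exactly deterministic model values, so closed-form equality tests
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_data import AssayTable, DescriptorMatrix, DockingScoreTable
from .fluorescence import R_GAS


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the descriptor and docking generators."""

    seed: int = 0
    # descriptor matrix
    n_compounds: int = 300
    n_active: int = 151
    n_latent_factors: int = 30
    copies_per_factor: int = 2
    noise_sd: float = 0.3
    n_label_factors: int = 5  # sparse logistic model: first few factors carry signal
    beta_scale: float = 2.0
    family_counts: dict[str, int] = field(
        default_factory=lambda: {"rdkit": 208, "drugtax": 163, "fingerprint": 1191}
    )
    n_constant_columns: int = 0
    # docking scores
    selective_fraction: float = 0.05
    target_name: str = "glucosidase"
    offtarget_name: str = "amylase"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.selective_fraction <= 1:
            raise ValueError("selective_fraction must be in [0, 1]")
        if self.n_active > self.n_compounds:
            raise ValueError("n_active cannot exceed n_compounds")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def gen_descriptor_matrix(cfg: GeneratorConfig) -> tuple[DescriptorMatrix, dict]:
    """Descriptor matrix with block-correlated columns and balanced labels.

    Latent factors are standard normal per compound; each factor yields
    ``copies_per_factor`` observed columns (factor + Gaussian noise).  The
    remaining columns up to the family totals are pure noise (binarized in
    the fingerprint family); ``n_constant_columns`` constant columns can be
    planted.  Labels are Bernoulli(sigmoid(beta . factors)) with a sparse
    beta, then repaired by flipping the compounds nearest the decision
    boundary so the active/inactive counts hit the configured ratio exactly.

    The truth dict records the factor-to-column partition, beta, labels and
    planted constants.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L, c = cfg.n_compounds, cfg.n_latent_factors, cfg.copies_per_factor
    factors = rng.standard_normal((n, L))

    informative = {}
    factor_partition: dict[int, list[str]] = {}
    for j in range(L):
        factor_partition[j] = []
        for r in range(c):
            name = f"f{j:03d}_copy{r}"
            informative[name] = factors[:, j] + cfg.noise_sd * rng.standard_normal(n)
            factor_partition[j].append(name)

    beta = np.zeros(L)
    k = min(cfg.n_label_factors, L)
    signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    beta[:k] = cfg.beta_scale * signs
    p = _sigmoid(factors @ beta)
    labels = (rng.random(n) < p).astype(int)
    # repair to the exact class ratio, flipping boundary compounds first
    need = cfg.n_active - labels.sum()
    if need > 0:
        candidates = np.where(labels == 0)[0]
        order = candidates[np.argsort(-p[candidates])]
        labels[order[:need]] = 1
    elif need < 0:
        candidates = np.where(labels == 1)[0]
        order = candidates[np.argsort(p[candidates])]
        labels[order[:-need]] = 0
    if labels.sum() != cfg.n_active:
        raise ValueError("infeasible class balance for the requested ratio")

    # distribute columns across families: informative first (rdkit), then
    # noise fill per family; fingerprint columns are binarized
    columns: dict[str, np.ndarray] = {}
    families: dict[str, str] = {}
    fam_counts = dict(cfg.family_counts) or {"other": len(informative) + cfg.n_constant_columns}
    total = sum(fam_counts.values())
    n_inform = len(informative)
    if n_inform + cfg.n_constant_columns > total:
        raise ValueError("family totals too small for informative + constant columns")

    inform_iter = iter(informative.items())
    n_const_left = cfg.n_constant_columns
    placed_inform = 0
    constant_names: list[str] = []
    for fam, count in fam_counts.items():
        for i in range(count):
            name_i = None
            if fam != "fingerprint" and placed_inform < n_inform:
                name_i, col = next(inform_iter)
                placed_inform += 1
            elif n_const_left > 0:
                name_i = f"{fam}_const{n_const_left:03d}"
                col = np.full(n, 1.0)
                n_const_left -= 1
                constant_names.append(name_i)
            else:
                name_i = f"{fam}_noise{i:04d}"
                col = rng.standard_normal(n)
                if fam == "fingerprint":
                    col = (col > 0).astype(float)
            columns[name_i] = col
            families[name_i] = fam
    # if fingerprint-only config left informative columns unplaced, append them
    for name_i, col in inform_iter:
        columns[name_i] = col
        families[name_i] = "rdkit"

    ids = [f"CMPD{i:05d}" for i in range(n)]
    values = pd.DataFrame(columns, index=ids)
    matrix = DescriptorMatrix(
        values=values,
        labels=pd.Series(labels, index=ids, name="label"),
        families=families,
    )
    truth = {
        "factor_partition": factor_partition,
        "beta": beta,
        "labels": dict(zip(ids, labels.tolist())),
        "constant_columns": constant_names,
        "factors": factors,
    }
    return matrix, truth


def gen_docking_scores(
    cfg: GeneratorConfig, compound_ids: list[str] | None = None
) -> tuple[DockingScoreTable, dict]:
    """Per-target bimodal docking scores with designed selective compounds.

    Non-selective compounds draw from a two-component Gaussian mixture per
    target (a strong-binder mode near -9 and a weak mode near -6 kcal/mol).
    A ``selective_fraction`` of compounds is designed selective: target score
    strictly below -8.5 with margin, off-target strictly above -5.0 with
    margin.  Truth lists the designed selective ids.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if compound_ids is None:
        compound_ids = [f"LIB{i:05d}" for i in range(cfg.n_compounds)]
    n = len(compound_ids)
    n_sel = int(round(cfg.selective_fraction * n))
    sel_idx = rng.choice(n, size=n_sel, replace=False)
    is_sel = np.zeros(n, dtype=bool)
    is_sel[sel_idx] = True

    def mixture(size):
        comp = rng.random(size) < 0.4
        strong = rng.normal(-9.0, 0.6, size)
        weak = rng.normal(-6.0, 1.2, size)
        return np.where(comp, strong, weak)

    target = mixture(n)
    offtarget = mixture(n)
    # designed selectives: margins keep them strictly inside both cutoffs
    target[is_sel] = -8.8 - rng.exponential(0.8, n_sel)
    offtarget[is_sel] = -4.7 + rng.uniform(0.0, 2.5, n_sel)

    scores = pd.DataFrame(
        {cfg.target_name: target, cfg.offtarget_name: offtarget},
        index=compound_ids,
    )
    truth = {"designed_selectives": [compound_ids[i] for i in sorted(sel_idx)]}
    return DockingScoreTable(scores=scores), truth


# ---------------------------------------------------------------------------
# assay generators


def gen_dose_response(
    ic50: float = 23.03e-6,
    slope: float = 1.0,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTable, dict]:
    """Logistic dose-response table: inhibition% = 100 / (1 + (IC50/c)^b).

    Default IC50 is 23.03 uM (the strongest measured inhibitor's value used
    as the planted truth).  Noise is multiplicative Gaussian on the percent.
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = ic50 * np.logspace(-1.5, 1.5, 8)
    c = np.asarray(concentrations, dtype=float)
    p = 1.0 / (1.0 + (ic50 / c) ** slope)
    y = 100.0 * p
    if noise_sd > 0:
        y = y * (1.0 + noise_sd * rng.standard_normal(len(c)))
        y = np.clip(y, 0.01, 99.99)
    table = AssayTable(
        kind="dose_response",
        data=pd.DataFrame({"concentration": c, "inhibition_percent": y}),
        units={"concentration": "mol/L"},
    )
    return table, {"ic50": ic50, "slope": slope}


def gen_kinetics(
    km: float = 2e-3,
    vmax: float = 1.0,
    ki: float = 0.5e-3,
    mode: str = "competitive",
    substrate=None,
    inhibitor_levels=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTable, dict]:
    """Initial-rate surface under a chosen inhibition model.

    competitive:    v = Vmax [S] / (Km (1 + [I]/Ki) + [S])
    noncompetitive: v = (Vmax / (1 + [I]/Ki)) [S] / (Km + [S])
    uncompetitive:  v = Vmax [S] / (Km + [S] (1 + [I]/Ki)) -- apparent Km and
                    Vmax both divided by (1 + [I]/Ki)

    Km and Ki default to 2 mM and 0.5 mM (mol/L internally); noise is
    multiplicative Gaussian on the rate.
    """
    rng = np.random.default_rng(seed)
    if substrate is None:
        substrate = km * np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
    if inhibitor_levels is None:
        inhibitor_levels = np.array([0.0, 0.5, 1.0, 2.0]) * ki
    rows = []
    for i_conc in inhibitor_levels:
        alpha = 1.0 + i_conc / ki
        for s in substrate:
            if mode == "competitive":
                v = vmax * s / (km * alpha + s)
            elif mode == "noncompetitive":
                v = (vmax / alpha) * s / (km + s)
            elif mode == "uncompetitive":
                v = vmax * s / (km + s * alpha)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if noise_sd > 0:
                v = v * (1.0 + noise_sd * rng.standard_normal())
                v = max(v, 1e-12)
            rows.append({"substrate": s, "inhibitor": i_conc, "rate": v})
    table = AssayTable(
        kind="kinetics",
        data=pd.DataFrame(rows),
        units={"substrate": "mol/L", "inhibitor": "mol/L"},
    )
    return table, {"km": km, "vmax": vmax, "ki": ki, "mode": mode}


def ka_from_thermo(dh: float, ds: float, temperature: float) -> float:
    """Association constant from van't Hoff parameters:
    log10 Ka = -dH/(2.303 R T) + dS/(2.303 R)."""
    ln10 = np.log(10.0)
    log_ka = -dh / (ln10 * R_GAS * temperature) + ds / (ln10 * R_GAS)
    return float(10.0**log_ka)


def gen_quench(
    dh: float = -30e3,
    ds: float = -50.0,
    temperatures=(300.15, 305.15, 310.15),
    f0: float = 1000.0,
    quencher=None,
    tau0: float = 1.0e-8,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTable, dict]:
    """Static-quenching titrations at several temperatures.

    The 1:1 ground-state complex model F = F0 / (1 + Ka(T) [Q]) makes the
    Stern-Volmer constant equal the association constant (F0/F - 1 =
    Ka [Q]), and the double-log plot recovers n = 1 exactly.  Ka(T) follows
    the van't Hoff relation with the configured dH (J/mol) and dS
    (J/(mol K)).  Noise is multiplicative Gaussian on F.
    """
    rng = np.random.default_rng(seed)
    if quencher is None:
        quencher = np.concatenate([[0.0], np.linspace(2e-4, 2e-3, 8)])
    q = np.asarray(quencher, dtype=float)
    rows = []
    ka_by_t = {}
    for t in temperatures:
        ka = ka_from_thermo(dh, ds, t)
        ka_by_t[float(t)] = ka
        f = f0 / (1.0 + ka * q)
        if noise_sd > 0:
            noisy = f * (1.0 + noise_sd * rng.standard_normal(len(q)))
            # keep the series inside the quenching regime (F <= F0)
            f = np.minimum(np.maximum(noisy, 1e-9), f0)
            f[q == 0] = f0
        for qi, fi in zip(q, f):
            rows.append({"temperature": t, "quencher": qi, "intensity": fi})
    table = AssayTable(
        kind="quench",
        data=pd.DataFrame(rows),
        units={"quencher": "mol/L", "temperature": "K"},
    )
    truth = {"dh": dh, "ds": ds, "ka_by_temperature": ka_by_t, "f0": f0, "tau0": tau0, "n_sites": 1.0}
    return table, truth


def gen_sync_spectra(
    delta_lambda: float = 15.0,
    peak_center: float = 285.0,
    peak_width: float = 8.0,
    f0: float = 1000.0,
    max_quench: float = 0.4,
    max_shift: float = 4.0,
    concentrations=None,
    wavelengths=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTable, dict]:
    """Gaussian-peak synchronous spectra with planted quench and red shift.

    Peak amplitude decays linearly to (1 - max_quench) F0 and the center
    shifts linearly to +max_shift nm at the highest concentration.
    """
    rng = np.random.default_rng(seed)
    if concentrations is None:
        concentrations = np.linspace(0.0, 2e-3, 6)
    if wavelengths is None:
        wavelengths = np.arange(260.0, 320.5, 0.5)
    conc = np.asarray(concentrations, dtype=float)
    lam = np.asarray(wavelengths, dtype=float)
    qmax = conc.max() if conc.max() > 0 else 1.0
    rows = []
    for q in conc:
        frac = q / qmax
        amp = f0 * (1.0 - max_quench * frac)
        center = peak_center + max_shift * frac
        spec = amp * np.exp(-0.5 * ((lam - center) / peak_width) ** 2)
        if noise_sd > 0:
            spec = np.maximum(spec * (1.0 + noise_sd * rng.standard_normal(len(lam))), 0.0)
        for wl, inten in zip(lam, spec):
            rows.append({"concentration": q, "wavelength": wl, "intensity": inten})
    table = AssayTable(
        kind="sync_spectrum",
        data=pd.DataFrame(rows),
        units={"concentration": "mol/L", "wavelength": "nm"},
    )
    truth = {
        "delta_lambda": delta_lambda,
        "max_quench": max_quench,
        "max_shift": max_shift,
        "peak_center": peak_center,
        "f0": f0,
    }
    return table, truth


def gen_glucose_curve(
    baseline: float = 5.0,
    peak: float = 12.0,
    peak_time: float = 30.0,
    timepoints=(0, 10, 20, 30, 40, 60, 90, 120),
    suppression: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[AssayTable, dict]:
    """Postprandial blood-glucose curve (mmol/L over minutes).

    A gamma-shaped excursion above baseline peaking at ``peak_time``;
    ``suppression`` in [0, 1] scales the excursion down (inhibitor effect).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(timepoints, dtype=float)
    excursion = (peak - baseline) * (t / peak_time) * np.exp(1.0 - t / peak_time)
    y = baseline + (1.0 - suppression) * np.maximum(excursion, 0.0)
    if noise_sd > 0:
        y = np.maximum(y * (1.0 + noise_sd * rng.standard_normal(len(t))), 0.1)
    table = AssayTable(
        kind="glucose_curve",
        data=pd.DataFrame({"time_min": t, "glucose_mmol_L": y}),
        units={"time_min": "min", "glucose_mmol_L": "mmol/L"},
    )
    return table, {"baseline": baseline, "peak": peak, "suppression": suppression}
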