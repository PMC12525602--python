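"""Stern-Volmer quenching, binding constants, van't Hoff, synchronous RSQF."""

import numpy as np
import pytest

from selectiscreen import synthetic_data as sd
from selectiscreen.fluorescence import (
    KQ_DIFFUSION_LIMIT,
    QuenchSeries,
    SternVolmerFit,
    SyncSpectrumSeries,
    analyze_sync_spectra,
    classify_quench_mechanism,
    fit_binding_constant,
    fit_stern_volmer,
    fit_vant_hoff,
)


def series_from(ka=2000.0, f0=1000.0, q=None, temperature=300.15, tau0=1e-8):
    if q is None:
        q = np.concatenate([[0.0], np.linspace(2e-4, 2e-3, 6)])
    f = f0 / (1.0 + ka * q)
    return QuenchSeries(quencher=q, intensity=f, temperature=temperature, tau0=tau0)


# --- Stern-Volmer ------------------------------------------------------------

def test_stern_volmer_exact_slope():
    fit = fit_stern_volmer(series_from(ka=2000.0))
    assert fit.ksv == pytest.approx(2000.0, rel=1e-12)
    assert fit.kq == pytest.approx(2000.0 / 1e-8, rel=1e-12)


def test_stern_volmer_insufficient_levels():
    s = QuenchSeries(quencher=np.array([0.0, 1e-4]), intensity=np.array([1000.0, 900.0]),
                     temperature=300.15)
    with pytest.raises(ValueError, match="3 quencher levels"):
        fit_stern_volmer(s)


def test_stern_volmer_enhancement_diagnosed():
    q = np.array([0.0, 1e-4, 2e-4, 4e-4])
    f = np.array([1000.0, 1100.0, 900.0, 800.0])
    s = QuenchSeries(quencher=q, intensity=f, temperature=300.15)
    with pytest.raises(ValueError, match="enhancement"):
        fit_stern_volmer(s)


def test_mechanism_threshold():
    """Ksv = 1000 L/mol with tau0 = 1e-8 s gives Kq = 1e11 > 2e10: static."""
    fit = fit_stern_volmer(series_from(ka=1000.0, tau0=1e-8))
    assert fit.kq > KQ_DIFFUSION_LIMIT
    assert fit.mechanism == "static"


@pytest.mark.parametrize(
    "kq,expected",
    [(3e12, "static"), (1e9, "dynamic"), (2.0e10, "dynamic")],  # boundary is strict
)
def test_classify_mechanism_primary_rule(kq, expected):
    fits = [SternVolmerFit(ksv=kq * 1e-8, kq=kq, r_squared=1.0, mechanism="", temperature=300.15)]
    assert classify_quench_mechanism(fits)["mechanism"] == expected


def test_ksv_decreasing_with_temperature_reported_as_secondary_evidence():
    table, truth = sd.gen_quench(noise_sd=0.0)
    fits = []
    for t, grp in table.data.groupby("temperature"):
        fits.append(fit_stern_volmer(QuenchSeries(
            quencher=grp["quencher"].to_numpy(), intensity=grp["intensity"].to_numpy(),
            temperature=float(t), tau0=truth["tau0"])))
    out = classify_quench_mechanism(fits)
    assert out["ksv_decreasing_with_temperature"] is True
    assert out["mechanism"] == "static"


# --- binding constant --------------------------------------------------------

def test_binding_constant_exact_recovery():
    """The 1:1 static model F = F0/(1 + Ka [Q]) satisfies the double-log
    relation with n = 1 exactly."""
    fit = fit_binding_constant(series_from(ka=5e4, q=np.concatenate([[0.0], np.linspace(1e-5, 2e-4, 8)])))
    assert fit.ka == pytest.approx(5e4, rel=1e-6)
    assert fit.n_sites == pytest.approx(1.0, rel=1e-6)


def test_binding_constant_intensity_scale_invariance():
    q = np.concatenate([[0.0], np.linspace(2e-4, 2e-3, 6)])
    f = 1000.0 / (1.0 + 2000.0 * q)
    s1 = QuenchSeries(quencher=q, intensity=f, temperature=300.15)
    s2 = QuenchSeries(quencher=q, intensity=2 * f, temperature=300.15)
    f1, f2 = fit_binding_constant(s1), fit_binding_constant(s2)
    assert f1.ka == pytest.approx(f2.ka, rel=1e-12)
    assert f1.n_sites == pytest.approx(f2.n_sites, rel=1e-12)


def test_binding_constant_monte_carlo_site_number():
    """1% intensity noise, 300 simulations: fitted n in [0.9, 1.1] in at
    least 90% of runs."""
    hits = 0
    for rep in range(300):
        table, truth = sd.gen_quench(noise_sd=0.01, seed=5000 + rep, temperatures=(300.15,))
        grp = table.data
        s = QuenchSeries(quencher=grp["quencher"].to_numpy(),
                         intensity=grp["intensity"].to_numpy(), temperature=300.15)
        n = fit_binding_constant(s).n_sites
        hits += 0.9 <= n <= 1.1
    assert hits >= 0.9 * 300


def test_stern_volmer_and_binding_agree_for_static_generator():
    """For the 1:1 ground-state complex model both routes estimate the same
    association constant."""
    table, truth = sd.gen_quench(noise_sd=0.0, temperatures=(300.15,))
    grp = table.data
    s = QuenchSeries(quencher=grp["quencher"].to_numpy(),
                     intensity=grp["intensity"].to_numpy(), temperature=300.15)
    ksv = fit_stern_volmer(s).ksv
    ka = fit_binding_constant(s).ka
    truth_ka = truth["ka_by_temperature"][300.15]
    assert ksv == pytest.approx(truth_ka, rel=1e-9)
    assert ka == pytest.approx(truth_ka, rel=1e-9)


# --- van't Hoff --------------------------------------------------------------

def test_vant_hoff_exact_recovery():
    dh, ds = -30e3, -50.0
    temps = (300.15, 305.15, 310.15)
    ka = {t: sd.ka_from_thermo(dh, ds, t) for t in temps}
    fit = fit_vant_hoff(ka)
    assert fit.dh == pytest.approx(dh, rel=1e-9)
    assert fit.ds == pytest.approx(ds, rel=1e-9)
    for t in temps:
        assert fit.dg_by_t[t] == pytest.approx(dh - t * ds, rel=1e-12)


def test_vant_hoff_flat_line():
    fit = fit_vant_hoff({300.0: 1e4, 310.0: 1e4})
    assert fit.dh == pytest.approx(0.0, abs=1e-6)
    assert fit.dg(305.0) == pytest.approx(-305.0 * fit.ds, rel=1e-9)


def test_vant_hoff_two_points_exact_interpolation():
    ka = {300.0: 5e3, 310.0: 2e3}
    fit = fit_vant_hoff(ka)
    assert fit.r_squared == pytest.approx(1.0)


def test_vant_hoff_equal_temperatures_error():
    with pytest.raises(ValueError, match="distinct temperatures"):
        fit_vant_hoff({300.0: 1e4})


def test_dg_identity_holds_exactly():
    fit = fit_vant_hoff({300.15: 4e2, 305.15: 3.3e2, 310.15: 2.8e2})
    for t, dg in fit.dg_by_t.items():
        assert dg - (fit.dh - t * fit.ds) == 0.0


# --- synchronous spectra -----------------------------------------------------

def _series_from_table(table, truth):
    wl = np.sort(table.data["wavelength"].unique())
    spectra = {
        float(q): g.sort_values("wavelength")["intensity"].to_numpy()
        for q, g in table.data.groupby("concentration")
    }
    return SyncSpectrumSeries(delta_lambda=truth["delta_lambda"], wavelengths=wl, spectra=spectra)


def test_identical_spectra_no_quench_no_shift():
    wl = np.arange(260.0, 320.0, 0.5)
    spec = 100.0 * np.exp(-0.5 * ((wl - 285.0) / 8.0) ** 2)
    series = SyncSpectrumSeries(delta_lambda=15, wavelengths=wl,
                                spectra={0.0: spec, 1e-3: spec.copy()})
    out = analyze_sync_spectra(series)
    assert out.rsqf[1e-3] == pytest.approx(0.0, abs=1e-12)
    assert out.shift[1e-3] == pytest.approx(0.0, abs=1e-9)
    assert not out.red_shift_detected


def test_planted_quench_and_red_shift_recovered():
    """40% peak quench and a +4 nm planted shift are recovered (shift to
    0.2 nm via parabolic refinement)."""
    table, truth = sd.gen_sync_spectra(max_quench=0.4, max_shift=4.0, noise_sd=0.0)
    out = analyze_sync_spectra(_series_from_table(table, truth))
    qmax = max(out.rsqf)
    assert out.rsqf[qmax] == pytest.approx(0.4, abs=1e-6)
    assert out.shift[qmax] == pytest.approx(4.0, abs=0.2)
    assert out.red_shift_detected


def test_rsqf_limit_complete_quench():
    wl = np.arange(260.0, 320.0, 0.5)
    spec0 = 100.0 * np.exp(-0.5 * ((wl - 285.0) / 8.0) ** 2)
    series = SyncSpectrumSeries(delta_lambda=60, wavelengths=wl,
                                spectra={0.0: spec0, 1e-3: spec0 * 1e-9})
    out = analyze_sync_spectra(series)
    assert out.rsqf[1e-3] == pytest.approx(1.0, abs=1e-6)


def test_rsqf_monotone_in_concentration():
    table, truth = sd.gen_sync_spectra(noise_sd=0.0)
    out = analyze_sync_spectra(_series_from_table(table, truth))
    concs = sorted(out.rsqf)
    vals = [out.rsqf[q] for q in concs]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


def test_reference_spectrum_required():
    wl = np.arange(260.0, 320.0, 0.5)
    with pytest.raises(ValueError, match=r"\[Q\]=0"):
        SyncSpectrumSeries(delta_lambda=15, wavelengths=wl, spectra={1e-3: np.ones_like(wl)})


def test_mismatched_grids_rejected():
    wl = np.arange(260.0, 320.0, 0.5)
    with pytest.raises(ValueError, match="share the wavelength grid"):
        SyncSpectrumSeries(delta_lambda=15, wavelengths=wl,
                           spectra={0.0: np.ones_like(wl), 1e-3: np.ones(3)})
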