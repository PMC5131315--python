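import warnings

import numpy as np
import pytest

from calcimem import tdfs
from calcimem.tdfs import (
    AnalysisError,
    DecayCurve,
    InstrumentResponse,
    fit_decay,
    fit_decay_series,
    fit_langmuir_freundlich,
    fit_lognormal,
    generate_synthetic_tdfs,
    integrated_relaxation_time,
    lognormal_shape,
    reconstruct_tres,
    total_shift,
    wavelength_to_wavenumber,
)


def _delta_irf(n=512, dt=0.05):
    t = np.arange(n) * dt
    r = np.zeros(n)
    r[0] = 1.0
    return InstrumentResponse(t=t, response=r)


class TestFitDecay:
    def test_single_exponential_recovered_to_one_percent(self):
        t = np.arange(1024) * 0.05
        sigma = 0.08 / (2 * np.sqrt(2 * np.log(2)))
        irf_curve = np.exp(-0.5 * ((t - 1.0) / sigma) ** 2)
        irf = InstrumentResponse(t=t, response=irf_curve)
        model = np.convolve(irf.response, 5000 * np.exp(-t / 2.0))[: len(t)]
        decay = DecayCurve(t=t, counts=np.round(model).astype(int), wavelength=450.0)
        fit = fit_decay(decay, irf, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(2.0, rel=0.01)

    def test_delta_irf_closed_form(self):
        irf = _delta_irf()
        t = irf.t
        counts = np.round(3000 * np.exp(-t / 3.0)).astype(int)
        fit = fit_decay(DecayCurve(t=t, counts=counts, wavelength=450.0), irf, 1)
        assert fit.lifetimes[0] == pytest.approx(3.0, rel=0.005)
        np.testing.assert_allclose(
            fit.decay_function(t), fit.amplitudes[0] * np.exp(-t / 3.0), rtol=1e-3
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_exponential_poisson_within_five_percent(self, seed):
        rng = np.random.default_rng(seed)
        irf = _delta_irf(1024)
        t = irf.t
        truth = 10_000 * (0.7 * np.exp(-t / 1.0) + 0.3 * np.exp(-t / 5.0))
        counts = rng.poisson(truth)
        fit = fit_decay(DecayCurve(t=t, counts=counts, wavelength=450.0), irf, 2)
        assert fit.lifetimes[0] == pytest.approx(1.0, rel=0.05)
        assert fit.lifetimes[1] == pytest.approx(5.0, rel=0.05)
        assert fit.chi2_reduced < 1.3

    def test_bad_component_count(self):
        irf = _delta_irf(64)
        d = DecayCurve(t=irf.t, counts=np.ones(64, int), wavelength=450.0)
        with pytest.raises(ValueError):
            fit_decay(d, irf, 5)

    def test_series_fit_tracks_nonexponential_decay(self):
        # product of exponential and slow modulation: inside the span of the
        # fixed lifetime basis even though it is not a 2-exponential
        irf = _delta_irf(1024)
        t = irf.t
        truth = 8000 * np.exp(-t / 2.0) / (1 + 0.3 * t)
        d = DecayCurve(t=t, counts=np.round(truth).astype(int), wavelength=450.0)
        fit = fit_decay_series(d, irf)
        rel = np.abs(fit.model_counts[truth > 50] / truth[truth > 50] - 1)
        assert rel.max() < 0.02


class TestTRES:
    def _fits_identical(self):
        irf = _delta_irf(256)
        t = irf.t
        wls = np.array([400.0, 450.0, 500.0, 550.0])
        fits = {}
        for wl in wls:
            counts = np.round(1000 * np.exp(-t / 2.0)).astype(int)
            fits[wl] = fit_decay(DecayCurve(t=t, counts=counts, wavelength=wl), irf, 1)
        return fits, wls

    def test_identical_decays_give_time_constant_spectrum(self):
        fits, wls = self._fits_identical()
        ss = (wls, np.array([1.0, 3.0, 2.0, 0.5]))
        times = np.linspace(0, 5, 11)
        tres = reconstruct_tres(fits, ss, times)
        shape0 = tres.intensity[:, 0] / tres.intensity[:, 0].sum()
        for j in range(1, len(times)):
            np.testing.assert_allclose(
                tres.intensity[:, j] / tres.intensity[:, j].sum(), shape0, rtol=1e-9
            )

    def test_wavelength_conversion(self):
        assert wavelength_to_wavenumber(500.0) == pytest.approx(20000.0)

    def test_time_integral_conserves_steady_state(self):
        fits, wls = self._fits_identical()
        ss_int = np.array([1.0, 3.0, 2.0, 0.5])
        times = np.linspace(0, 80, 4000)
        tres = reconstruct_tres(fits, (wls, ss_int), times)
        for i, wl in enumerate(tres.wavelengths):
            s_lambda = tres.intensity[i] / (wl**2 * 1e-7)  # undo the Jacobian
            integral = np.trapezoid(s_lambda, times)  # trapezoid truncation only
            ss_i = ss_int[np.argmax(wls == wl)]
            assert integral == pytest.approx(ss_i, rel=1e-4)

    def test_missing_wavelength_rejected(self):
        fits, wls = self._fits_identical()
        del fits[450.0]
        with pytest.raises(ValueError, match="450"):
            reconstruct_tres(fits, (wls, np.ones(4)), np.linspace(0, 5, 5))


class TestLogNormal:
    def test_symmetric_gaussian_limit(self):
        nu = np.linspace(18000, 26000, 30)
        y = np.exp(-0.5 * ((nu - 22000) / 900.0) ** 2)
        fit = fit_lognormal(nu, y)
        assert fit.peak == pytest.approx(22000, abs=1.0)
        assert abs(fit.asymmetry) < 0.02

    def test_round_trip_16_points(self):
        nu = np.linspace(18000, 25500, 16)
        y = lognormal_shape(nu, 21500.0, 2.0, 2600.0, -0.25)
        fit = fit_lognormal(nu, y)
        assert fit.peak == pytest.approx(21500.0, rel=1e-3)
        assert fit.width == pytest.approx(2600.0, rel=1e-3)
        assert fit.asymmetry == pytest.approx(-0.25, abs=1e-3)

    def test_five_point_minimum(self):
        nu = np.linspace(20000, 24000, 5)
        y = lognormal_shape(nu, 22000.0, 1.0, 2000.0, -0.1)
        fit = fit_lognormal(nu, y)
        assert fit.peak == pytest.approx(22000.0, rel=1e-2)
        with pytest.raises(ValueError):
            fit_lognormal(nu[:4], y[:4])

    def test_peak_outside_window_flagged(self):
        nu = np.linspace(20000, 24000, 12)
        y = lognormal_shape(nu, 19000.0, 1.0, 2500.0, -0.1)
        with pytest.warns(UserWarning, match="outside"):
            fit = fit_lognormal(nu, y)
        assert fit.extrapolated


class TestShiftAndTau:
    def test_shift_arithmetic(self):
        times = np.linspace(0, 10, 50)
        nu = np.full(50, 21800.0)
        dnu, nu_inf, ok = total_shift(nu, times, 23800.0)
        assert dnu == pytest.approx(2000.0) and ok

    def test_flat_at_nu0_gives_zero(self):
        times = np.linspace(0, 10, 50)
        dnu, _, _ = total_shift(np.full(50, 23800.0), times, 23800.0)
        assert dnu == 0.0

    def test_unrelaxed_plateau_warns(self):
        times = np.linspace(0, 2, 50)
        nu = 23800.0 - 500.0 * times  # still drifting at the end
        with pytest.warns(UserWarning, match="drift"):
            _, _, ok = total_shift(nu, times, 23800.0)
        assert not ok

    def test_single_exponential_identity(self):
        times = np.linspace(0, 25, 200)
        nu = 22000.0 + 1800.0 * np.exp(-times / 1.7)
        tau = integrated_relaxation_time(nu, times, 23800.0, 22000.0)
        assert tau == pytest.approx(1.7, abs=1e-6)

    def test_mixture_amplitude_weighted_mean(self):
        times = np.concatenate([[0], np.geomspace(0.01, 30, 150)])
        c = 0.5 * np.exp(-times / 1.0) + 0.5 * np.exp(-times / 3.0)
        nu = 22000.0 + 1800.0 * c
        tau = integrated_relaxation_time(nu, times, 23800.0, 22000.0)
        assert tau == pytest.approx(2.0, abs=1e-6)

    def test_random_mixtures_analytic_identity(self, rng):
        for _ in range(5):
            a = rng.dirichlet(np.ones(3))
            taus = rng.uniform(0.3, 6.0, size=3)
            times = np.concatenate([[0], np.geomspace(0.01, 50, 200)])
            c = (a[:, None] * np.exp(-times[None, :] / taus[:, None])).sum(0)
            nu = 22000.0 + 1500.0 * c
            est = integrated_relaxation_time(nu, times, 23500.0, 22000.0)
            assert est == pytest.approx(float(a @ taus), abs=1e-5)

    def test_nondecaying_c_rejected(self):
        times = np.linspace(0, 10, 50)
        with pytest.raises(AnalysisError):
            integrated_relaxation_time(np.full(50, 22000.0), times, 23800.0, 21000.0)
        with pytest.raises(AnalysisError):
            integrated_relaxation_time(
                np.linspace(22000, 23000, 50), times, 23800.0, 21000.0
            )


class TestGeneratorAndEndToEnd:
    def test_seed_determinism(self):
        d1, irf1, ss1, _ = generate_synthetic_tdfs(seed=5)
        d2, irf2, ss2, _ = generate_synthetic_tdfs(seed=5)
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(ss1[1], ss2[1])

    def test_noiseless_delta_irf_identity_pipeline(self):
        decays, irf, ss, truth = generate_synthetic_tdfs(
            irf_fwhm=1e-4, irf_center=0.0, peak_counts=10_000_000, seed=0
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = tdfs.analyze_tdfs(decays, irf, ss, nu0=truth.nu0)
        assert res.delta_nu == pytest.approx(truth.delta_nu, abs=20.0)
        assert res.tau_ns == pytest.approx(truth.tau_ns, abs=0.05)

    def test_recovery_two_seeds_within_intrinsic_uncertainty(self):
        errs_d, errs_t = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in (101, 202):
                decays, irf, ss, truth = generate_synthetic_tdfs(seed=seed)
                res = tdfs.analyze_tdfs(decays, irf, ss, nu0=truth.nu0)
                errs_d.append(res.delta_nu - truth.delta_nu)
                errs_t.append(res.tau_ns - truth.tau_ns)
        assert np.max(np.abs(errs_d)) < 100.0
        assert np.max(np.abs(errs_t)) < 0.15


class TestLangmuirFreundlich:
    def test_langmuir_round_trip(self, rng):
        c = np.array([0.0, 1e-3, 5e-3, 0.025, 0.1, 0.2, 0.5, 1.0])
        truth = {"zeta0": -45.0, "zeta_max": 15.0, "K": 30.0, "n": 1.0}
        z = tdfs._lf_model(c, **truth)
        fit = fit_langmuir_freundlich(c, z)
        assert fit["K"] == pytest.approx(30.0, rel=0.01)
        assert fit["n"] == pytest.approx(1.0, rel=0.01)

    def test_limits(self):
        p = {"zeta0": -45.0, "zeta_max": 15.0, "K": 30.0, "n": 0.8}
        assert tdfs._lf_model(np.array([0.0]), **p)[0] == pytest.approx(-45.0)
        assert tdfs._lf_model(np.array([1e9]), **p)[0] == pytest.approx(15.0, abs=0.1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_langmuir_freundlich(np.arange(4.0), np.arange(4.0))
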