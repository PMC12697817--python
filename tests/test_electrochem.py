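"""Exponential fits, Randles impedance, EIS summaries, memory, t-tests."""

import numpy as np
import pytest

from protodyn.electrochem import (
    early_late_ttest,
    eis_summary,
    fit_dynamic_decay,
    fit_exponential_decay,
    memory_from_autocorrelation,
    percent_attenuation,
    randles_impedance,
    relaxation_frequency,
)
from protodyn.errors import DegenerateFitWarning, UsageError
from protodyn.signal_io import TimeSeries
from protodyn.synthetic import DecaySpec, gen_decay_series, gen_randles_spectrum


class TestExponentialFit:
    def test_noiseless_swv_parameters_recovered(self):
        grid = tuple(np.linspace(5, 50, 10))
        df = gen_decay_series(DecaySpec(y0=179.54, rate=0.0032, grid=grid))
        fit = fit_exponential_decay(df["x"], df["y"])
        assert fit.y0 == pytest.approx(179.54, rel=1e-6)
        assert fit.rate == pytest.approx(0.0032, rel=1e-6)
        assert fit.characteristic == pytest.approx(312.5, rel=1e-6)

    def test_two_point_closed_form(self):
        # rate = ln(176.10/154.30)/45 from the two endpoint currents,
        # then y0 follows from either point (oracle: closed form)
        rate = np.log(176.10 / 154.30) / 45.0
        y0 = 176.10 * np.exp(rate * 5.0)
        x = np.array([5.0, 27.5, 50.0])
        y = y0 * np.exp(-rate * x)
        fit = fit_exponential_decay(x, y)
        assert fit.rate == pytest.approx(rate, rel=1e-9)
        assert rate == pytest.approx(0.002937, abs=1e-6)

    def test_constant_input_degenerate_warning(self):
        with pytest.warns(DegenerateFitWarning):
            fit = fit_exponential_decay(np.arange(5.0), np.full(5, 3.0))
        assert fit.rate == 0.0
        assert fit.characteristic == np.inf

    def test_noise_recovery_within_three_se(self):
        # 50 seeds at 2% noise: recovered parameters unbiased within 3 SE
        grid = tuple(np.linspace(0, 200, 40))
        y0s, rates = [], []
        for seed in range(50):
            df = gen_decay_series(
                DecaySpec(y0=100.0, rate=0.01, grid=grid, noise_sd=2.0, seed=seed)
            )
            fit = fit_exponential_decay(df["x"], df["y"])
            y0s.append(fit.y0)
            rates.append(fit.rate)
        for est, truth in ((y0s, 100.0), (rates, 0.01)):
            est = np.asarray(est)
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 3 * se + 1e-12

    def test_offset_variant_recovery(self):
        x = np.linspace(0, 10, 30)
        y = 2.0 * np.exp(-0.8 * x) + 0.5
        fit = fit_exponential_decay(x, y, with_offset=True)
        assert fit.y0 == pytest.approx(2.0, rel=1e-6)
        assert fit.rate == pytest.approx(0.8, rel=1e-6)
        assert fit.offset == pytest.approx(0.5, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(UsageError):
            fit_exponential_decay([1, 2], [1.0, 0.5])


class TestPercentAttenuation:
    def test_study_swv_attenuation(self):
        assert percent_attenuation(176.10, 154.30) == pytest.approx(12.38, abs=0.005)

    @pytest.mark.parametrize("lo, hi, expected", [(5.0, 5.0, 0.0), (100, 50, 50.0)])
    def test_simple_cases(self, lo, hi, expected):
        assert percent_attenuation(lo, hi) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(UsageError):
            percent_attenuation(0.0, 1.0)


class TestRandles:
    def test_limits(self):
        assert randles_impedance(100, 5000, 1e-6, 0, 1e9).real == pytest.approx(
            100, rel=1e-3
        )
        assert randles_impedance(100, 5000, 1e-6, 0, 1e-9).real == pytest.approx(
            5100, rel=1e-6
        )

    def test_apex_identity(self):
        Rs, Rct, Cdl = 100.0, 5000.0, 1e-6
        z = randles_impedance(Rs, Rct, Cdl, 0.0, 1.0 / (2 * np.pi * Rct * Cdl))
        assert z.real == pytest.approx(Rs + Rct / 2, rel=1e-12)
        assert -z.imag == pytest.approx(Rct / 2, rel=1e-12)

    def test_warburg_adds_45_degree_tail(self):
        z = randles_impedance(0.0, 0.0, 0.0, 100.0, 0.01)
        assert z.real == pytest.approx(-z.imag, rel=1e-9)  # 45° line

    def test_relaxation_frequency(self):
        assert relaxation_frequency(1.0, 1.0 / (2 * np.pi)) == pytest.approx(1.0)
        f0 = relaxation_frequency(5250.0, 5.08e-8)
        assert f0 == pytest.approx(1 / (2 * np.pi * 5250 * 5.08e-8), rel=1e-12)
        assert relaxation_frequency(5250.0, 2 * 5.08e-8) == pytest.approx(
            f0 / 2, rel=1e-12
        )


class TestEisSummary:
    def test_known_moments(self):
        spec = gen_randles_spectrum(100, 5000, 1e-6, 0, np.logspace(0, 5, 40))
        summary = eis_summary(spec)
        assert summary.mean_zre == pytest.approx(spec["Zre_ohm"].mean())
        assert summary.sd_zim == pytest.approx(spec["Zim_ohm"].std(ddof=1))
        assert summary.ci95_zre[0] < summary.mean_zre < summary.ci95_zre[1]

    def test_duplicated_row_collapses_ci(self):
        import pandas as pd

        spec = pd.DataFrame({"f_Hz": [1.0, 1.0], "Zre_ohm": [5.0, 5.0],
                             "Zim_ohm": [-1.0, -1.0]})
        summary = eis_summary(spec)
        assert summary.sd_zre == 0.0
        assert summary.ci95_zre == (5.0, 5.0)

    def test_pure_resistor_phase(self):
        import pandas as pd

        spec = pd.DataFrame({"f_Hz": [1, 10, 100], "Zre_ohm": [50.0] * 3,
                             "Zim_ohm": [0.0] * 3})
        summary = eis_summary(spec)
        assert summary.mean_phase == pytest.approx(0.0)
        assert summary.sd_logmag == pytest.approx(0.0)


class TestMemory:
    def test_ar1_time_constant(self):
        # AR(1) closed form: R(lag) = φ^lag, so τ = −1/ln(φ).  The sample
        # ACF tail is noisy, so check the seed-averaged estimate.
        phi, n = 0.9, 10_000
        taus = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = np.empty(n)
            x[0] = 0.0
            eps = rng.normal(size=n)
            for i in range(1, n):
                x[i] = phi * x[i - 1] + eps[i]
            fit = memory_from_autocorrelation(TimeSeries(np.arange(float(n)), x))
            taus.append(fit.characteristic)
        tau_expected = -1.0 / np.log(phi)
        assert np.mean(taus) == pytest.approx(tau_expected, rel=0.10)

    def test_white_noise_has_short_memory(self):
        rng = np.random.default_rng(1)
        fit = memory_from_autocorrelation(
            TimeSeries(np.arange(4096.0), rng.normal(size=4096))
        )
        assert fit.characteristic < 2.0
        assert fit.y0 + fit.offset == pytest.approx(1.0, abs=0.1)  # R(0) = 1

    def test_exponential_signal_memory_matches_rate(self):
        k, n = 1e-3, 8192
        rng = np.random.default_rng(5)
        t = np.arange(float(n))
        vals = 5e-8 * np.exp(-k * t) + rng.normal(0, 1e-10, n)
        fit = memory_from_autocorrelation(TimeSeries(t, vals, unit="F"))
        assert fit.characteristic == pytest.approx(1.0 / k, rel=0.15)


class TestDynamicDecay:
    def test_study_reciprocal_identity(self):
        # τ = 322258.045248 s and k = 3.103103e−6 s⁻¹ are reciprocals
        assert 1.0 / 322258.045248 == pytest.approx(3.103103e-6, rel=1e-6)

    def test_noiseless_recovery_of_printed_parameters(self):
        t = np.arange(0.0, 500_000.0, 250.0)
        c = 5.273669e-8 * np.exp(-3.103103e-6 * t)
        fit = fit_dynamic_decay(TimeSeries(t, c, unit="F"))
        assert fit.y0 == pytest.approx(5.273669e-8, rel=1e-6)
        assert fit.rate == pytest.approx(3.103103e-6, rel=1e-6)
        assert fit.characteristic * fit.rate == pytest.approx(1.0, rel=1e-12)

    def test_zero_rate_degenerate(self):
        with pytest.warns(DegenerateFitWarning):
            fit = fit_dynamic_decay(TimeSeries(np.arange(32.0), np.full(32, 2e-8)))
        assert fit.rate == 0.0


class TestEarlyLateTtest:
    def test_identical_segments(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=500)
        s = TimeSeries(np.arange(1000.0), np.concatenate([half, half]))
        res = early_late_ttest(s)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(1)
        early = rng.normal(0, 0.1, 500)
        late = rng.normal(10, 0.1, 500)
        s = TimeSeries(np.arange(1000.0), np.concatenate([early, late]))
        res = early_late_ttest(s)
        assert res.p_value < 1e-6
        assert res.delta == pytest.approx(10.0, abs=0.1)

    @pytest.mark.parametrize("shift", [3.0, -3.0])
    def test_delta_sign_follows_shift(self, shift):
        rng = np.random.default_rng(2)
        early = rng.normal(0, 1, 200)
        late = early + shift
        s = TimeSeries(np.arange(400.0), np.concatenate([early, late]))
        assert np.sign(early_late_ttest(s).delta) == np.sign(shift)
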