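"""Methyl order parameters and MQ-CPMG relaxation dispersion."""

import numpy as np
import pytest

from nmrdyn import methyl
from nmrdyn.errors import ValidationError
from nmrdyn.series import IntensitySeries


class TestEtaRatioModel:
    def test_zero_eta_zero_ratio(self):
        assert np.all(methyl.eta_ratio_model(0.0, 2.0, [0.01, 0.02]) == 0.0)

    def test_long_time_limit_three_quarters(self):
        assert methyl.eta_ratio_model(10.0, 0.0, 100.0) == pytest.approx(
            0.75, abs=1e-6)

    def test_hand_value(self):
        # 0.75*tanh(10*0.01) at eta=10, delta=0, T=10 ms
        assert float(methyl.eta_ratio_model(10.0, 0.0, 0.010)) == \
            pytest.approx(0.0748, abs=5e-5)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValidationError):
            methyl.eta_ratio_model(-1.0, 0.0, 0.01)

    def test_strictly_increasing_and_bounded(self):
        t = np.linspace(0.001, 0.2, 50)
        r = methyl.eta_ratio_model(8.0, 0.0, t)
        assert np.all(np.diff(r) > 0)
        assert np.all(r < 0.75)


class TestEtaFit:
    def test_default_delay_grid_spans_2_to_24_ms(self):
        assert methyl.DEFAULT_ETA_DELAYS[0] == pytest.approx(0.002)
        assert methyl.DEFAULT_ETA_DELAYS[-1] == pytest.approx(0.024)
        assert len(methyl.DEFAULT_ETA_DELAYS) == 8

    def test_noiseless_exact_recovery(self):
        t = methyl.DEFAULT_ETA_DELAYS
        r = methyl.eta_ratio_model(10.0, 2.0, t)
        fit = methyl.fit_eta(IntensitySeries("m", t, r))
        assert fit.eta == pytest.approx(10.0, rel=1e-6)
        assert fit.delta == pytest.approx(2.0, rel=1e-5)

    def test_small_bias_at_two_percent_noise(self):
        rng = np.random.default_rng(3)
        t = methyl.DEFAULT_ETA_DELAYS
        clean = methyl.eta_ratio_model(10.0, 2.0, t)
        etas = []
        for _ in range(30):
            noisy = clean * (1 + rng.normal(0, 0.02, len(t)))
            etas.append(methyl.fit_eta(IntensitySeries("m", t, noisy)).eta)
        assert abs(np.mean(etas) - 10.0) / 10.0 < 0.05

    def test_flat_ratios_flagged_unidentifiable(self):
        t = methyl.DEFAULT_ETA_DELAYS
        fit = methyl.fit_eta(IntensitySeries("m", t, np.full(8, 1e-5),
                                             np.full(8, 1e-3)))
        assert not fit.identifiable


class TestS2Tauc:
    def test_zero_eta_zero_product(self):
        assert methyl.s2tauc_from_eta(0.0)[0] == 0.0

    def test_constant_from_codata(self):
        # independent evaluation of (9/10)(mu0/4pi)^2 P2(0)^2 gH^4 hbar^2/rHH^6
        # gives 3.609e9 1/s^2, so eta = 10.8 1/s maps to ~3.0 ns
        assert methyl.s2tauc_from_eta(10.8)[0] == pytest.approx(2.9925,
                                                                abs=2e-3)

    def test_round_trip_with_forward(self):
        eta = methyl.eta_from_s2tauc(3.0)
        assert methyl.s2tauc_from_eta(eta)[0] == pytest.approx(3.0,
                                                               rel=1e-12)

    def test_s2_axis_given_tauc(self):
        t = methyl.DEFAULT_ETA_DELAYS
        eta = methyl.eta_from_s2tauc(3.0)
        r = methyl.eta_ratio_model(eta, 1.0, t)
        fit = methyl.fit_eta(IntensitySeries("m", t, r), tauc_ns=14.4)
        assert fit.s2_axis == pytest.approx(3.0 / 14.4, rel=1e-4)
        assert 0.0 <= fit.s2_axis <= 1.0


class TestR2eff:
    def test_equal_intensities_zero(self):
        assert methyl.r2eff_from_intensities(1.0, 1.0) == pytest.approx(0.0)

    def test_half_intensity_hand_value(self):
        # ln2 / 0.03 s
        assert float(methyl.r2eff_from_intensities(0.5, 1.0, 0.030)) == \
            pytest.approx(23.10, abs=0.005)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError):
            methyl.r2eff_from_intensities(0.0, 1.0)


NU_GRID = np.array([67.0, 133.0, 267.0, 500.0, 1000.0])


class TestDispersionForward:
    def test_zero_minor_population_flat(self):
        pars = methyl.TwoSiteExchangeParams(0.0, 1000.0, 1.0, r2_0=12.0)
        prof = methyl.mq_dispersion_forward(pars, NU_GRID)
        assert prof == pytest.approx(np.full(5, 12.0))

    def test_zero_shift_difference_flat(self):
        pars = methyl.TwoSiteExchangeParams(0.05, 1000.0, 0.0, 0.0, 12.0)
        prof = methyl.mq_dispersion_forward(pars, NU_GRID)
        assert prof == pytest.approx(np.full(5, 12.0), abs=1e-8)

    def test_fast_exchange_matches_luz_meiboom(self):
        pars = methyl.TwoSiteExchangeParams(0.1, 20000.0, 1.0, 0.0, 10.0)
        prop = methyl.mq_dispersion_forward(pars, NU_GRID)
        closed = methyl.luz_meiboom_r2eff(pars, NU_GRID)
        assert np.max(np.abs(prop - closed) / closed) < 0.01

    @pytest.mark.parametrize("kex,pmin,dw", [(500.0, 0.05, 1.0),
                                             (2000.0, 0.02, 2.0),
                                             (5000.0, 0.10, 0.5)])
    def test_nonincreasing_in_nu(self, kex, pmin, dw):
        pars = methyl.TwoSiteExchangeParams(pmin, kex, dw, r2_0=15.0)
        nu = np.arange(4, 62, 2) / (2 * 0.030)  # dense attainable grid
        prof = methyl.mq_dispersion_forward(pars, nu)
        assert np.all(np.diff(prof) < 1e-6)

    def test_amplitude_linear_in_p_minor(self):
        amps = []
        for pmin in (0.005, 0.01, 0.02):
            pars = methyl.TwoSiteExchangeParams(pmin, 500.0, 1.0, r2_0=15.0)
            prof = methyl.mq_dispersion_forward(pars, NU_GRID)
            amps.append(prof[0] - prof[-1])
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.1)
        assert amps[2] / amps[1] == pytest.approx(2.0, rel=0.1)


class TestDispersionGlobalFit:
    def test_noiseless_round_trip(self):
        kex = 500.0
        profiles = []
        for i, dw in enumerate((0.8, 1.5)):
            pars = methyl.TwoSiteExchangeParams(0.05, kex, dw, r2_0=15.0)
            r2 = methyl.mq_dispersion_forward(pars, NU_GRID)
            profiles.append(methyl.DispersionProfile(f"m{i}", NU_GRID, r2))
        fit = methyl.fit_dispersion_global(profiles)
        assert fit.k_ex == pytest.approx(kex, rel=1e-3)
        assert fit.p_minor == pytest.approx(0.05, rel=1e-3)
        assert fit.dw_c_ppm["m0"] == pytest.approx(0.8, rel=1e-3)
        assert fit.tau_ex_ms == pytest.approx(2.0, rel=1e-3)

    def test_single_flat_profile_unidentifiable(self):
        prof = methyl.DispersionProfile(
            "flat", NU_GRID, np.full(5, 12.0), np.full(5, 0.2))
        fit = methyl.fit_dispersion_global([prof])
        assert not fit.identifiable
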