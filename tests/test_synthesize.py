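"""Synthetic-data generator: forward-model consistency, determinism,
recovery scoring."""

import numpy as np
import pytest

from nmrdyn import binding, diffusion, exsy, methyl, relaxation, thermo
from nmrdyn import synthesize as syn
from nmrdyn.errors import ValidationError


class TestSpecValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError, match="unknown experiment kind"):
            syn.GeneratorSpec(kind="fid", seed=1)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            syn.GeneratorSpec(kind="exsy", seed=1, noise=-0.1)


class TestNoiselessConsistency:
    """sigma = 0 output lies exactly on each module's forward model."""

    def test_relaxation_decay(self):
        s, man = syn.generate(syn.GeneratorSpec("relaxation_decay", seed=1,
                                                noise=0.0))
        truth = man["truth"]
        assert s.intensity == pytest.approx(
            truth["i0"] * np.exp(-truth["rate"] * s.x))

    def test_eta_ratio(self):
        s, man = syn.generate(syn.GeneratorSpec("eta_ratio", seed=1,
                                                noise=0.0))
        truth = man["truth"]
        assert s.intensity == pytest.approx(methyl.eta_ratio_model(
            truth["eta"], truth["delta"], s.x))

    def test_exsy(self):
        ds, man = syn.generate(syn.GeneratorSpec("exsy", seed=1, noise=0.0))
        t = man["truth"]
        model = exsy.exsy_model(t["k_lo"], t["k_ol"], t["r1_l"], t["r1_o"],
                                t["i_l0"], t["i_o0"], ds.mixing_times)
        assert ds.i_ll == pytest.approx(model[0])
        assert ds.i_lo == pytest.approx(model[2])
        assert ds.mixing_times[0] == pytest.approx(0.05)
        assert ds.mixing_times[-1] == pytest.approx(1.0)

    def test_cpmg(self):
        profiles, man = syn.generate(syn.GeneratorSpec("cpmg", seed=1,
                                                       noise=0.0))
        t = man["truth"]
        for prof, dw in zip(profiles, t["dw_c_ppm"]):
            pars = methyl.TwoSiteExchangeParams(t["p_minor"], t["k_ex"],
                                                dw, r2_0=t["r2_0"])
            assert prof.r2eff == pytest.approx(methyl.mq_dispersion_forward(
                pars, prof.nu_cpmg, prof.field_1h_mhz, prof.ct_period))
        assert profiles[0].nu_cpmg.min() >= 66.0
        assert profiles[0].nu_cpmg.max() <= 1000.0

    def test_thermal(self):
        series, man = syn.generate(syn.GeneratorSpec("thermal", seed=1,
                                                     noise=0.0))
        t = man["truth"]
        for s in series:
            amp, base = t["probes"][s.probe_id]
            assert s.intensity == pytest.approx(
                base + amp * thermo.two_state_population(
                    s.x, t["delta_h_kj"], t["delta_s_kj_per_k"]))

    def test_gradient(self):
        gs, man = syn.generate(syn.GeneratorSpec("gradient", seed=1,
                                                 noise=0.0))
        t = man["truth"]
        assert gs.intensity == pytest.approx(t["i0"] * np.exp(
            -diffusion.stejskal_tanner_b(gs) * t["d_cm2_s"]))

    def test_isotherm_and_sensorgram(self):
        (c, r), man = syn.generate(syn.GeneratorSpec("isotherm", seed=1,
                                                     noise=0.0))
        t = man["truth"]
        assert r == pytest.approx(t["r_max"] * c / (t["k_d"] + c))
        sgs, man = syn.generate(syn.GeneratorSpec("sensorgram", seed=1,
                                                  noise=0.0))
        t = man["truth"]
        sg = sgs[0]
        assert sg.response == pytest.approx(binding.model_sensorgram(
            t["k_on"], t["k_off"], t["r_max"], sg.concentration, sg.time))


class TestDeterminism:
    @pytest.mark.parametrize("kind", ["relaxation_decay", "exsy", "thermal",
                                      "gradient", "isotherm"])
    def test_same_seed_identical(self, kind):
        a, _ = syn.generate(syn.GeneratorSpec(kind, seed=42, noise=0.02))
        b, _ = syn.generate(syn.GeneratorSpec(kind, seed=42, noise=0.02))

        def values(obj):
            if isinstance(obj, tuple):
                return obj[1]
            if isinstance(obj, list):
                return np.concatenate([values(o) for o in obj])
            for attr in ("intensity", "i_ll", "response"):
                if hasattr(obj, attr):
                    return np.asarray(getattr(obj, attr))
            raise AssertionError
        assert np.array_equal(values(a), values(b))

    def test_different_seed_differs(self):
        a, _ = syn.generate(syn.GeneratorSpec("exsy", seed=1, noise=0.02))
        b, _ = syn.generate(syn.GeneratorSpec("exsy", seed=2, noise=0.02))
        assert not np.array_equal(a.i_ll, b.i_ll)


class TestNoiseScaling:
    def test_rmse_grows_with_noise(self):
        # recovered diffusion coefficient RMSE is monotone over sigma
        rmses = []
        for noise in (0.005, 0.02, 0.05):
            errs = []
            for seed in range(15):
                gs, man = syn.generate(syn.GeneratorSpec(
                    "gradient", seed=9000 + seed, noise=noise))
                d = diffusion.fit_diffusion(gs).d_obs
                errs.append((d - man["truth"]["d_cm2_s"]) ** 2)
            rmses.append(np.sqrt(np.mean(errs)))
        assert rmses[0] < rmses[1] < rmses[2]


class TestRecoveryReport:
    def test_perfect_recovery_zero_bias_rmse(self):
        report = syn.recovery_report(
            {"rate": 1.82},
            [{"rate": (1.82, 0.05)} for _ in range(10)])
        assert report.loc["rate", "bias"] == pytest.approx(0.0, abs=1e-12)
        assert report.loc["rate", "rmse"] == pytest.approx(0.0, abs=1e-12)
        assert report.loc["rate", "coverage"] == 1.0

    def test_gaussian_one_sigma_coverage(self):
        # standard-normal oracle: |x| <= 1 with probability ~0.6827
        rng = np.random.default_rng(12)
        n = 2000
        estimates = [{"mu": (float(x), 1.0)} for x in rng.normal(0, 1, n)]
        report = syn.recovery_report({"mu": 0.0}, estimates)
        cover = report.loc["mu", "coverage"]
        binom_sd = np.sqrt(0.6827 * 0.3173 / n)
        assert abs(cover - 0.6827) < 4 * binom_sd

    def test_empty_estimates_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            syn.recovery_report({"a": 1.0}, [])

    def test_mismatched_parameter_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            syn.recovery_report({"a": 1.0}, [{"b": (1.0, 0.1)}])


class TestGlobalRoundTrip:
    """Every fit run on sigma=0 generator output recovers the truth."""

    def test_relaxation(self):
        s, man = syn.generate(syn.GeneratorSpec("relaxation_decay", seed=3,
                                                noise=0.0))
        rate, _ = relaxation.fit_exponential_decay(s)
        assert rate == pytest.approx(man["truth"]["rate"], rel=1e-6)

    def test_eta(self):
        s, man = syn.generate(syn.GeneratorSpec("eta_ratio", seed=3,
                                                noise=0.0))
        fit = methyl.fit_eta(s)
        assert fit.s2_tauc_ns == pytest.approx(man["truth"]["s2_tauc_ns"],
                                               rel=1e-4)

    def test_exsy(self):
        ds, man = syn.generate(syn.GeneratorSpec("exsy", seed=3, noise=0.0))
        fit = exsy.fit_exsy(ds)
        assert fit.k_ol == pytest.approx(man["truth"]["k_ol"], rel=1e-3)

    def test_thermo(self):
        sl, man = syn.generate(syn.GeneratorSpec("thermal", seed=3,
                                                 noise=0.0))
        fit = thermo.fit_two_state(sl)
        assert fit.delta_h_kj == pytest.approx(man["truth"]["delta_h_kj"],
                                               rel=1e-5)

    def test_binding(self):
        (c, r), man = syn.generate(syn.GeneratorSpec("isotherm", seed=3,
                                                     noise=0.0))
        fit = binding.fit_steady_state(c, r)
        assert fit.k_d == pytest.approx(man["truth"]["k_d"], rel=1e-5)
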