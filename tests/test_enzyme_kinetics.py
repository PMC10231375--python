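import numpy as np
import pytest

from mepflux import (
    MMKinetics,
    ProgressCurve,
    dmadp_idp_ratio,
    efficiency_fold,
    fit_lineweaver_burk,
    fit_mm_nls,
    fit_progress_curve,
    kcat_from_vmax,
    with_kcat,
)
from mepflux.exceptions import (
    AllZeroProductError,
    InsufficientLevelsError,
    MissingEnzymeMolarityError,
    MissingKcatError,
    ZeroDmadpError,
    ZeroVelocityError,
)


def mm_v(s, vmax=10.0, km=5.0):
    return vmax * np.asarray(s, dtype=float) / (km + np.asarray(s, dtype=float))


S_LEVELS = np.array([1.0, 2.0, 5.0, 10.0, 50.0])


class TestFitProgressCurve:
    def test_exact_box_lucas(self):
        t = np.linspace(0.0, 10.0, 12)
        pc = ProgressCurve(t, 10.0 * (1 - np.exp(-0.5 * t)), substrate_conc=5.0)
        fit = fit_progress_curve(pc)
        assert fit.a == pytest.approx(10.0, rel=1e-6)
        assert fit.b == pytest.approx(0.5, rel=1e-6)
        assert fit.v0 == pytest.approx(5.0, rel=1e-6)

    def test_short_linear_window(self):
        # y = 3t on [0, 0.2]: a, b individually flat, but v0 = a*b ~ slope
        t = np.linspace(0.0, 0.2, 6)
        pc = ProgressCurve(t, 3.0 * t, substrate_conc=5.0)
        fit = fit_progress_curve(pc)
        assert fit.v0 == pytest.approx(3.0, rel=0.02)

    def test_noisy_recovery(self):
        t = np.linspace(0.0, 10.0, 12)
        clean = 10.0 * (1 - np.exp(-0.5 * t))
        rng = np.random.default_rng(11)
        pc = ProgressCurve(t, np.clip(clean * (1 + 0.02 * rng.standard_normal(t.size)), 0, None),
                           substrate_conc=5.0)
        assert fit_progress_curve(pc).v0 == pytest.approx(5.0, rel=0.10)

    def test_all_zero_product(self):
        pc = ProgressCurve(np.arange(5.0), np.zeros(5), substrate_conc=1.0)
        with pytest.raises(AllZeroProductError):
            fit_progress_curve(pc)

    def test_too_few_points(self):
        pc = ProgressCurve(np.arange(3.0), np.array([0.0, 1.0, 2.0]), substrate_conc=1.0)
        with pytest.raises(ValueError):
            fit_progress_curve(pc)


class TestFitMMNls:
    def test_exact_recovery(self):
        kin = fit_mm_nls(S_LEVELS, mm_v(S_LEVELS))
        assert kin.km == pytest.approx(5.0, abs=1e-6)
        assert kin.vmax == pytest.approx(10.0, abs=1e-6)
        assert kin.method == "nonlinear"

    def test_half_saturation_identity(self):
        kin = fit_mm_nls(S_LEVELS, mm_v(S_LEVELS))
        v_at_km = kin.vmax * kin.km / (kin.km + kin.km)
        assert v_at_km == pytest.approx(kin.vmax / 2)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(1)
        v = mm_v(S_LEVELS) * (1 + 0.05 * rng.standard_normal(S_LEVELS.size))
        kin = fit_mm_nls(S_LEVELS, v)
        assert kin.km == pytest.approx(5.0, rel=0.15)
        assert kin.vmax == pytest.approx(10.0, rel=0.15)

    def test_insufficient_levels(self):
        with pytest.raises(InsufficientLevelsError):
            fit_mm_nls(np.array([1.0, 1.0, 2.0]), np.array([1.0, 1.0, 2.0]))


class TestFitLineweaverBurk:
    def test_noiseless_equivalence_with_nls(self):
        v = mm_v(S_LEVELS)
        lb = fit_lineweaver_burk(S_LEVELS, v)
        nls = fit_mm_nls(S_LEVELS, v)
        assert lb.km == pytest.approx(nls.km, rel=1e-9)
        assert lb.vmax == pytest.approx(nls.vmax, rel=1e-9)
        assert lb.method == "lineweaver_burk"

    def test_heteroscedastic_divergence_documented(self):
        # LB reweights errors via reciprocals; with noise the two estimators
        # need not agree (no numeric assertion on the gap, only that both run)
        rng = np.random.default_rng(42)
        v = mm_v(S_LEVELS) * (1 + 0.1 * rng.standard_normal(S_LEVELS.size))
        lb = fit_lineweaver_burk(S_LEVELS, v)
        nls = fit_mm_nls(S_LEVELS, v)
        assert lb.km > 0 and nls.km > 0

    def test_zero_velocity_rejected(self):
        with pytest.raises(ZeroVelocityError):
            fit_lineweaver_burk(S_LEVELS, np.array([0.0, 1.0, 2.0, 3.0, 4.0]))


class TestKcat:
    def test_simple_division(self):
        assert kcat_from_vmax(1.0, 0.05) == pytest.approx(20.0)

    def test_zero_vmax(self):
        assert kcat_from_vmax(0.0, 0.3) == 0.0

    def test_round_trip(self):
        assert kcat_from_vmax(62.0 * 0.01, 0.01) == pytest.approx(62.0)

    def test_missing_molarity(self):
        with pytest.raises(MissingEnzymeMolarityError):
            kcat_from_vmax(1.0, 0.0)

    def test_with_kcat_attaches_efficiency(self):
        kin = with_kcat(MMKinetics(km=5.0, vmax=10.0), enzyme_molar=0.5)
        assert kin.kcat == pytest.approx(20.0)
        assert kin.efficiency == pytest.approx(4.0)


class TestEfficiencyFold:
    def test_published_constants_give_sevenfold(self):
        # Km 6.0 uM / kcat 62.0 min^-1 vs Km 21.4 uM / kcat 31.6 min^-1
        e1 = MMKinetics(km=6.0, vmax=1.0, kcat=62.0)
        e2 = MMKinetics(km=21.4, vmax=1.0, kcat=31.6)
        fold = efficiency_fold(e1, e2)
        assert fold == pytest.approx(6.998, abs=1e-3)
        assert round(fold) == 7

    def test_identical_enzymes(self):
        e = MMKinetics(km=5.0, vmax=1.0, kcat=10.0)
        assert efficiency_fold(e, e) == 1.0

    def test_second_enzyme_pair_hand_value(self):
        # (28.0/21.2) / (7.8/15.9) = 2.6923 by hand
        e1 = MMKinetics(km=21.2, vmax=1.0, kcat=28.0)
        e2 = MMKinetics(km=15.9, vmax=1.0, kcat=7.8)
        assert efficiency_fold(e1, e2) == pytest.approx(2.6923, abs=1e-3)

    def test_missing_kcat(self):
        with pytest.raises(MissingKcatError):
            efficiency_fold(MMKinetics(km=1.0, vmax=1.0), MMKinetics(km=1.0, vmax=1.0, kcat=2.0))


class TestProductRatio:
    def test_one_to_twentyone(self):
        r = dmadp_idp_ratio(2.0, 42.0)
        assert r.normalized == (1.0, 21.0)
        assert r.render() == "1:21"

    def test_one_to_six(self):
        assert dmadp_idp_ratio(5.0, 30.0).render() == "1:6"

    def test_zero_idp(self):
        assert dmadp_idp_ratio(1.0, 0.0).render() == "1:0"

    def test_one_decimal_option(self):
        assert dmadp_idp_ratio(2.0, 13.0).render(decimals=1) == "1:6.5"

    def test_zero_dmadp_rejected(self):
        with pytest.raises(ZeroDmadpError):
            dmadp_idp_ratio(0.0, 5.0)


class TestRecoveryProperties:
    def test_km_recovery_ensemble(self):
        # 100 seeded assays, 5% CV on v0: median |Km error| <= 10%
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = mm_v(S_LEVELS) * (1 + 0.05 * rng.standard_normal(S_LEVELS.size))
            kin = fit_mm_nls(S_LEVELS, np.clip(v, 1e-9, None))
            errors.append(abs(kin.km - 5.0) / 5.0)
        assert np.median(errors) <= 0.10

    def test_v0_converges_to_mm_rate_as_window_shrinks(self):
        # BoxLucas v0 on simulated depletion curves approaches Vmax*S0/(Km+S0)
        # monotonically as the sampling window shrinks
        from mepflux.synthetic_data import AssaySimConfig, simulate_assay

        s0 = 5.0
        target = float(mm_v(s0))
        errs = []
        for t_max in (2.0, 0.5):
            times = np.linspace(0.0, t_max, 9)[1:]
            cfg = AssaySimConfig(km=5.0, vmax=10.0, substrate_levels=[s0], times=times,
                                 noise_cv=0.0, seed=0)
            curves, _ = simulate_assay(cfg)
            v0 = fit_progress_curve(curves[0]).v0
            errs.append(abs(v0 - target) / target)
        assert errs[1] < errs[0]
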