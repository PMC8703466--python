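"""Inner-filter correction, Stern-Volmer, mechanism and double-log fits."""

import numpy as np
import pytest

from specbind.datamodel import AnalysisConfig, TitrationPoint, TitrationSeries, ValidationError
from specbind.quenching import (
    SternVolmerResult,
    classify_mechanism,
    double_log_fit,
    inner_filter_correct,
    stern_volmer_fit,
)
from specbind.simulate import GroundTruth, simulate_binding_equilibrium, simulate_titration


class TestInnerFilter:
    def test_zero_absorbance_is_identity(self, make_series):
        s = make_series([0, 1e-6], [1000.0, 900.0], corrected=False,
                        absorbances=[(0.0, 0.0), (0.0, 0.0)])
        c = inner_filter_correct(s)
        assert [p.F_obs for p in c.points] == [1000.0, 900.0]
        assert c.corrected

    def test_worked_correction_factor(self, make_series):
        # A_ex = A_em = 0.1 -> factor 10**0.06
        s = make_series([0, 1e-6], [1000.0, 100.0], corrected=False,
                        absorbances=[(0.0, 0.0), (0.1, 0.1)])
        c = inner_filter_correct(s)
        assert c.points[1].F_obs == pytest.approx(100.0 * 10**0.06, rel=1e-12)
        assert c.points[1].F_obs == pytest.approx(114.815, abs=0.001)

    def test_factor_never_below_one(self, make_series):
        rng = np.random.default_rng(3)
        absorb = [(rng.uniform(0, 0.5), rng.uniform(0, 0.5)) for _ in range(6)]
        F = 1000.0 - 50.0 * np.arange(6)
        s = make_series(np.arange(6) * 1e-6, F, corrected=False, absorbances=absorb)
        c = inner_filter_correct(s)
        assert all(cp.F_obs >= p.F_obs for cp, p in zip(c.points, s.points))

    def test_double_correction_guarded(self, make_series):
        s = make_series([0, 1e-6], [1000.0, 900.0], corrected=False,
                        absorbances=[(0.0, 0.0), (0.1, 0.1)])
        c = inner_filter_correct(s)
        with pytest.raises(ValidationError, match="already"):
            inner_filter_correct(c)

    def test_missing_absorbances_pass_through_with_warning(self, make_series):
        s = make_series([0, 1e-6], [1000.0, 900.0], corrected=False)
        with pytest.warns(UserWarning, match="lack absorbances"):
            c = inner_filter_correct(s)
        assert c.points[1].F_obs == 900.0

    def test_simulated_attenuation_restored(self, truth, ligand_grid):
        clean = simulate_titration(truth, 4e-6, ligand_grid, noise=False)
        attenuated = simulate_titration(truth, 4e-6, ligand_grid, noise=False,
                                        inner_filter=True)
        restored = inner_filter_correct(attenuated)
        np.testing.assert_allclose(restored.intensity, clean.intensity, rtol=1e-12)


class TestSternVolmer:
    def test_exact_linear_recovery(self, make_series):
        ksv = 1.9e4
        lig = np.arange(10) * 1e-6
        F = 1000.0 / (1.0 + ksv * lig)
        r = stern_volmer_fit(make_series(lig, F))
        assert r.K_SV == pytest.approx(ksv, rel=1e-12)
        assert r.intercept == pytest.approx(1.0, rel=1e-12)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_intensity_gives_zero_slope(self, make_series):
        lig = np.arange(5) * 1e-6
        r = stern_volmer_fit(make_series(lig, np.full(5, 1000.0)))
        assert r.K_SV == pytest.approx(0.0, abs=1e-12)
        assert r.intercept == pytest.approx(1.0)

    def test_kq_from_tau0_matches_table_scale(self, make_series):
        # K_SV = 1.9e4 M^-1 with tau0 = 2.13 ns gives k_q ~ 8.9e12 M^-1 s^-1
        lig = np.arange(10) * 1e-6
        F = 1000.0 / (1.0 + 1.9e4 * lig)
        r = stern_volmer_fit(make_series(lig, F), tau0=2.13e-9)
        assert r.k_q == pytest.approx(1.9e4 / 2.13e-9, rel=1e-12)
        assert r.k_q == pytest.approx(8.9e12, rel=0.01)

    def test_too_few_points_rejected(self, make_series):
        s = make_series([0, 1e-6], [1000.0, 900.0])
        with pytest.raises(ValidationError, match="3 points"):
            stern_volmer_fit(s)

    def test_uncorrected_series_rejected_by_default(self, make_series):
        s = make_series([0, 1e-6, 2e-6], [1000.0, 900.0, 800.0], corrected=False)
        with pytest.raises(ValidationError, match="uncorrected"):
            stern_volmer_fit(s)
        assert stern_volmer_fit(s, require_corrected=False).K_SV > 0


def _sv(T, ksv, se=100.0, kq=None):
    return SternVolmerResult(
        K_SV=ksv, K_SV_se=se, intercept=1.0, intercept_se=0.01,
        temperature=T, r_squared=0.999, k_q=kq,
        k_q_se=None if kq is None else kq * 0.01,
    )


class TestMechanism:
    def test_static_signature(self):
        # Ksv decreasing with T, flat lifetime ratios, k_q >> diffusion limit
        svs = [_sv(283, 1.9e4, kq=8.9e12), _sv(293, 1.5e4, kq=6.9e12),
               _sv(303, 1.0e4, kq=4.3e12)]
        ratios = [(1.0, 1.0), (1.2, 1.01), (1.45, 0.98)]
        v = classify_mechanism(svs, ratios)
        assert v.verdict == "static"
        assert v.ksv_decreasing and v.tau_ratio_flat and v.kq_exceeds_limit

    def test_dynamic_signature(self):
        svs = [_sv(283, 1.0e4, kq=5e9), _sv(293, 1.5e4, kq=6e9), _sv(303, 1.9e4, kq=7e9)]
        ratios = [(1.0, 1.0), (1.3, 1.3), (1.6, 1.6)]
        assert classify_mechanism(svs, ratios).verdict == "dynamic"

    def test_contradictory_signals_are_ambiguous(self):
        svs = [_sv(283, 1.9e4, kq=5e9), _sv(293, 1.5e4, kq=5e9), _sv(303, 1.0e4, kq=5e9)]
        assert classify_mechanism(svs).verdict == "ambiguous"

    def test_single_temperature_is_ambiguous(self):
        assert classify_mechanism([_sv(293, 1.5e4)]).verdict == "ambiguous"

    def test_verdict_invariant_under_input_order(self):
        svs = [_sv(283, 1.9e4, kq=8.9e12), _sv(293, 1.5e4, kq=6.9e12),
               _sv(303, 1.0e4, kq=4.3e12)]
        ratios = [(1.3, 1.0), (1.1, 1.02)]
        base = classify_mechanism(svs, ratios).verdict
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            assert classify_mechanism([svs[i] for i in perm], ratios).verdict == base

    def test_insignificant_trend_not_counted(self):
        # overlapping error bars: drop not beyond combined se
        svs = [_sv(283, 1.55e4, se=500.0), _sv(293, 1.5e4, se=600.0)]
        v = classify_mechanism(svs)
        assert v.ksv_decreasing is False


class TestDoubleLog:
    def test_noise_free_one_to_one_recovery(self, truth):
        # (F0-F)/F = K_a x at n=1; exact inverse of the generator
        s = simulate_binding_equilibrium(truth, 4e-6, np.linspace(1e-6, 3e-5, 20))
        r = double_log_fit(s)
        assert r.n_stoich == pytest.approx(1.0, rel=1e-9)
        assert r.K_a == pytest.approx(truth.K_a, rel=1e-9)

    def test_cooperative_exponent_recovered(self):
        truth = GroundTruth(n_stoich=1.5, K_a=3e4)
        s = simulate_binding_equilibrium(truth, 4e-6, np.linspace(1e-6, 3e-5, 20))
        r = double_log_fit(s)
        assert r.n_stoich == pytest.approx(1.5, rel=1e-9)
        assert r.K_a == pytest.approx(3e4, rel=1e-9)

    def test_table_ordering_reproduced(self, truth):
        # K_a decreasing with temperature (2.5 -> 2.2 -> 1.8 x 1e4 M^-1 pattern)
        kas = {}
        for T in (283.0, 293.0, 303.0):
            s = simulate_binding_equilibrium(truth, 4e-6, np.linspace(1e-6, 3e-5, 20),
                                             temperature=T)
            kas[T] = double_log_fit(s).K_a
        assert kas[283.0] > kas[293.0] > kas[303.0]
        assert kas[293.0] == pytest.approx(2.2e4, rel=1e-6)

    def test_one_percent_noise_within_three_se(self, truth):
        rng = np.random.default_rng(11)
        t = GroundTruth(noise_rel_intensity=0.01)
        s = simulate_binding_equilibrium(t, 4e-6, np.linspace(1e-6, 3e-5, 24),
                                         rng=rng, noise=True)
        r = double_log_fit(s)
        assert abs(r.K_a - t.K_a) < 3 * r.K_a_se
        assert abs(r.n_stoich - 1.0) < 3 * r.n_stoich_se

    def test_no_quenching_rejected(self, make_series):
        s = make_series(np.arange(6) * 1e-6, np.full(6, 1000.0))
        with pytest.raises(ValidationError, match="no quenching"):
            double_log_fit(s)
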