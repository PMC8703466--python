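"""IDF inversion, Scatchard diagnostics and Hill cooperative fits."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from specbind.datamodel import TitrationPoint, TitrationSeries, ValidationError
from specbind.idf import (
    IDFPoint,
    QuenchCurve,
    delta_f,
    hill_fit,
    idf_hill_analysis,
    idf_invert,
    scatchard,
)
from specbind.simulate import (
    GroundTruth,
    hill_binding_density,
    simulate_titration,
)


def _isotherm_points(n, kb, h, n_pts=12, span=(0.2, 5.0)):
    """IDF points lying exactly on a Hill isotherm around half-saturation."""
    x = np.geomspace(span[0] / kb, span[1] / kb, n_pts)
    nu = hill_binding_density(x, n, kb, h)
    return [IDFPoint(float(v / n), float(xx), float(v)) for xx, v in zip(x, nu)]


def _stub_curve(protein, c, s=1.0, hi=1.0):
    """QuenchCurve with a known logistic, for hand-checkable inversions."""
    lig = np.concatenate([[0.0], np.geomspace(1e-7, 1e-3, 12)])
    pts = tuple(TitrationPoint(float(l), 1000.0 - i) for i, l in enumerate(lig))
    series = TitrationSeries(protein, 293.0, pts, corrected=True)
    return QuenchCurve(series, np.zeros(len(lig)), (0.0, hi, c, s), "logistic4", 1.0)


class TestDeltaF:
    def test_no_quenching_is_error(self, make_series):
        s = make_series(np.arange(6) * 1e-6, np.full(6, 1000.0))
        with pytest.raises(ValidationError, match="dF is zero"):
            delta_f(s)

    def test_fractional_quenching_values(self, make_series):
        s = make_series([0, 1e-6, 2e-6], [1000.0, 700.0, 500.0])
        q = delta_f(s)
        assert q.dF[0] == 0.0
        assert q.dF[1] == pytest.approx(0.30)
        assert q.dF[2] == pytest.approx(0.50)

    def test_higher_protein_curve_lies_right(self, truth, ligand_grid):
        # at equal dF the 8 uM titration needs more total ligand than 6 uM
        cA = delta_f(simulate_titration(truth, 6e-6, ligand_grid, noise=False))
        cB = delta_f(simulate_titration(truth, 8e-6, ligand_grid, noise=False))
        lo = max(cA.dF_range()[0], cB.dF_range()[0])
        hi = min(cA.dF_range()[1], cB.dF_range()[1])
        for level in np.linspace(lo + 0.01, hi - 0.01, 5):
            assert cB.invert(level) > cA.invert(level)

    def test_nonmonotone_warns_but_fits(self, make_series):
        F = [1000.0, 900.0, 930.0, 700.0, 600.0, 550.0]
        s = make_series(np.arange(6) * 1e-6, F)
        with pytest.warns(UserWarning, match="decreases"):
            q = delta_f(s)
        assert q.params is not None


class TestIdfInvert:
    def test_hand_solved_mass_conservation(self):
        # curves built so that dF=0.5 maps to [L] = 1.0e-5 and 1.2e-5 M
        cA = _stub_curve(6e-6, c=np.log10(1.0e-5))
        cB = _stub_curve(8e-6, c=np.log10(1.2e-5))
        (pt,) = idf_invert(cA, cB, levels=[0.5])
        assert pt.binding_density == pytest.approx(1.0, rel=1e-9)
        assert pt.ppl_free == pytest.approx(4.0e-6, rel=1e-9)

    def test_identical_curves_give_zero_binding_density(self):
        cA = _stub_curve(6e-6, c=-5.0)
        cB = _stub_curve(8e-6, c=-5.0)
        (pt,) = idf_invert(cA, cB, levels=[0.5])
        assert pt.binding_density == pytest.approx(0.0, abs=1e-12)
        assert pt.ppl_free == pytest.approx(1e-5, rel=1e-9)

    def test_swap_invariance(self, truth, ligand_grid):
        cA = delta_f(simulate_titration(truth, 6e-6, ligand_grid, noise=False))
        cB = delta_f(simulate_titration(truth, 8e-6, ligand_grid, noise=False))
        pts_ab = idf_invert(cA, cB)
        pts_ba = idf_invert(cB, cA)
        for a, b in zip(pts_ab, pts_ba):
            assert a.binding_density == pytest.approx(b.binding_density, rel=1e-9)
            assert a.ppl_free == pytest.approx(b.ppl_free, rel=1e-9)

    def test_equal_protein_concentrations_rejected(self):
        cA = _stub_curve(6e-6, c=-5.0)
        cB = _stub_curve(6e-6, c=-4.9)
        with pytest.raises(ValidationError, match="distinct"):
            idf_invert(cA, cB)

    def test_out_of_range_levels_dropped_with_warning(self):
        cA = _stub_curve(6e-6, c=-5.0)
        cB = _stub_curve(8e-6, c=-4.9)
        with pytest.warns(UserWarning, match="dropped"):
            pts = idf_invert(cA, cB, levels=[0.5, 5.0])
        assert len(pts) == 1

    def test_noise_free_points_lie_on_generating_isotherm(self, truth):
        grid = np.arange(0, 49) * 0.5e-6
        cA = delta_f(simulate_titration(truth, 6e-6, grid, noise=False), method="pchip")
        cB = delta_f(simulate_titration(truth, 8e-6, grid, noise=False), method="pchip")
        for p in idf_invert(cA, cB, tail_frac=0.1):
            expected = hill_binding_density(p.ppl_free, truth.n_sites, truth.K_b, truth.h)
            assert p.binding_density == pytest.approx(expected, rel=0.01)


class TestScatchard:
    @pytest.mark.parametrize(
        "h,expected",
        [(0.8, "negative"), (1.0, "none"), (1.3, "positive"), (1.6, "positive")],
    )
    def test_concavity_classifies_cooperativity(self, h, expected):
        pts = _isotherm_points(2.2, 6.3e4, h, n_pts=15, span=(0.05, 8.0))
        assert scatchard(pts).cooperativity_evidence == expected

    def test_langmuir_scatchard_is_linear(self):
        pts = _isotherm_points(2.0, 5e4, 1.0, n_pts=15)
        res = scatchard(pts)
        # classical linearity: parabola curvature negligible on the data scale
        x = np.array(res.x)
        y = np.array(res.y)
        slope, icept = np.polyfit(x, y, 1)
        assert np.allclose(y, slope * x + icept, rtol=1e-9)

    def test_few_points_leave_diagnostic_undefined(self):
        pts = _isotherm_points(2.2, 6.3e4, 1.4, n_pts=3)
        res = scatchard(pts)
        assert res.quad_coeff is None
        assert res.cooperativity_evidence == "undefined"
        assert len(res.x) == 3


class TestHillFit:
    def test_half_saturation_identity(self):
        for h in (0.7, 1.0, 1.4, 2.5):
            assert hill_binding_density(1.0 / 6.3e4, 2.2, 6.3e4, h) == pytest.approx(1.1)

    def test_noise_free_exact_recovery(self):
        pts = _isotherm_points(2.2, 6.3e4, 1.4)
        r = hill_fit(pts)
        assert r.n_sites == pytest.approx(2.2, rel=1e-6)
        assert r.K_b == pytest.approx(6.3e4, rel=1e-6)
        assert r.h == pytest.approx(1.4, rel=1e-6)
        assert r.cooperativity_label == "positive"

    def test_h_one_matches_independent_langmuir_oracle(self):
        pts = _isotherm_points(2.0, 5e4, 1.0)
        x = np.array([p.ppl_free for p in pts])
        nu = np.array([p.binding_density for p in pts])

        def langmuir(x, n, kb):
            return n * kb * x / (1 + kb * x)

        (n_l, kb_l), _ = curve_fit(langmuir, x, nu, p0=(1.0, 1e4))
        r = hill_fit(pts)
        assert r.h == pytest.approx(1.0, abs=1e-7)
        assert r.n_sites == pytest.approx(n_l, rel=1e-6)
        assert r.K_b == pytest.approx(kb_l, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 5"):
            hill_fit(_isotherm_points(2.2, 6.3e4, 1.4, n_pts=4))


class TestEndToEnd:
    @pytest.mark.parametrize(
        "n,kb,h",
        [(2.2, 6.3e4, 1.4), (1.0, 1e5, 1.0), (4.0, 3e4, 2.0), (1.5, 2e5, 0.8)],
    )
    def test_noise_free_chain_recovers_truth(self, n, kb, h):
        truth = GroundTruth(n_sites=n, K_b=kb, h=h)
        grid = np.arange(0, 97) * 0.25e-6
        cA = delta_f(simulate_titration(truth, 6e-6, grid, noise=False), method="pchip")
        cB = delta_f(simulate_titration(truth, 8e-6, grid, noise=False), method="pchip")
        r = hill_fit(idf_invert(cA, cB))
        assert r.n_sites == pytest.approx(n, rel=0.01)
        assert r.K_b == pytest.approx(kb, rel=0.01)
        assert r.h == pytest.approx(h, rel=0.01)

    def test_noisy_chain_covers_truth_within_propagated_uncertainty(self, truth, ligand_grid):
        rng = np.random.default_rng(0)
        sA = simulate_titration(truth, 6e-6, ligand_grid, rng=rng)
        sB = simulate_titration(truth, 8e-6, ligand_grid, rng=rng)
        pts, sc, hr = idf_hill_analysis(delta_f(sA), delta_f(sB))
        assert abs(hr.n_sites - truth.n_sites) < 3 * hr.n_sites_se
        assert abs(hr.K_b - truth.K_b) < 3 * hr.K_b_se
        assert abs(hr.h - truth.h) < 3 * hr.h_se
        assert sc.cooperativity_evidence == "positive"
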