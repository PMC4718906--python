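import numpy as np
import pytest
from scipy import stats

from conftest import curve_from_points
from nnufti import (
    ConcentrationModel,
    fit_concentration_model,
    normalize_thi,
    scan_optimal_nnuf,
    t_score,
)
from nnufti.errors import (
    DegenerateDataError,
    DomainError,
    ExtrapolationWarning,
    FitError,
)


class TestTScore:
    def test_identical_groups_score_zero(self):
        values = [0.6, 0.62, 0.64]
        assert t_score(values, values) == 0.0

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateDataError):
            t_score([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])

    def test_matches_reference_implementation(self):
        a = [0.60, 0.62, 0.64]
        b = [0.70, 0.74, 0.78]
        expected = abs(stats.ttest_ind(a, b, equal_var=True).statistic)
        assert t_score(a, b) == pytest.approx(expected, rel=1e-12)

    def test_welch_matches_reference(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 15)
        expected = abs(stats.ttest_ind(a, b, equal_var=False).statistic)
        assert t_score(a, b, welch=True) == pytest.approx(expected, rel=1e-12)

    def test_group_size_validated(self):
        with pytest.raises(DomainError):
            t_score([1.0], [2.0, 3.0])


def _shifted_cohort(offsets, jitter):
    """Curves whose right branches are translated apart by a ThI offset."""
    curves = []
    for off, jit in zip(offsets, jitter):
        points = [
            (0.1 + jit, 0.2),
            (0.3 + jit, 1.0),
            (0.5 + off, 0.5),
            (0.7 + off, 0.2),
            (0.8 + off, 0.1),
        ]
        curves.append(curve_from_points(points, nuf_scale=10))
    return curves


class TestScanOptimalNnuf:
    def test_right_shift_selects_right_side(self):
        rng = np.random.default_rng(0)
        neg = _shifted_cohort(np.zeros(6), rng.normal(0, 0.005, 6))
        pos = _shifted_cohort(np.full(6, 0.08), rng.normal(0, 0.005, 6))
        result = scan_optimal_nnuf(neg, pos)
        assert result.optimal_side == "right"
        defined = ~np.isnan(result.t_left) & ~np.isnan(result.t_right)
        assert (result.t_right[defined] >= result.t_left[defined]).all()

    def test_identical_cohorts_score_zero(self):
        rng = np.random.default_rng(1)
        curves = _shifted_cohort(np.zeros(4), rng.normal(0, 0.01, 4))
        result = scan_optimal_nnuf(curves, list(curves))
        defined = np.concatenate([result.t_left, result.t_right])
        assert np.nanmax(defined) == pytest.approx(0.0, abs=1e-12)
        assert result.optimal_side in ("left", "right")

    def test_reordering_cohort_is_invariant(self):
        rng = np.random.default_rng(3)
        neg = _shifted_cohort(np.zeros(5), rng.normal(0, 0.01, 5))
        pos = _shifted_cohort(np.full(5, 0.1), rng.normal(0, 0.01, 5))
        a = scan_optimal_nnuf(neg, pos)
        b = scan_optimal_nnuf(neg[::-1], pos[::-1])
        np.testing.assert_allclose(a.t_right, b.t_right, rtol=1e-12)
        np.testing.assert_allclose(a.t_left, b.t_left, rtol=1e-12)
        assert (a.optimal_level, a.optimal_side) == (b.optimal_level, b.optimal_side)

    def test_cohort_size_validated(self):
        curves = _shifted_cohort(np.zeros(2), np.zeros(2))
        with pytest.raises(DomainError):
            scan_optimal_nnuf(curves[:1], curves)

    def test_scan_frame_has_both_sides(self):
        rng = np.random.default_rng(4)
        neg = _shifted_cohort(np.zeros(3), rng.normal(0, 0.01, 3))
        pos = _shifted_cohort(np.full(3, 0.05), rng.normal(0, 0.01, 3))
        frame = scan_optimal_nnuf(neg, pos).to_frame()
        assert set(frame["side"]) == {"left", "right"}


class TestConcentrationModel:
    def test_exact_quadratic_recovery(self):
        m = np.linspace(30, 120, 12)
        thi = 0.8 - 0.004 * m + 0.00001 * m**2
        model = fit_concentration_model(list(zip(m, thi)))
        c0, c1, c2 = model.coefficients
        assert c0 == pytest.approx(0.8, rel=1e-9)
        assert c1 == pytest.approx(-0.004, rel=1e-9)
        assert c2 == pytest.approx(0.00001, rel=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_relationship(self):
        model = fit_concentration_model([(40, 0.62), (60, 0.62), (80, 0.62)])
        c0, c1, c2 = model.coefficients
        assert c0 == pytest.approx(0.62, abs=1e-9)
        assert c1 == pytest.approx(0.0, abs=1e-9)
        assert c2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(30, 120, 40)
        thi = 0.75 - 0.003 * m + 8e-6 * m**2 + rng.normal(0, 0.01, 40)
        model = fit_concentration_model(list(zip(m, thi)))
        # independent solve of the normal equations
        X = np.column_stack([np.ones_like(m), m, m**2])
        beta = np.linalg.solve(X.T @ X, X.T @ thi)
        assert np.allclose(model.coefficients, beta, rtol=1e-8)
        resid = thi - X @ beta
        r2 = 1 - resid @ resid / ((thi - thi.mean()) @ (thi - thi.mean()))
        assert model.r_squared == pytest.approx(r2, rel=1e-10)

    def test_rank_deficient_rejected(self):
        with pytest.raises(FitError):
            fit_concentration_model([(60, 0.6), (60, 0.61), (60, 0.62), (60, 0.63)])

    def test_json_round_trip(self, tmp_path):
        model = fit_concentration_model([(40, 0.7), (60, 0.65), (80, 0.62)])
        model.to_json(tmp_path / "model.json")
        loaded = ConcentrationModel.from_json(tmp_path / "model.json")
        assert loaded == model


class TestNormalizeThi:
    def test_identity_at_reference(self):
        model = fit_concentration_model([(40, 0.7), (60, 0.65), (80, 0.62)])
        assert normalize_thi(model, 0.64, 60.0) == pytest.approx(0.64, abs=1e-12)

    def test_linear_correction_arithmetic(self):
        model = ConcentrationModel(
            coefficients=(0.70, -0.001, 0.0), m_ref=60.0, r_squared=1.0,
            n_fit=3, m_range=(30.0, 120.0),
        )
        # f(100) = 0.60, f(60) = 0.64 -> nThI = 0.64 + (0.64 - 0.60)
        assert normalize_thi(model, 0.64, 100.0) == pytest.approx(0.68, abs=1e-12)

    def test_order_preserving_at_fixed_m(self):
        model = fit_concentration_model([(40, 0.7), (60, 0.65), (80, 0.62)])
        lo = normalize_thi(model, 0.60, 90.0)
        hi = normalize_thi(model, 0.70, 90.0)
        assert hi > lo

    def test_extrapolation_warning(self):
        model = ConcentrationModel(
            coefficients=(0.7, 0.0, 0.0), m_range=(30.0, 120.0),
        )
        with pytest.warns(ExtrapolationWarning):
            value = normalize_thi(model, 0.6, 300.0)
        assert np.isfinite(value)

    def test_decorrelates_planted_trend(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(30, 120, 40)
        thi = 0.78 - 0.0035 * m + 1.2e-5 * m**2 + rng.normal(0, 0.02, 40)
        model = fit_concentration_model(list(zip(m, thi)))
        nthi = np.array([normalize_thi(model, t, mi) for t, mi in zip(thi, m)])
        r = np.corrcoef(m, nthi)[0, 1]
        assert abs(r) < 0.1
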