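"""Non-steady-state forward model, rate-constant fitting and acceptance filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from conftest import integer_n_chem
from hwturnover import (
    EnrichmentCurve,
    KineticFit,
    PeptideTimeSeries,
    accept_peptide,
    compare_fit_methods,
    fit_k_manual,
    fit_k_nss,
    fit_k_two_exponential,
    fractional_synthesis,
    model_m0_exact,
    plateau_m0,
    smooth_trace,
)
from hwturnover.errors import DomainError, InsufficientDataError, PairingError
from hwturnover.kinetics import model_m0_adaptive


def make_series(times, m0, peptide="QMEQTYWQANPFR", phase="whole", reps=None):
    times = np.asarray(times, dtype=float)
    reps = np.asarray(reps) if reps is not None else np.array(["r1"] * times.size)
    return PeptideTimeSeries(
        peptide=peptide, protein_id="P1", phase=phase, times=times, replicates=reps, m0=np.asarray(m0)
    )


class TestForwardModel:
    def test_starts_at_natural_abundance(self, comp_chem, curve):
        assert model_m0_exact(0.05, 0.0, comp_chem, curve) == pytest.approx(comp_chem.a, rel=1e-12)

    def test_converges_to_plateau(self, comp_chem, curve):
        plateau = plateau_m0(comp_chem.a, curve.pss, comp_chem.n_sites)
        assert model_m0_exact(0.05, 1e4, comp_chem, curve) == pytest.approx(plateau, rel=1e-9)

    def test_monotone_non_increasing_and_bounded(self, comp_chem, curve, study_days):
        values = model_m0_exact(0.033, study_days, comp_chem, curve)
        plateau = plateau_m0(comp_chem.a, curve.pss, comp_chem.n_sites)
        assert np.all(np.diff(values) <= 1e-12)
        assert np.all(values <= comp_chem.a + 1e-12)
        assert np.all(values >= plateau - 1e-12)

    @pytest.mark.parametrize("k", [1e-4, 1e-3, 1e-2, 0.1, 1.0])
    @pytest.mark.parametrize("n", [1, 8, 20, 40])
    def test_closed_form_matches_adaptive_quadrature(self, curve, k, n):
        """Binomial-expansion closed form vs adaptive integration, integer N."""
        chem = integer_n_chem(a=0.9, n=n)
        for t in (0.5, 6.0, 31.0, 127.0):
            exact = model_m0_exact(k, t, chem, curve)
            reference = model_m0_adaptive(k, t, chem, curve)
            assert exact == pytest.approx(reference, rel=1e-8)

    def test_degenerate_rate_equal_to_precursor_multiple(self):
        """k exactly equal to j*kp must hit the analytic limit, not divide by zero."""
        curve = EnrichmentCurve(kp=0.1, pss=0.0558)
        chem = integer_n_chem(a=0.8, n=5)
        for j in (1, 2, 3):
            k = j * curve.kp
            value = model_m0_exact(k, 21.0, chem, curve)
            assert np.isfinite(value)
            assert value == pytest.approx(model_m0_adaptive(k, 21.0, chem, curve), rel=1e-8)

    def test_fractional_n_quadrature_matches_adaptive(self, comp_chem, curve):
        assert not float(comp_chem.n_sites).is_integer()
        for t in (1.0, 15.0, 63.0):
            assert model_m0_exact(0.033, t, comp_chem, curve) == pytest.approx(
                model_m0_adaptive(0.033, t, comp_chem, curve), rel=1e-10
            )

    def test_invalid_arguments(self, comp_chem, curve):
        with pytest.raises(DomainError):
            model_m0_exact(-0.1, 1.0, comp_chem, curve)
        with pytest.raises(DomainError):
            model_m0_exact(0.1, -1.0, comp_chem, curve)


class TestFractionalSynthesis:
    def test_zero_at_time_zero(self):
        assert fractional_synthesis(0.1, 0.7913, 0.0) == 0.0

    def test_instant_precursor_limit(self):
        t = np.array([1.0, 10.0, 50.0])
        fast = fractional_synthesis(0.1, 1e6, t)
        assert fast == pytest.approx(1.0 - np.exp(-0.1 * t), rel=1e-4)

    def test_continuous_at_k_equals_kp(self):
        near = fractional_synthesis(0.7913 * (1 + 1e-10), 0.7913, 10.0)
        limit = fractional_synthesis(0.7913, 0.7913, 10.0)
        assert near == pytest.approx(limit, rel=1e-6)

    @pytest.mark.parametrize("k", [0.01, 0.1, 0.7913, 2.0])
    def test_matches_ode_oracle(self, k):
        """f' = k*(p(t)/pss - f), f(0)=0, solved numerically."""
        kp = 0.7913
        sol = solve_ivp(
            lambda t, f: k * ((1.0 - np.exp(-kp * t)) - f),
            (0.0, 10.0),
            [0.0],
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        for t in (0.5, 2.0, 10.0):
            assert fractional_synthesis(k, kp, t) == pytest.approx(
                float(sol.sol(t)[0]), abs=1e-8
            )


class TestFitNss:
    def test_noiseless_roundtrip(self, comp_chem, curve, study_days):
        m0 = model_m0_exact(0.0095, study_days, comp_chem, curve)
        fit = fit_k_nss(make_series(study_days, m0), comp_chem, curve)
        assert fit.k == pytest.approx(0.0095, rel=0.005)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.accepted

    def test_three_timepoints_fit_but_not_accepted(self, comp_chem, curve):
        days = np.array([0.0, 15.0, 63.0])
        m0 = model_m0_exact(0.02, days, comp_chem, curve)
        fit = fit_k_nss(make_series(days, m0), comp_chem, curve)
        assert fit.k == pytest.approx(0.02, rel=0.01)
        assert not fit.accepted

    def test_constant_series_hits_lower_bound(self, comp_chem, curve, study_days):
        m0 = np.full(study_days.size, comp_chem.a)
        fit = fit_k_nss(make_series(study_days, m0), comp_chem, curve)
        assert fit.k <= 1e-4  # essentially no decay

    def test_single_timepoint_rejected(self, comp_chem, curve):
        series = make_series([0.0, 0.0], [comp_chem.a, comp_chem.a], reps=["r1", "r2"])
        with pytest.raises(InsufficientDataError):
            fit_k_nss(series, comp_chem, curve)

    def test_replicates_enter_as_separate_residuals(self, comp_chem, curve, study_days):
        rng = np.random.default_rng(20200512)
        times = np.repeat(study_days, 3)
        m0 = model_m0_exact(0.05, times, comp_chem, curve) + rng.normal(0.0, 0.01, times.size)
        series = make_series(times, np.clip(m0, 1e-6, 1.0), reps=np.tile(["r1", "r2", "r3"], 8))
        fit = fit_k_nss(series, comp_chem, curve)
        assert fit.n_timepoints == 8
        assert fit.k == pytest.approx(0.05, rel=0.15)


class TestTwoExponentialAndManual:
    def test_two_exponential_recovers_its_own_model(self, comp_chem, curve, study_days):
        plateau = comp_chem.plateau(curve.pss)
        m0 = comp_chem.a - (comp_chem.a - plateau) * fractional_synthesis(0.02, curve.kp, study_days)
        fit = fit_k_two_exponential(make_series(study_days, m0), comp_chem, curve)
        assert fit.method == "two_exponential"
        assert fit.k == pytest.approx(0.02, rel=1e-4)

    def test_manual_recovers_its_own_model(self, comp_chem, curve, study_days):
        plateau = comp_chem.plateau(curve.pss)
        m0 = plateau + (comp_chem.a - plateau) * np.exp(-0.02 * study_days)
        fit = fit_k_manual(make_series(study_days, m0), comp_chem, curve.pss)
        assert fit.method == "manual_constrained"
        assert fit.k == pytest.approx(0.02, rel=1e-4)

    def test_manual_fit_biased_on_nss_data(self, comp_chem, curve, study_days):
        """Ignoring the precursor rise systematically shifts the manual estimate."""
        m0 = model_m0_exact(0.02, study_days, comp_chem, curve)
        fit = fit_k_manual(make_series(study_days, m0), comp_chem, curve.pss)
        assert abs(fit.k - 0.02) / 0.02 > 0.01  # discrepancy is real, not rounding

    def test_manual_needs_three_timepoints(self, comp_chem, curve):
        series = make_series([0.0, 15.0], [comp_chem.a, comp_chem.a * 0.9])
        with pytest.raises(InsufficientDataError):
            fit_k_manual(series, comp_chem, curve.pss)


class TestCompareFitMethods:
    def test_identical_lists_give_zero(self):
        assert compare_fit_methods([0.01, 0.05], [0.01, 0.05]) == 0.0

    def test_single_pair_symmetric_percent_difference(self):
        assert compare_fit_methods([0.01], [0.012]) == pytest.approx(18.18, abs=0.01)

    def test_empty_or_mismatched_lists_rejected(self):
        with pytest.raises(PairingError):
            compare_fit_methods([], [])
        with pytest.raises(PairingError):
            compare_fit_methods([0.01], [0.01, 0.02])


class TestSmoothTrace:
    def test_constant_trace_unchanged(self):
        trace = np.full(20, 3.5)
        assert smooth_trace(trace) == pytest.approx(trace)

    def test_polynomial_of_filter_order_reproduced(self):
        x = np.arange(30, dtype=float)
        trace = 0.5 * x**2 - 3 * x + 2
        smoothed = smooth_trace(trace, window=7, order=2)
        assert smoothed[3:-3] == pytest.approx(trace[3:-3], rel=1e-9)

    def test_noise_reduction_on_sine(self):
        rng = np.random.default_rng(20200512)
        x = np.linspace(0, 2 * np.pi, 200)
        clean = np.sin(x)
        noisy = clean + rng.normal(0.0, 0.1, x.size)
        smoothed = smooth_trace(noisy, window=7, order=2)
        assert np.std(smoothed - clean) < np.std(noisy - clean)

    @pytest.mark.parametrize("window,order", [(6, 2), (5, 5), (7, -1)])
    def test_invalid_window_or_order(self, window, order):
        with pytest.raises(DomainError):
            smooth_trace(np.ones(50), window=window, order=order)

    def test_short_trace_rejected(self):
        with pytest.raises(DomainError):
            smooth_trace(np.ones(5), window=7)


def fit_with(n, r2, se):
    return KineticFit(
        peptide="PEP", protein_id="P", phase="whole", k=0.01,
        r_squared=r2, se=se, n_timepoints=n, method="nss_exact", accepted=False,
    )


class TestAcceptanceFilter:
    @pytest.mark.parametrize(
        "n,r2,se,expected",
        [
            (5, 0.79, 0.04, True),  # SE clause rescues low R^2
            (3, 0.99, 0.001, False),  # too few time points dominates
            (4, 0.80, 0.06, True),  # inclusive R^2 boundary
        ],
    )
    def test_rule(self, n, r2, se, expected):
        assert accept_peptide(fit_with(n, r2, se)) is expected

    def test_nan_diagnostics_fail_their_clause(self):
        assert not accept_peptide(fit_with(8, float("nan"), float("nan")))
        assert accept_peptide(fit_with(8, float("nan"), 0.01))
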