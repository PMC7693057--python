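"""Log-logistic response model, fitting, and EC10 extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msar.doseresponse import (
    FitError,
    ec10_from_fit,
    fit_abundance_direct,
    fit_response,
    loglogistic_response,
)
from msar.io_toxdata import EndpointClass, ToxRecord
from tests.conftest import make_fit, records_from_curve

CONCS = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0])


class TestLogLogisticResponse:
    @pytest.mark.parametrize(
        "c,c50,beta,expected",
        [
            (10.0, 10.0, 2.0, 0.5),   # half-max at C50 by definition
            (10.0, 10.0, 0.37, 0.5),
            (0.0, 10.0, 2.0, 0.0),    # control limit
            (30.0, 10.0, 2.0, 0.9),   # 1 - 1/(1+9)
        ],
    )
    def test_closed_form_values(self, c, c50, beta, expected):
        assert loglogistic_response(c, c50, beta) == pytest.approx(expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_response(1.0, -1.0, 2.0)
        with pytest.raises(ValueError):
            loglogistic_response(1.0, 10.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        c50=st.floats(1e-3, 1e3),
        beta=st.floats(0.05, 50.0),
        scale=st.floats(1e-3, 1e3),
    )
    def test_monotone_nondecreasing_in_concentration(self, c50, beta, scale):
        c = np.sort(np.concatenate([[0.0], scale * np.geomspace(1e-3, 1e3, 50)]))
        y = loglogistic_response(c, c50, beta)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all((y >= 0) & (y <= 1))


class TestFitResponse:
    def test_noise_free_exact_recovery(self):
        recs = records_from_curve(10.0, 2.0, CONCS)
        fit = fit_response(recs)
        assert fit.c50 == pytest.approx(10.0, rel=1e-6)
        assert fit.beta == pytest.approx(2.0, rel=1e-6)
        assert fit.residual_sse == pytest.approx(0.0, abs=1e-12)
        assert fit.n_points == len(recs)

    def test_mean_recovery_under_noise(self):
        # 200 replicates of N(0, 0.03^2) noise on the same 5-point design
        rng = np.random.default_rng(42)
        base = records_from_curve(10.0, 2.0, [1, 3, 10, 30, 100])
        c50s = []
        for _ in range(200):
            noisy = [
                ToxRecord(r.chemical, r.species, r.endpoint_class, r.concentration,
                          float(np.clip(r.response + rng.normal(0, 0.03), 0, 1)))
                for r in base
            ]
            c50s.append(fit_response(noisy).c50)
        assert np.mean(c50s) == pytest.approx(10.0, rel=0.05)

    def test_single_concentration_is_precondition_error(self):
        recs = [
            ToxRecord("X", "sp", EndpointClass.SURVIVAL, 10.0, r)
            for r in (0.1, 0.2, 0.3)
        ]
        with pytest.raises(FitError, match="distinct concentrations"):
            fit_response(recs)

    def test_all_zero_responses_unidentifiable(self):
        recs = [
            ToxRecord("X", "sp", EndpointClass.SURVIVAL, c, 0.0)
            for c in (0.0, 1.0, 10.0)
        ]
        with pytest.raises(FitError, match="no effect observed"):
            fit_response(recs)

    def test_sse_beats_brute_force_grid(self):
        # grid-search oracle over (C50, beta) on a noisy 5-point input
        rng = np.random.default_rng(7)
        recs = [
            ToxRecord("X", "sp", EndpointClass.SURVIVAL, float(c),
                      float(np.clip(1 - 1 / (1 + (c / 8.0) ** 1.5)
                                    + rng.normal(0, 0.05), 0, 1)))
            for c in [1, 3, 10, 30, 100]
        ]
        fit = fit_response(recs)
        conc = np.array([r.concentration for r in recs])
        resp = np.array([r.response for r in recs])
        best = np.inf
        for c50 in np.geomspace(0.1, 1000, 120):
            for beta in np.geomspace(0.1, 30, 120):
                sse = np.sum((1 - 1 / (1 + (conc / c50) ** beta) - resp) ** 2)
                best = min(best, sse)
        assert fit.residual_sse <= best + 1e-12

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(1)
        recs = [
            ToxRecord("X", "sp", EndpointClass.SURVIVAL, float(c),
                      float(np.clip(1 - 1 / (1 + c / 10.0) + rng.normal(0, 0.05), 0, 1)))
            for c in [0, 1, 3, 10, 30, 100]
        ]
        fit = fit_response(recs)
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.linalg.eigvalsh(fit.covariance).min() >= -1e-12


class TestFitAbundanceDirect:
    def test_noise_free_exact_recovery(self):
        c50, beta, r0 = 5.0, 1.5, 2.0
        concs = np.array([0.0, 0.5, 1.0, 2.0, 5.0])  # stay on the viable branch
        k = 1 - np.log1p((concs / c50) ** beta) / np.log(r0)
        recs = [
            ToxRecord("X", "alga", EndpointClass.ABUNDANCE, float(c), float(1 - kk))
            for c, kk in zip(concs, k)
        ]
        fit = fit_abundance_direct(recs, r0=r0)
        assert fit.c50 == pytest.approx(5.0, rel=1e-6)
        assert fit.beta == pytest.approx(1.5, rel=1e-6)
        assert fit.r0_used == 2.0

    def test_half_effect_concentration_gives_zero_kratio_for_r0_2(self):
        # K(C50)/K(0) = 1 - ln 2 / ln R0 = 0 exactly when R0 = 2
        fit = make_fit(c50=5.0, beta=1.5, endpoint=EndpointClass.ABUNDANCE, r0_used=2.0)
        assert fit.predict(5.0) == pytest.approx(0.0, abs=1e-12)

    def test_r0_of_one_rejected(self):
        recs = [
            ToxRecord("X", "alga", EndpointClass.ABUNDANCE, float(c), float(y))
            for c, y in [(0, 0), (1, 0.3), (10, 0.9)]
        ]
        with pytest.raises(FitError, match="R0"):
            fit_abundance_direct(recs, r0=1.0)

    def test_wrong_endpoint_class_rejected(self):
        recs = records_from_curve(10.0, 2.0, CONCS)
        with pytest.raises(FitError, match="abundance"):
            fit_abundance_direct(recs, r0=2.0)


class TestEC10:
    @pytest.mark.parametrize(
        "c50,beta,expected",
        [
            (10.0, 1.0, 10.0 / 9.0),
            (10.0, 2.0, 10.0 * (1 / 9) ** 0.5),
            (10.0, 1e9, 10.0),  # step-response limit
        ],
    )
    def test_closed_form(self, c50, beta, expected):
        fit = make_fit(c50=c50, beta=beta)
        assert ec10_from_fit(fit) == pytest.approx(expected, rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c50=st.floats(1e-3, 1e3), beta=st.floats(0.1, 30.0))
    def test_ec10_below_c50_and_response_is_ten_percent(self, c50, beta):
        fit = make_fit(c50=c50, beta=beta)
        ec10 = ec10_from_fit(fit)
        assert ec10 < c50
        assert loglogistic_response(ec10, c50, beta) == pytest.approx(0.10, abs=1e-9)

    def test_direct_fit_rejected(self):
        fit = make_fit(endpoint=EndpointClass.ABUNDANCE, r0_used=2.0)
        with pytest.raises(FitError):
            ec10_from_fit(fit)
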