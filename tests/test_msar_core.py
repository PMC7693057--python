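"""MSAR aggregation, log-logistic refit, HC5, and the two variants."""

import numpy as np
import pytest

from msar.doseresponse import FitError
from msar.io_toxdata import EndpointClass, SpeciesTraits
from msar.msar_core import (
    MSARFit,
    aggregate_msar,
    default_grid,
    fit_msar_loglogistic,
    hc5_from_msar,
    hc5_raw,
    msa_loss_at,
    variant_msar,
)
from msar.population import AbundanceCurve
from tests.conftest import make_fit

GRID = np.concatenate([[0.0], np.geomspace(0.01, 1e4, 200)])


def _curve(c50=10.0, beta=2.0, r0=10.0, species="sp"):
    return AbundanceCurve.from_endpoint_fits(
        species, r0, surv_fit=make_fit(c50=c50, beta=beta,
                                       endpoint=EndpointClass.SURVIVAL)
    )


class TestAggregate:
    def test_identical_curves_average_to_themselves(self):
        curves = [_curve(species=f"s{i}") for i in range(5)]
        msar = aggregate_msar(curves, GRID)
        assert np.allclose(msar.msa_values, curves[0](GRID), atol=1e-12)
        assert msar.n_species == 5

    def test_two_step_species_half_lost_between_thresholds(self):
        curves = [AbundanceCurve.step_at("a", 1.0), AbundanceCurve.step_at("b", 10.0)]
        msar = aggregate_msar(curves, np.array([0.0, 5.0]))
        assert msar.msa_values[1] == pytest.approx(0.5)

    def test_control_msa_is_one_and_nonincreasing(self):
        curves = [_curve(c50=c, species=f"s{c}") for c in (1.0, 5.0, 50.0)]
        msar = aggregate_msar(curves, GRID)
        assert msar.msa_values[0] == 1.0
        assert np.all(np.diff(msar.msa_values) <= 1e-12)

    def test_mean_is_exact_over_species(self):
        curves = [_curve(c50=c, species=f"s{c}") for c in (1.0, 5.0, 50.0)]
        msar = aggregate_msar(curves, GRID)
        manual = np.mean([c(GRID) for c in curves], axis=0)
        assert np.max(np.abs(msar.msa_values - manual)) < 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_msar([], GRID)


class TestRefit:
    def test_exact_recovery_from_generated_loglogistic(self):
        truth = MSARFit(a=10.0, beta=1.3)
        msar = aggregate_msar([_curve()], GRID)  # placeholder curve
        msar.msa_values = truth(GRID)
        fit = fit_msar_loglogistic(msar)
        assert fit.a == pytest.approx(10.0, rel=1e-6)
        assert fit.beta == pytest.approx(1.3, rel=1e-6)

    def test_half_max_at_a_by_construction(self):
        fit = MSARFit(a=3.7, beta=2.2)
        assert fit(3.7) == pytest.approx(0.5)

    def test_single_species_refit_beats_grid_oracle(self):
        # direct-abundance curve vs brute-force (a, beta) grid search
        direct = make_fit(c50=5.0, beta=1.5, endpoint=EndpointClass.ABUNDANCE,
                          r0_used=2.0)
        msar = aggregate_msar([AbundanceCurve.from_direct_fit(direct)], GRID)
        fit = fit_msar_loglogistic(msar)
        best = np.inf
        for a in np.geomspace(0.1, 100, 100):
            for beta in np.geomspace(0.2, 20, 100):
                sse = np.sum((1 / (1 + (GRID / a) ** beta) - msar.msa_values) ** 2)
                best = min(best, sse)
        assert fit.sse <= best + 1e-12

    def test_flat_msar_rejected(self):
        msar = aggregate_msar([_curve()], GRID)
        msar.msa_values = np.ones_like(GRID)
        with pytest.raises(FitError, match="flat"):
            fit_msar_loglogistic(msar)


class TestHC5AndLoss:
    @pytest.mark.parametrize(
        "a,beta,expected",
        [
            (10.0, 1.0, 10.0 / 19.0),
            (19.0, 1.0, 1.0),
            (10.0, 1e9, 10.0),  # step limit
        ],
    )
    def test_hc5_closed_form(self, a, beta, expected):
        assert hc5_from_msar(MSARFit(a=a, beta=beta)) == pytest.approx(
            expected, rel=1e-6
        )

    def test_hc5_below_a_and_loss_is_five_percent(self):
        fit = MSARFit(a=12.0, beta=2.4)
        hc5 = hc5_from_msar(fit)
        assert hc5 < fit.a
        assert msa_loss_at(fit, hc5) == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize(
        "a,beta,c,expected",
        [(10.0, 1.0, 0.0, 0.0), (10.0, 1.0, 10.0, 0.5), (10.0, 2.0, 5.0, 0.2)],
    )
    def test_loss_values(self, a, beta, c, expected):
        assert msa_loss_at(MSARFit(a=a, beta=beta), c) == pytest.approx(expected)

    def test_raw_hc5_close_to_fit_hc5_for_loglogistic_msar(self):
        truth = MSARFit(a=10.0, beta=1.5)
        msar = aggregate_msar([_curve()], GRID)
        msar.msa_values = truth(GRID)
        assert hc5_raw(msar) == pytest.approx(hc5_from_msar(truth), rel=0.02)


class TestVariants:
    def _panel(self):
        fits = {
            f"s{i}": [
                make_fit(c50=ec, beta=2.0, species=f"s{i}"),
                make_fit(c50=lc, beta=2.0, species=f"s{i}",
                         endpoint=EndpointClass.SURVIVAL),
            ]
            for i, (ec, lc) in enumerate([(2.0, 9.0), (5.0, 30.0), (20.0, 80.0)])
        }
        traits = {s: SpeciesTraits(species=s, r0=20.0) for s in fits}
        return fits, traits

    def test_default_matches_plain_aggregation(self):
        fits, traits = self._panel()
        from msar.population import build_abundance_curves

        direct = aggregate_msar(build_abundance_curves(fits, traits), GRID)
        via_variant = variant_msar(fits, GRID, "default", traits)
        assert np.allclose(direct.msa_values, via_variant.msa_values, atol=1e-15)

    def test_step_variant_equals_one_minus_ecdf_of_min_c50(self):
        fits, traits = self._panel()
        msar = variant_msar(fits, GRID, "no_intraspecies_variation", traits)
        thresholds = np.array([min(f.c50 for f in fl) for fl in fits.values()])
        ecdf = np.array([(thresholds <= c).mean() for c in GRID])
        assert np.allclose(msar.msa_values, 1.0 - ecdf, atol=1e-15)

    def test_reproduction_only_lies_above_default(self):
        fits, traits = self._panel()
        m_def = variant_msar(fits, GRID, "default", traits)
        m_rep = variant_msar(fits, GRID, "reproduction_only", traits)
        assert np.all(m_rep.msa_values >= m_def.msa_values - 1e-12)
        pos = GRID > 0
        assert np.any(m_rep.msa_values[pos] > m_def.msa_values[pos])

    def test_reproduction_only_without_reproduction_data_is_an_error(self):
        fits = {
            "s1": [make_fit(c50=5.0, endpoint=EndpointClass.SURVIVAL, species="s1")]
        }
        traits = {"s1": SpeciesTraits(species="s1", r0=20.0)}
        with pytest.raises(ValueError, match="reproduction"):
            variant_msar(fits, GRID, "reproduction_only", traits)

    def test_unknown_variant_rejected(self):
        fits, traits = self._panel()
        with pytest.raises(ValueError, match="variant"):
            variant_msar(fits, GRID, "bogus", traits)


class TestDefaultGrid:
    def test_spans_two_decades_beyond_data_and_starts_at_zero(self):
        grid = default_grid([0.0, 0.5, 80.0])
        assert grid[0] == 0.0
        assert grid[1] == pytest.approx(0.005)
        assert grid[-1] == pytest.approx(8000.0)
        assert len(grid) == 201

    def test_needs_a_positive_concentration(self):
        with pytest.raises(ValueError):
            default_grid([0.0])
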