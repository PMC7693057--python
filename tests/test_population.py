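"""Fecundity ratios, exposure-abundance conversion, and R0 resolution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msar.doseresponse import fit_abundance_direct
from msar.io_toxdata import EndpointClass, SpeciesTraits, ToxRecord
from msar.population import (
    AbundanceCurve,
    AllometryParams,
    TraitError,
    abundance_ratio,
    fecundity_ratio,
    r0_from_traits,
    species_abundance_curve,
)
from tests.conftest import make_fit


class TestFecundityRatio:
    def test_control_is_one(self):
        assert fecundity_ratio(0.0, make_fit(), make_fit()) == pytest.approx(1.0)

    def test_both_endpoints_at_their_half_effect(self):
        rep = make_fit(c50=10.0, beta=2.0)
        surv = make_fit(c50=10.0, beta=3.0, endpoint=EndpointClass.SURVIVAL)
        assert fecundity_ratio(10.0, rep, surv) == pytest.approx(0.25)

    def test_single_endpoint_contributes_single_factor(self):
        surv = make_fit(c50=10.0, beta=2.0, endpoint=EndpointClass.SURVIVAL)
        assert fecundity_ratio(10.0, surv_fit=surv) == pytest.approx(0.5)

    def test_no_fits_is_an_error(self):
        with pytest.raises(ValueError):
            fecundity_ratio(1.0)


class TestAbundanceRatio:
    def test_control_is_exactly_one(self):
        assert abundance_ratio(0.0, make_fit(), make_fit(
            endpoint=EndpointClass.SURVIVAL), r0=2.0) == 1.0

    def test_hand_computed_value(self):
        # both endpoints at C50=10, beta=1, R0=e^4:
        # 1 - (ln2 + ln2)/4 = 1 - 2 ln2 / 4
        rep = make_fit(c50=10.0, beta=1.0)
        surv = make_fit(c50=10.0, beta=1.0, endpoint=EndpointClass.SURVIVAL)
        got = abundance_ratio(10.0, rep, surv, r0=math.exp(4.0))
        assert got == pytest.approx(1.0 - 2.0 * math.log(2.0) / 4.0, rel=1e-12)

    def test_nonviable_population_clamped_to_zero(self):
        # raw value 1 - 2 ln 2 < 0 with R0 = e
        rep = make_fit(c50=10.0, beta=1.0)
        surv = make_fit(c50=10.0, beta=1.0, endpoint=EndpointClass.SURVIVAL)
        assert abundance_ratio(10.0, rep, surv, r0=math.e) == 0.0

    def test_r0_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="R0"):
            abundance_ratio(1.0, make_fit(), r0=1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        ec50=st.floats(0.01, 1e3),
        lc50=st.floats(0.01, 1e3),
        brep=st.floats(0.1, 20.0),
        bsurv=st.floats(0.1, 20.0),
        r0=st.floats(1.01, 1e4),
    )
    def test_nonincreasing_in_concentration(self, ec50, lc50, brep, bsurv, r0):
        rep = make_fit(c50=ec50, beta=brep)
        surv = make_fit(c50=lc50, beta=bsurv, endpoint=EndpointClass.SURVIVAL)
        c = np.concatenate([[0.0], np.geomspace(1e-4, 1e6, 60)])
        k = abundance_ratio(c, rep, surv, r0=r0)
        assert np.all(np.diff(k) <= 1e-12)
        assert np.all((k >= 0) & (k <= 1))

    def test_adding_reproduction_never_raises_abundance(self):
        rep = make_fit(c50=8.0, beta=1.7)
        surv = make_fit(c50=20.0, beta=2.5, endpoint=EndpointClass.SURVIVAL)
        c = np.geomspace(0.1, 1e4, 80)
        both = abundance_ratio(c, rep, surv, r0=10.0)
        surv_only = abundance_ratio(c, surv_fit=surv, r0=10.0)
        assert np.all(both <= surv_only + 1e-12)

    def test_consistency_with_direct_fit(self):
        # K-ratios produced by the growth model, refitted directly, give
        # back the generating parameters
        surv = make_fit(c50=6.0, beta=2.2, endpoint=EndpointClass.SURVIVAL)
        r0 = 7.0
        concs = np.concatenate([[0.0], np.geomspace(0.5, 60.0, 7)])
        k = abundance_ratio(concs, surv_fit=surv, r0=r0)
        recs = [
            ToxRecord("X", "sp", EndpointClass.ABUNDANCE, float(c), float(1 - kk))
            for c, kk in zip(concs, k)
        ]
        fit = fit_abundance_direct(recs, r0=r0)
        assert fit.c50 == pytest.approx(6.0, rel=1e-6)
        assert fit.beta == pytest.approx(2.2, rel=1e-6)


class TestR0FromTraits:
    def test_clonal_default_is_two(self):
        assert r0_from_traits(SpeciesTraits(species="alga", is_clonal=True)) == 2.0

    def test_experimental_value_wins(self):
        t = SpeciesTraits(species="x", r0=50.0, body_mass=0.001, is_clonal=True)
        assert r0_from_traits(t) == 50.0

    def test_allometric_inversion(self):
        # r = 0.1/day and Tg = 20 days at the test mass -> R0 = e^2
        allo = AllometryParams(a_r=0.1, b_r=0.0, a_T=20.0, b_T=0.0)
        t = SpeciesTraits(species="x", body_mass=1.0)
        assert r0_from_traits(t, allo) == pytest.approx(math.exp(2.0))

    def test_mass_independence_with_opposite_exponents(self):
        # b_r = -b_T makes r * Tg independent of W
        allo = AllometryParams(a_r=0.05, b_r=-0.25, a_T=40.0, b_T=0.25)
        masses = np.geomspace(1e-6, 1e-4, 9)  # two orders of magnitude
        r0s = [r0_from_traits(SpeciesTraits(species="x", body_mass=float(w)), allo)
               for w in masses]
        assert max(r0s) / min(r0s) < 1.10

    def test_mass_without_intercepts_is_an_error(self):
        with pytest.raises(TraitError, match="allometry"):
            r0_from_traits(SpeciesTraits(species="x", body_mass=0.01))


class TestAbundanceCurve:
    def test_evaluator_control_is_one_and_nonincreasing(self):
        curve = AbundanceCurve.from_endpoint_fits(
            "sp", 5.0, rep_fit=make_fit(),
            surv_fit=make_fit(endpoint=EndpointClass.SURVIVAL),
        )
        grid = np.concatenate([[0.0], np.geomspace(0.01, 1e4, 100)])
        k = curve(grid)
        assert k[0] == 1.0
        assert np.all(np.diff(k) <= 1e-12)
        assert np.all((k >= 0) & (k <= 1))

    def test_source_tags(self):
        surv = make_fit(endpoint=EndpointClass.SURVIVAL)
        assert AbundanceCurve.from_endpoint_fits("s", 5.0, surv_fit=surv).source == \
            "survival_only"
        assert AbundanceCurve.from_endpoint_fits(
            "s", 5.0, rep_fit=make_fit(), surv_fit=surv).source == "combined_surv_rep"

    def test_direct_fit_takes_precedence(self):
        direct = make_fit(endpoint=EndpointClass.ABUNDANCE, r0_used=2.0)
        curve = species_abundance_curve("s", [direct, make_fit()], r0=5.0)
        assert curve.source == "direct_abundance"

    def test_step_curve_is_closed_on_the_right(self):
        curve = AbundanceCurve.step_at("s", 10.0)
        assert curve(9.999) == 1.0
        assert curve(10.0) == 0.0  # species counted as lost at exactly C50
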