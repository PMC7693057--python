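import numpy as np
import pytest

from msar.doseresponse import DoseResponseFit
from msar.io_toxdata import EndpointClass, SpeciesTraits, ToxRecord
from msar.synthetic import PanelSpec, generate_panel


def make_fit(c50=10.0, beta=2.0, species="sp", endpoint=EndpointClass.REPRODUCTION,
             cov=None, r0_used=None, sse=0.0, n_points=7):
    return DoseResponseFit(
        species=species,
        endpoint_class=endpoint,
        c50=c50,
        beta=beta,
        covariance=np.zeros((2, 2)) if cov is None else np.asarray(cov),
        residual_sse=sse,
        n_points=n_points,
        r0_used=r0_used,
    )


def records_from_curve(c50, beta, concs, species="sp", chemical="X",
                       endpoint=EndpointClass.REPRODUCTION):
    """Noise-free records generated from a known log-logistic curve."""
    concs = np.asarray(concs, dtype=float)
    resp = 1.0 - 1.0 / (1.0 + (concs / c50) ** beta)
    return [
        ToxRecord(chemical=chemical, species=species, endpoint_class=endpoint,
                  concentration=float(c), response=float(y))
        for c, y in zip(concs, resp)
    ]


@pytest.fixture
def noise_free_panel():
    """A small panel with exact (noise-free) responses and its ground truth."""
    spec = PanelSpec(n_species=8, binomial_n=None, gaussian_sd=0.0, seed=3)
    records, traits, truth = generate_panel(spec)
    return records, {t.species: t for t in traits}, truth


@pytest.fixture
def noisy_panel():
    """A case-study-scale noisy panel (binomial survival, Gaussian fractions)."""
    spec = PanelSpec(n_species=15, seed=11)
    records, traits, truth = generate_panel(spec)
    return records, {t.species: t for t in traits}, truth
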