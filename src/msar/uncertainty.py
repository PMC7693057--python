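"""Monte-Carlo propagation of fit uncertainty into MSAR bands and HC5 CIs.

Each dose-response fit carries the asymptotic least-squares covariance of
its parameters on log scale.  One Monte-Carlo iteration draws (log C50,
log beta) for every fit from its multivariate normal, rebuilds every
species' exposure-abundance curve, aggregates them into one possible MSAR,
refits the community log-logistic, and records its HC5.  Pointwise 2.5/97.5
percentiles over iterations form the 95% confidence band; the HC5 CI is the
percentile interval of the recorded HC5 samples with a multiplicative
median-bias correction (see :func:`msar_envelope`).

Species are treated as independent (each species' curve is sampled
separately) and R0 values are held fixed: only exposure-response fit
uncertainty is propagated.  Bands are parameter-only confidence bands by
default; ``include_residual`` additionally perturbs each species curve by a
draw from its residual error, which widens the band toward a prediction
band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .doseresponse import DoseResponseFit, FitError
from .io_toxdata import SpeciesTraits
from .msar_core import (
    MSARCurve,
    MSARFit,
    aggregate_msar,
    fit_msar_loglogistic,
    hc5_from_msar,
)
from .population import (
    AllometryParams,
    r0_from_traits,
    species_abundance_curve,
)

__all__ = [
    "UncertaintyEnvelope",
    "sample_curve",
    "msar_envelope",
    "ci_from_samples",
]


#: Truncation of parameter draws, in log units around the point estimate.
_MAX_LOG_DEVIATION = 6.0

#: Cap on the per-parameter standard deviation of (log C50, log beta) used
#: for sampling.  Step-like fits leave the slope unidentified upward and the
#: linearized covariance explodes; a cap of 2 log units (a 7-fold 1-sigma)
#: already means "essentially unconstrained" at the scale of a toxicity test
#: while keeping sampled curves numerically meaningful.
_MAX_LOG_SD = 2.0


def _cap_covariance(cov: np.ndarray, cap: float = _MAX_LOG_SD) -> np.ndarray:
    """Shrink oversized diagonal entries to ``cap``^2, preserving correlation."""
    d = np.sqrt(np.diag(cov))
    if np.all(d <= cap):
        return cov
    s = np.where(d > cap, cap / np.where(d > 0, d, 1.0), 1.0)
    return (cov * s).T * s


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() >= 0:
        return cov
    warnings.warn(
        f"covariance not positive semi-definite (min eigenvalue {eigval.min():.3e}); "
        "repaired by eigenvalue clipping",
        RuntimeWarning,
        stacklevel=3,
    )
    repaired = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    return 0.5 * (repaired + repaired.T)


def sample_curve(fit: DoseResponseFit, rng: np.random.Generator) -> DoseResponseFit:
    """One parameter draw from a fit's uncertainty: a possible response curve.

    Draws (log C50, log beta) from the fit's multivariate normal and returns
    a point-estimate fit (zero covariance) with the same metadata.  A zero
    covariance returns the fit's own parameters.
    """
    cov = np.asarray(fit.covariance, dtype=float)
    if np.all(cov == 0):
        c50, beta = fit.c50, fit.beta
    else:
        mean = np.log([fit.c50, fit.beta])
        cov = _cap_covariance(_nearest_psd(0.5 * (cov + cov.T)))
        draw = rng.multivariate_normal(mean, cov, method="eigh")
        # near-singular Jacobians (step-like fits) give astronomically wide
        # normals; truncate at e^+-6 (~400-fold) around the point estimate so
        # uninformative directions stay numerically meaningful
        draw = np.clip(draw, mean - _MAX_LOG_DEVIATION, mean + _MAX_LOG_DEVIATION)
        c50, beta = np.exp(draw)
    return DoseResponseFit(
        species=fit.species,
        endpoint_class=fit.endpoint_class,
        c50=float(c50),
        beta=float(beta),
        covariance=np.zeros((2, 2)),
        residual_sse=fit.residual_sse,
        n_points=fit.n_points,
        r0_used=fit.r0_used,
    )


@dataclass
class UncertaintyEnvelope:
    """95% confidence band around the deterministic MSAR plus the HC5 CI."""

    n_iter: int
    seed: int
    grid: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    hc5_samples: np.ndarray
    hc5_ci: tuple[float, float]
    deterministic_msa: np.ndarray
    deterministic_fit: MSARFit
    deterministic_hc5: float
    n_failed: int = 0
    level: float = 0.95


def ci_from_samples(
    samples: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Empirical percentile interval ((1-level)/2, 1-(1-level)/2), linear interpolation."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples for a percentile interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly in (0, 1)")
    tail = (1.0 - level) / 2.0 * 100.0
    lo, hi = np.percentile(samples, [tail, 100.0 - tail])
    return float(lo), float(hi)


def _residual_sd(fit: DoseResponseFit) -> float:
    dof = fit.n_points - 2
    return float(np.sqrt(fit.residual_sse / dof)) if dof > 0 else 0.0


def msar_envelope(
    fits_by_species: Mapping[str, Sequence[DoseResponseFit]],
    grid: Sequence[float],
    n_iter: int = 1000,
    seed: int = 0,
    traits_by_species: Mapping[str, SpeciesTraits] | None = None,
    allometry: AllometryParams | None = None,
    chemical: str = "",
    level: float = 0.95,
    include_residual: bool = False,
) -> UncertaintyEnvelope:
    """Monte-Carlo MSAR envelope and HC5 confidence interval.

    Per iteration every species' fit parameters are redrawn, the community
    curve is re-aggregated and refitted, and its HC5 recorded.  Iterations
    whose refit fails are dropped and counted; more than 10% failures aborts
    with an error.  Identical inputs, seed and n_iter reproduce the envelope
    bit for bit.
    """
    grid = np.asarray(grid, dtype=float)
    traits_by_species = traits_by_species or {}
    rng = np.random.default_rng(seed)

    # resolve R0 once per species; R0 uncertainty is not propagated
    r0_by_species: dict[str, float | None] = {}
    for species, fits in fits_by_species.items():
        if any(f.is_direct for f in fits):
            r0_by_species[species] = None
        else:
            traits = traits_by_species.get(species)
            if traits is None:
                raise ValueError(f"no traits for species {species!r}")
            r0_by_species[species] = r0_from_traits(traits, allometry)

    det_curves = [
        species_abundance_curve(sp, fits, r0_by_species[sp])
        for sp, fits in fits_by_species.items()
    ]
    det_msar = aggregate_msar(det_curves, grid, chemical=chemical)
    det_fit = fit_msar_loglogistic(det_msar)
    det_hc5 = hc5_from_msar(det_fit)
    warm = (det_fit.a, det_fit.beta)

    msa_matrix = np.empty((n_iter, grid.size))
    hc5_samples = []
    n_failed = 0
    kept = 0
    for _ in range(n_iter):
        try:
            sampled = {
                sp: [sample_curve(f, rng) for f in fits]
                for sp, fits in fits_by_species.items()
            }
            rows = []
            for sp, fits in sampled.items():
                curve = species_abundance_curve(sp, fits, r0_by_species[sp])
                vals = np.asarray(curve(grid), dtype=float)
                if include_residual:
                    sd = max(_residual_sd(f) for f in fits)
                    vals = np.clip(vals + rng.normal(0.0, sd), 0.0, 1.0) if sd > 0 else vals
                rows.append(vals)
            msa = np.mean(rows, axis=0)
            it_msar = MSARCurve(
                chemical=chemical, species_curves=[], grid=grid, msa_values=msa
            )
            try:
                it_fit = fit_msar_loglogistic(it_msar, theta0=warm)
            except FitError:
                it_fit = fit_msar_loglogistic(it_msar)
        except (FitError, ValueError):
            n_failed += 1
            continue
        msa_matrix[kept] = msa
        hc5_samples.append(hc5_from_msar(it_fit))
        kept += 1
    if n_failed > 0.10 * n_iter:
        raise RuntimeError(
            f"{n_failed}/{n_iter} Monte-Carlo iterations failed to refit; "
            "inputs too unstable for an envelope"
        )
    msa_matrix = msa_matrix[:kept]
    tail = (1.0 - level) / 2.0 * 100.0
    lower, upper = np.percentile(msa_matrix, [tail, 100.0 - tail], axis=0)
    hc5_samples = np.asarray(hc5_samples)
    # Median-bias-corrected percentile interval: the simulated HC5s are
    # left-skewed around the plug-in estimate (small-beta draws depress the
    # low-concentration tail far more than large-beta draws can raise it),
    # so the raw percentile interval sits below the estimate and
    # under-covers.  Rescaling the interval so its median matches the
    # deterministic HC5 is the multiplicative median-bias correction.
    raw_ci = ci_from_samples(hc5_samples, level)
    med = float(np.median(hc5_samples))
    factor = det_hc5 / med if med > 0 else 1.0
    hc5_ci = (raw_ci[0] * factor, raw_ci[1] * factor)
    return UncertaintyEnvelope(
        n_iter=n_iter,
        seed=seed,
        grid=grid,
        lower95=lower,
        upper95=upper,
        hc5_samples=hc5_samples,
        hc5_ci=hc5_ci,
        deterministic_msa=det_msar.msa_values,
        deterministic_fit=det_fit,
        deterministic_hc5=det_hc5,
        n_failed=n_failed,
        level=level,
    )


def envelope_to_dict(env: UncertaintyEnvelope) -> dict:
    return {
        "n_iter": env.n_iter,
        "seed": env.seed,
        "n_failed": env.n_failed,
        "level": env.level,
        "grid": env.grid.tolist(),
        "lower95": env.lower95.tolist(),
        "upper95": env.upper95.tolist(),
        "deterministic_msa": env.deterministic_msa.tolist(),
        "deterministic_fit": {
            "a": env.deterministic_fit.a,
            "beta": env.deterministic_fit.beta,
        },
        "deterministic_hc5": env.deterministic_hc5,
        "hc5_ci": list(env.hc5_ci),
    }
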