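"""EC10-based species sensitivity distributions (SSDs) and their HC5.

An SSD summarizes interspecies variation in sensitivity as a cumulative
distribution over one point per species -- here the EC10, the concentration
affecting 10% of individuals (or, for directly fitted abundance curves, the
concentration at 10% abundance loss).  Per species the most sensitive
endpoint is used, matching regulatory SSD convention.

The distribution family is the log-logistic (a logistic on log
concentration; ``scipy.stats.fisk``), fitted by maximum likelihood with the
location fixed at zero.  The hazardous concentration for 5% of species is
its 5th percentile, ``scale * (1/19)^(1/shape)``.  Uncertainty comes from a
nonparametric bootstrap over species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .doseresponse import DoseResponseFit, ec10_from_fit

__all__ = [
    "SSDFit",
    "species_ec10",
    "ec10_table",
    "fit_ssd",
    "hc5_from_ssd",
    "bootstrap_hc5_ci",
]


@dataclass
class SSDFit:
    """Maximum-likelihood log-logistic SSD over per-species EC10s.

    ``scale`` is the distribution's median; ``shape`` the log-logistic shape
    (large shape = little interspecies variation).  ``degenerate`` flags the
    zero-variance case where the MLE shape diverges.
    """

    chemical: str
    ec10_values: np.ndarray
    scale: float
    shape: float
    n_species: int
    degenerate: bool = False

    def cdf(self, c):
        """Potentially affected fraction of species at concentration c."""
        c = np.asarray(c, dtype=float)
        if self.degenerate:
            out = np.where(c >= self.scale, 1.0, 0.0)
        else:
            out = stats.fisk.cdf(c, self.shape, loc=0, scale=self.scale)
        return out if out.ndim else float(out)


def _direct_ec10(fit: DoseResponseFit) -> float:
    """Concentration at 10% abundance loss for a direct K-ratio fit.

    Solving 1 - ln(1 + (c/C50)^beta)/ln R0 = 0.9 gives the closed form
    ``C50 * (R0^0.1 - 1)^(1/beta)``.
    """
    return float(fit.c50 * (fit.r0_used**0.1 - 1.0) ** (1.0 / fit.beta))


def species_ec10(fits: Sequence[DoseResponseFit]) -> float:
    """One EC10 for a species: the minimum across its endpoint fits."""
    if not fits:
        raise ValueError("no fits supplied")
    values = [
        _direct_ec10(f) if f.is_direct else ec10_from_fit(f) for f in fits
    ]
    return float(min(values))


def ec10_table(
    fits_by_species: Mapping[str, Sequence[DoseResponseFit]]
) -> dict[str, float]:
    """Per-species EC10s; species with no fittable endpoint are skipped."""
    out = {}
    for species, fits in fits_by_species.items():
        if fits:
            out[species] = species_ec10(fits)
    return out


def fit_ssd(ec10_values: Sequence[float], chemical: str = "") -> SSDFit:
    """Maximum-likelihood log-logistic fit to per-species EC10 values."""
    values = np.asarray(ec10_values, dtype=float)
    if values.size < 3:
        raise ValueError(f"need >= 3 EC10 values to fit an SSD, got {values.size}")
    if np.any(values <= 0):
        raise ValueError("EC10 values must be positive")
    if np.ptp(values) == 0:
        return SSDFit(
            chemical=chemical,
            ec10_values=values,
            scale=float(values[0]),
            shape=math.inf,
            n_species=values.size,
            degenerate=True,
        )
    shape, _, scale = stats.fisk.fit(values, floc=0)
    return SSDFit(
        chemical=chemical,
        ec10_values=values,
        scale=float(scale),
        shape=float(shape),
        n_species=values.size,
    )


def hc5_from_ssd(fit: SSDFit) -> float:
    """5th percentile of the fitted SSD: ``scale * (1/19)^(1/shape)``."""
    if fit.degenerate:
        return fit.scale
    return float(fit.scale * (1.0 / 19.0) ** (1.0 / fit.shape))


def bootstrap_hc5_ci(
    ec10_values: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the SSD HC5, resampling species."""
    values = np.asarray(ec10_values, dtype=float)
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_boot):
        resampled = rng.choice(values, size=values.size, replace=True)
        if np.ptp(resampled) == 0:
            samples.append(float(resampled[0]))
            continue
        try:
            samples.append(hc5_from_ssd(fit_ssd(resampled)))
        except Exception:
            continue
    lo = (1.0 - level) / 2.0 * 100.0
    return (
        float(np.percentile(samples, lo)),
        float(np.percentile(samples, 100.0 - lo)),
    )


def ssd_to_dict(fit: SSDFit, hc5: float | None = None, ci=None) -> dict:
    out = {
        "chemical": fit.chemical,
        "scale": fit.scale,
        "shape": None if math.isinf(fit.shape) else fit.shape,
        "degenerate": fit.degenerate,
        "n_species": fit.n_species,
        "ec10_values": fit.ec10_values.tolist(),
    }
    out["hc5"] = hc5_from_ssd(fit) if hc5 is None else hc5
    if ci is not None:
        out["hc5_ci"] = list(ci)
    return out
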