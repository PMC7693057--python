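"""Community-level aggregation: the mean species abundance relationship (MSAR).

The MSAR is the unweighted mean of the species-level relative abundances,

    MSA(c) = (1/n) * sum_i K(c)_i / K(0)_i,

evaluated on a concentration grid.  A decreasing 2-parameter log-logistic

    MSA_fit(c) = 1 / (1 + (c/a)^beta)

is refitted through the aggregated curve; hazardous concentrations are read
off this refit, e.g. the HC5 (5% community abundance loss) at
``a * (1/19)^(1/beta)``.

Two variants probe the framework's structural assumptions: a
reproduction-only MSAR (survival effects excluded) and a
no-intraspecies-variation MSAR in which every species responds
all-or-nothing at its most sensitive half-effect concentration, so the
community curve collapses onto 1 minus the empirical CDF of the
min(EC50, LC50) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .doseresponse import DoseResponseFit, FitError
from .io_toxdata import EndpointClass, SpeciesTraits
from .population import (
    DIRECT_ABUNDANCE,
    REPRODUCTION_ONLY,
    AbundanceCurve,
    AllometryParams,
    build_abundance_curves,
    r0_from_traits,
)

__all__ = [
    "MSARCurve",
    "MSARFit",
    "default_grid",
    "aggregate_msar",
    "fit_msar_loglogistic",
    "hc5_from_msar",
    "hc5_raw",
    "msa_loss_at",
    "variant_msar",
    "VARIANTS",
]

VARIANTS = ("default", "reproduction_only", "no_intraspecies_variation")


@dataclass
class MSARCurve:
    """Aggregated community curve: grid, MSA values, and the species curves behind it."""

    chemical: str
    species_curves: list[AbundanceCurve]
    grid: np.ndarray
    msa_values: np.ndarray
    variant: str = "default"

    @property
    def n_species(self) -> int:
        return len(self.species_curves)

    def __call__(self, c):
        """MSA at arbitrary concentrations (recomputed from the species curves)."""
        vals = np.mean([curve(c) for curve in self.species_curves], axis=0)
        return vals if np.ndim(vals) else float(vals)


@dataclass
class MSARFit:
    """Log-logistic refit of an MSAR: MSA_fit(c) = 1 / (1 + (c/a)^beta)."""

    a: float  # half-maximal effective concentration of the community curve, ug/L
    beta: float
    sse: float = 0.0

    def __post_init__(self):
        if self.a <= 0 or self.beta <= 0:
            raise ValueError("a and beta must be positive")

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        with np.errstate(over="ignore"):
            out = 1.0 / (1.0 + (c / self.a) ** self.beta)
        return out if out.ndim else float(out)


def default_grid(concentrations: Sequence[float], n: int = 200) -> np.ndarray:
    """Log-spaced evaluation grid spanning two decades beyond the tested range.

    ``n`` points from min(positive)/100 to max*100, with c = 0 prepended so
    the control anchor is always on the grid.
    """
    conc = np.asarray(concentrations, dtype=float)
    pos = conc[conc > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive concentration to build a grid")
    lo, hi = pos.min() / 100.0, pos.max() * 100.0
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


def aggregate_msar(
    curves: Sequence[AbundanceCurve],
    grid: Sequence[float],
    chemical: str = "",
    variant: str = "default",
) -> MSARCurve:
    """Pointwise unweighted mean of the species curves over the grid."""
    if len(curves) == 0:
        raise ValueError("cannot aggregate an empty set of species curves")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be a sorted 1-D array")
    values = np.mean(np.stack([np.asarray(c(grid), dtype=float) for c in curves]), axis=0)
    return MSARCurve(
        chemical=chemical,
        species_curves=list(curves),
        grid=grid,
        msa_values=values,
        variant=variant,
    )


def fit_msar_loglogistic(
    msar: MSARCurve, theta0: tuple[float, float] | None = None
) -> MSARFit:
    """Least-squares (a, beta) of the decreasing log-logistic through the MSAR.

    ``theta0`` optionally warm-starts the optimizer (used by the Monte-Carlo
    loop, where consecutive iterations share a neighbourhood).
    """
    grid, values = msar.grid, msar.msa_values
    if np.ptp(values) < 1e-12:
        raise FitError("MSAR is flat; log-logistic refit is unidentifiable")

    def residuals(theta):
        a, beta = np.exp(theta)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + (grid / a) ** beta) - values

    def jacobian(theta):
        from .doseresponse import _loglogistic_jac

        a, beta = np.exp(theta)
        return -_loglogistic_jac(grid, a, beta)

    if theta0 is not None:
        starts = [np.log(theta0)]
    else:
        # start a at the interpolated 0.5 crossing, else the grid's geometric middle
        if values.min() < 0.5 < values.max():
            a0 = float(np.interp(0.5, values[::-1], grid[::-1]))
        else:
            pos = grid[grid > 0]
            a0 = float(np.sqrt(pos.min() * pos.max()))
        a0 = max(a0, np.nextafter(0, 1) + grid[grid > 0].min() / 1e6)
        starts = [np.log([a0, b]) for b in (1.0, 0.5, 2.0, 4.0)]
    best = None
    for s in starts:
        res = least_squares(
            residuals, s, jac=jacobian, method="lm", ftol=1e-12, xtol=1e-12,
            gtol=1e-12, max_nfev=2000,
        )
        if np.all(np.isfinite(res.x)) and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("MSAR log-logistic refit failed to converge")
    a, beta = np.exp(best.x)
    return MSARFit(a=float(a), beta=float(beta), sse=float(2 * best.cost))


def hc5_from_msar(fit: MSARFit) -> float:
    """Concentration at 5% community abundance loss: ``a * (1/19)^(1/beta)``."""
    return float(fit.a * (1.0 / 19.0) ** (1.0 / fit.beta))


def hc5_raw(msar: MSARCurve) -> float:
    """HC5 read off the raw piecewise MSAR by log-linear interpolation."""
    values, grid = msar.msa_values, msar.grid
    if values.min() > 0.95:
        raise ValueError("MSAR never drops to 0.95 on the grid; widen the grid")
    idx = int(np.argmax(values <= 0.95))
    if idx == 0:
        return float(grid[0])
    c_lo, c_hi = grid[idx - 1], grid[idx]
    v_lo, v_hi = values[idx - 1], values[idx]
    if c_lo == 0:
        return float(np.interp(0.95, [v_hi, v_lo], [c_hi, c_lo]))
    t = (0.95 - v_lo) / (v_hi - v_lo)
    return float(np.exp(np.log(c_lo) + t * (np.log(c_hi) - np.log(c_lo))))


def msa_loss_at(msar_or_fit: MSARCurve | MSARFit, c) -> float:
    """Community abundance loss 1 - MSA(c)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    out = 1.0 - np.asarray(msar_or_fit(c), dtype=float)
    return out if out.ndim else float(out)


def _min_c50(fits: Sequence[DoseResponseFit]) -> float:
    return min(f.c50 for f in fits)


def variant_msar(
    fits_by_species: Mapping[str, Sequence[DoseResponseFit]],
    grid: Sequence[float],
    variant: str = "default",
    traits_by_species: Mapping[str, SpeciesTraits] | None = None,
    allometry: AllometryParams | None = None,
    chemical: str = "",
) -> MSARCurve:
    """Build the default MSAR or one of its two diagnostic variants.

    ``reproduction_only`` keeps each animal's reproduction fit and drops its
    survival fit (survival-only species leave the panel); direct abundance
    curves are retained as-is since they carry no separable survival term.
    ``no_intraspecies_variation`` replaces every fitted slope by an
    all-or-nothing step at the species' smallest half-effect concentration,
    so the MSAR equals 1 minus the empirical CDF (right-closed) of the
    min(EC50, LC50) values.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if variant == "default":
        curves = build_abundance_curves(fits_by_species, traits_by_species, allometry)
        return aggregate_msar(curves, grid, chemical=chemical, variant=variant)

    if variant == "no_intraspecies_variation":
        curves = [
            AbundanceCurve.step_at(species, _min_c50(fits))
            for species, fits in fits_by_species.items()
        ]
        return aggregate_msar(curves, grid, chemical=chemical, variant=variant)

    # reproduction_only
    curves = []
    n_rep = 0
    traits_by_species = traits_by_species or {}
    for species, fits in fits_by_species.items():
        direct = [f for f in fits if f.is_direct]
        if direct:
            curves.append(AbundanceCurve.from_direct_fit(direct[0]))
            continue
        rep = next(
            (f for f in fits if f.endpoint_class == EndpointClass.REPRODUCTION), None
        )
        if rep is None:
            continue  # survival-only species cannot contribute
        n_rep += 1
        traits = traits_by_species.get(species)
        if traits is None:
            raise ValueError(f"no traits for species {species!r}")
        r0 = r0_from_traits(traits, allometry)
        curves.append(
            AbundanceCurve.from_endpoint_fits(species, r0, rep_fit=rep)
        )
    if n_rep == 0:
        raise ValueError("reproduction_only variant: no species carries a reproduction fit")
    return aggregate_msar(curves, grid, chemical=chemical, variant=variant)


def msar_to_dict(msar: MSARCurve, fit: MSARFit | None = None) -> dict:
    out = {
        "chemical": msar.chemical,
        "variant": msar.variant,
        "n_species": msar.n_species,
        "grid": msar.grid.tolist(),
        "msa_values": msar.msa_values.tolist(),
    }
    if fit is not None:
        out["fit"] = {"a": fit.a, "beta": fit.beta, "sse": fit.sse}
        out["hc5"] = hc5_from_msar(fit)
    return out
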