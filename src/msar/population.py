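"""From fitted endpoint responses to species-level exposure-abundance curves.

Chronic effects on survival and reproduction jointly reduce the lifetime
fecundity of an exposed population,

    R0(c)/R0(0) = [1 / (1 + (c/EC50)^beta_rep)] * [1 / (1 + (c/LC50)^beta_surv)],

and under logistic growth with an unchanged generation time Tg the intrinsic
rate of increase r = ln(R0)/Tg scales as

    r(c)/r(0) = 1 - [ln(1 + (c/EC50)^beta_rep) + ln(1 + (c/LC50)^beta_surv)] / ln R0(0).

Since a proportional decrease in r corresponds to a proportional decrease in
the carrying capacity K, this ratio is read directly as the relative
equilibrium abundance K(c)/K(0).  Values below zero mean the population is
not viable at that exposure and are clamped to 0, which keeps the community
mean on its defined [0, 1] scale.

R0(0) comes from experiments where available, is fixed at 2 for clonal
species (algae), and otherwise follows allometric scalings of r and Tg with
adult body mass.  Because r and Tg scale with opposite exponents
(approximately W^-1/4 and W^+1/4), the allometric R0 is nearly independent
of body mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .doseresponse import DoseResponseFit, FitError
from .io_toxdata import EndpointClass, SpeciesTraits

__all__ = [
    "AllometryParams",
    "AbundanceCurve",
    "fecundity_ratio",
    "abundance_ratio",
    "r0_from_traits",
    "species_abundance_curve",
    "build_abundance_curves",
    "TraitError",
]


class TraitError(ValueError):
    """A species lacks the traits needed to derive R0."""


@dataclass(frozen=True)
class AllometryParams:
    """Allometric scalings r(W) = a_r * W^b_r (1/day), Tg(W) = a_T * W^b_T (days).

    The exponents default to the canonical quarter-power scalings with
    opposite signs; the intercepts depend on taxon and temperature and must
    be supplied (no defensible universal default exists).
    """

    a_r: float | None = None  # 1/day at W = 1 kg
    b_r: float = -0.25
    a_T: float | None = None  # days at W = 1 kg
    b_T: float = 0.25

    def r0(self, body_mass: float) -> float:
        """R0 = exp(r(W) * Tg(W)); mass-independent when b_r = -b_T."""
        if self.a_r is None or self.a_T is None:
            raise TraitError("allometric intercepts a_r and a_T are not configured")
        if body_mass <= 0:
            raise ValueError("body mass must be positive")
        r = self.a_r * body_mass**self.b_r
        tg = self.a_T * body_mass**self.b_T
        return math.exp(r * tg)


#: Lifetime fecundity assumed for clonal species (division into two daughters).
CLONAL_R0 = 2.0


def r0_from_traits(
    traits: SpeciesTraits, allometry: AllometryParams | None = None
) -> float:
    """Undisturbed lifetime fecundity with precedence experimental > clonal > allometric."""
    if traits.r0 is not None:
        return traits.r0
    if traits.is_clonal:
        return CLONAL_R0
    if traits.body_mass is not None:
        if allometry is None:
            raise TraitError(
                f"species {traits.species!r} has only body mass but no allometry "
                "parameters were provided"
            )
        r0 = allometry.r0(traits.body_mass)
        if r0 <= 1:
            raise TraitError(
                f"allometric R0 = {r0:.4g} <= 1 for {traits.species!r}; "
                "check intercepts (r * Tg must be positive)"
            )
        return r0
    raise TraitError(
        f"species {traits.species!r} has no usable trait (R0, clonal flag or body mass)"
    )


def _check_fit(fit: DoseResponseFit | None, name: str) -> None:
    if fit is not None and fit.is_direct:
        raise FitError(f"{name} must be a survival/reproduction response fit")


def fecundity_ratio(
    c,
    rep_fit: DoseResponseFit | None = None,
    surv_fit: DoseResponseFit | None = None,
):
    """Lifetime-fecundity ratio R0(c)/R0(0) from endpoint fits.

    The ratio is the product of one factor 1/(1 + (c/C50)^beta) per supplied
    endpoint; a missing endpoint contributes a factor of 1.
    """
    if rep_fit is None and surv_fit is None:
        raise ValueError("at least one of rep_fit, surv_fit is required")
    _check_fit(rep_fit, "rep_fit")
    _check_fit(surv_fit, "surv_fit")
    c = np.asarray(c, dtype=float)
    out = np.ones_like(c)
    with np.errstate(over="ignore"):
        for fit in (rep_fit, surv_fit):
            if fit is not None:
                out = out / (1.0 + (c / fit.c50) ** fit.beta)
    return out if out.ndim else float(out)


def abundance_ratio(
    c,
    rep_fit: DoseResponseFit | None = None,
    surv_fit: DoseResponseFit | None = None,
    r0: float = 2.0,
):
    """Relative abundance K(c)/K(0) of an exposed population.

    ``max(0, 1 - [sum of ln(1 + (c/C50)^beta) over endpoints] / ln R0)``.
    A negative raw value means r(c) < 0 (nonviable population) and is
    clamped to 0.
    """
    if rep_fit is None and surv_fit is None:
        raise ValueError("at least one of rep_fit, surv_fit is required")
    if r0 <= 1:
        raise ValueError(f"R0 must exceed 1 (got {r0}): ln R0 must be positive")
    _check_fit(rep_fit, "rep_fit")
    _check_fit(surv_fit, "surv_fit")
    c = np.asarray(c, dtype=float)
    log_terms = np.zeros_like(c)
    with np.errstate(over="ignore"):
        for fit in (rep_fit, surv_fit):
            if fit is not None:
                log_terms = log_terms + np.log1p((c / fit.c50) ** fit.beta)
    out = np.clip(1.0 - log_terms / math.log(r0), 0.0, None)
    return out if out.ndim else float(out)


# curve sources
COMBINED = "combined_surv_rep"
SURVIVAL_ONLY = "survival_only"
REPRODUCTION_ONLY = "reproduction_only"
DIRECT_ABUNDANCE = "direct_abundance"
STEP = "step"  # no-intraspecies-variation variant


@dataclass
class AbundanceCurve:
    """A species' exposure-abundance relationship K(c)/K(0), callable on concentrations.

    ``source`` records which endpoints fed the curve so variant builds and
    downstream filters can tell a full curve from a single-endpoint one.
    """

    species: str
    source: str
    components: dict[str, DoseResponseFit] = field(default_factory=dict)
    r0: float | None = None
    threshold: float | None = None  # only for step curves

    def __call__(self, c):
        c_arr = np.asarray(c, dtype=float)
        if self.source == STEP:
            out = np.where(c_arr < self.threshold, 1.0, 0.0)
        elif self.source == DIRECT_ABUNDANCE:
            fit = self.components["direct"]
            out = np.clip(fit.predict(c_arr), 0.0, 1.0)
        else:
            out = abundance_ratio(
                c_arr,
                rep_fit=self.components.get("reproduction"),
                surv_fit=self.components.get("survival"),
                r0=self.r0,
            )
            out = np.asarray(out)
        return out if out.ndim else float(out)

    @classmethod
    def from_endpoint_fits(
        cls,
        species: str,
        r0: float,
        rep_fit: DoseResponseFit | None = None,
        surv_fit: DoseResponseFit | None = None,
    ) -> "AbundanceCurve":
        if rep_fit is None and surv_fit is None:
            raise ValueError(f"species {species!r}: no endpoint fits supplied")
        if r0 <= 1:
            raise ValueError(f"species {species!r}: R0 must exceed 1, got {r0}")
        components = {}
        if rep_fit is not None:
            components["reproduction"] = rep_fit
        if surv_fit is not None:
            components["survival"] = surv_fit
        if rep_fit is not None and surv_fit is not None:
            source = COMBINED
        elif surv_fit is not None:
            source = SURVIVAL_ONLY
        else:
            source = REPRODUCTION_ONLY
        return cls(species=species, source=source, components=components, r0=r0)

    @classmethod
    def from_direct_fit(cls, fit: DoseResponseFit) -> "AbundanceCurve":
        if not fit.is_direct:
            raise ValueError("from_direct_fit needs an abundance/growth fit")
        return cls(
            species=fit.species,
            source=DIRECT_ABUNDANCE,
            components={"direct": fit},
            r0=fit.r0_used,
        )

    @classmethod
    def step_at(cls, species: str, threshold: float) -> "AbundanceCurve":
        """All-or-nothing curve: intact below the threshold, lost at and above it."""
        if threshold <= 0:
            raise ValueError("step threshold must be positive")
        return cls(species=species, source=STEP, threshold=threshold)


def species_abundance_curve(
    species: str,
    fits: Sequence[DoseResponseFit],
    r0: float | None = None,
) -> AbundanceCurve:
    """Build one species' abundance curve from its available endpoint fits.

    A direct abundance/growth fit takes precedence (it already measures the
    population-level response); otherwise reproduction and survival fits are
    combined through the growth model, which needs an R0.
    """
    direct = [f for f in fits if f.is_direct]
    if direct:
        return AbundanceCurve.from_direct_fit(direct[0])
    rep = next(
        (f for f in fits if f.endpoint_class == EndpointClass.REPRODUCTION), None
    )
    surv = next((f for f in fits if f.endpoint_class == EndpointClass.SURVIVAL), None)
    if r0 is None:
        raise TraitError(f"species {species!r} needs an R0 for endpoint-based curves")
    return AbundanceCurve.from_endpoint_fits(species, r0, rep_fit=rep, surv_fit=surv)


def build_abundance_curves(
    fits_by_species: Mapping[str, Sequence[DoseResponseFit]],
    traits_by_species: Mapping[str, SpeciesTraits] | None = None,
    allometry: AllometryParams | None = None,
) -> list[AbundanceCurve]:
    """Abundance curves for a whole panel; R0s resolved from traits as needed."""
    curves = []
    traits_by_species = traits_by_species or {}
    for species, fits in fits_by_species.items():
        r0 = None
        if not any(f.is_direct for f in fits):
            traits = traits_by_species.get(species)
            if traits is None:
                raise TraitError(f"no traits for species {species!r}")
            r0 = r0_from_traits(traits, allometry)
        curves.append(species_abundance_curve(species, fits, r0))
    return curves
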