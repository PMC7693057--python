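"""Synthetic multi-species toxicity panels with known ground truth.

A panel mimics the structure of a compiled chronic-toxicity dataset for one
chemical: a mix of animal species tested on reproduction and survival (some
on survival alone) and clonal algae tested directly on abundance, each
species observed at a handful of log-spaced concentrations plus a control.
Defaults mirror a metals case study at its published scale: 10-18 species,
6 concentrations per test, interspecies half-effect concentrations spread
over about an order of magnitude, Hill slopes between 1 and 4.

Noise follows the mechanisms of the underlying assays: survival fractions
are binomial counts out of ``binomial_n`` test organisms; reproduction and
abundance fractions get additive Gaussian error truncated to [0, 1].  Real
compiled datasets additionally contain between-study heterogeneity, uneven
designs and censored endpoints, none of which are emulated here.

Ground truth (every generating parameter) is returned alongside the
records, so parameter- and HC5-recovery are directly checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_toxdata import EndpointClass, SpeciesTraits, ToxRecord
from .msar_core import MSARCurve, aggregate_msar
from .population import AbundanceCurve, abundance_ratio

__all__ = ["PanelSpec", "generate_panel", "true_msar", "true_curves"]

KIND_BOTH = "animal_both"
KIND_SURVIVAL = "animal_survival_only"
KIND_ALGAE = "algae_direct"


@dataclass
class PanelSpec:
    """Generator settings for one synthetic panel.

    ``frac_*`` give the trophic mix (they must sum to 1); counts are rounded
    with at least the remainder going to the first group.  Concentrations
    per test are log-spaced over ±1.5 decades around each species' typical
    half-effect concentration, plus a control at 0.
    """

    n_species: int = 16
    frac_both: float = 0.6
    frac_survival_only: float = 0.1
    frac_algae: float = 0.3
    log10_c50_mean: float = 1.0  # median interspecies EC50 = 10 ug/L
    log10_c50_sd: float = 0.5  # ~1 order of magnitude interspecies spread
    beta_range: tuple[float, float] = (1.0, 4.0)
    lc50_shift_decades: tuple[float, float] = (0.3, 1.0)  # LC50/EC50, log10
    r0_range: tuple[float, float] = (5.0, 100.0)  # animals, log-uniform
    n_concentrations: int = 6
    conc_span_decades: float = 1.5
    binomial_n: int | None = 20  # survival noise; None = noise-free
    gaussian_sd: float = 0.05  # reproduction/abundance noise; 0 = noise-free
    seed: int = 0
    chemical: str = "synthetic"

    def __post_init__(self):
        fracs = (self.frac_both, self.frac_survival_only, self.frac_algae)
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("trophic-mix fractions must be nonnegative and sum to 1")
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        if self.n_concentrations < 3:
            raise ValueError("need at least 3 concentrations per test")
        if self.log10_c50_sd < 0 or self.gaussian_sd < 0:
            raise ValueError("scale parameters must be nonnegative")
        if self.binomial_n is not None and self.binomial_n < 1:
            raise ValueError("binomial_n must be positive")


def _species_counts(spec: PanelSpec) -> tuple[int, int, int]:
    n_surv = round(spec.n_species * spec.frac_survival_only)
    n_algae = round(spec.n_species * spec.frac_algae)
    n_both = spec.n_species - n_surv - n_algae
    if n_both < 0:
        n_algae += n_both
        n_both = 0
    return n_both, n_surv, n_algae


def generate_panel(
    spec: PanelSpec,
) -> tuple[list[ToxRecord], list[SpeciesTraits], pd.DataFrame]:
    """Simulate one panel: records, traits, and the ground-truth table.

    The truth table has one row per species with columns ``species``,
    ``kind``, ``ec50``, ``beta_rep``, ``lc50``, ``beta_surv``, ``c50``,
    ``beta`` (direct fits), and ``r0``; parameters a species does not have
    are NaN.  The same spec and seed always produce the identical panel.
    """
    rng = np.random.default_rng(spec.seed)
    n_both, n_surv, n_algae = _species_counts(spec)
    kinds = [KIND_BOTH] * n_both + [KIND_SURVIVAL] * n_surv + [KIND_ALGAE] * n_algae

    records: list[ToxRecord] = []
    traits: list[SpeciesTraits] = []
    truth_rows = []
    b_lo, b_hi = spec.beta_range
    for i, kind in enumerate(kinds):
        name = f"sp{i + 1:02d}_{kind}"
        c50_typ = 10.0 ** rng.normal(spec.log10_c50_mean, spec.log10_c50_sd)
        row = {
            "species": name, "kind": kind,
            "ec50": np.nan, "beta_rep": np.nan,
            "lc50": np.nan, "beta_surv": np.nan,
            "c50": np.nan, "beta": np.nan, "r0": np.nan,
        }
        if kind == KIND_ALGAE:
            row["c50"] = c50_typ
            row["beta"] = rng.uniform(b_lo, b_hi)
            row["r0"] = 2.0
            traits.append(SpeciesTraits(species=name, is_clonal=True))
            anchor = c50_typ
        else:
            row["r0"] = float(
                np.exp(rng.uniform(*np.log(spec.r0_range)))
            )
            traits.append(SpeciesTraits(species=name, r0=row["r0"]))
            if kind == KIND_BOTH:
                row["ec50"] = c50_typ
                row["beta_rep"] = rng.uniform(b_lo, b_hi)
                row["lc50"] = c50_typ * 10.0 ** rng.uniform(*spec.lc50_shift_decades)
                row["beta_surv"] = rng.uniform(b_lo, b_hi)
                anchor = float(np.sqrt(row["ec50"] * row["lc50"]))
            else:  # survival only
                row["lc50"] = c50_typ
                row["beta_surv"] = rng.uniform(b_lo, b_hi)
                anchor = c50_typ
        truth_rows.append(row)

        concs = np.concatenate(
            [
                [0.0],
                anchor
                * np.logspace(
                    -spec.conc_span_decades,
                    spec.conc_span_decades,
                    spec.n_concentrations,
                ),
            ]
        )
        records.extend(_simulate_species(rng, spec, name, row, concs))

    truth = pd.DataFrame(truth_rows)
    return records, traits, truth


def _loglogistic(c, c50, beta):
    with np.errstate(over="ignore"):
        return 1.0 - 1.0 / (1.0 + (c / c50) ** beta)


def _simulate_species(rng, spec, name, row, concs):
    out = []
    if not np.isnan(row["lc50"]):
        p = _loglogistic(concs, row["lc50"], row["beta_surv"])
        if spec.binomial_n is not None:
            n = spec.binomial_n
            obs = rng.binomial(n, p) / n
            n_sub = n
        else:
            obs, n_sub = p, None
        for c, y in zip(concs, obs):
            out.append(
                ToxRecord(
                    chemical=spec.chemical, species=name,
                    endpoint_class=EndpointClass.SURVIVAL,
                    concentration=float(c), response=float(y), n_subjects=n_sub,
                )
            )
    if not np.isnan(row["ec50"]):
        y = _loglogistic(concs, row["ec50"], row["beta_rep"])
        if spec.gaussian_sd > 0:
            y = np.clip(y + rng.normal(0.0, spec.gaussian_sd, y.size), 0.0, 1.0)
        for c, yy in zip(concs, y):
            out.append(
                ToxRecord(
                    chemical=spec.chemical, species=name,
                    endpoint_class=EndpointClass.REPRODUCTION,
                    concentration=float(c), response=float(yy),
                )
            )
    if not np.isnan(row["c50"]):
        with np.errstate(over="ignore"):
            k = np.clip(
                1.0 - np.log1p((concs / row["c50"]) ** row["beta"]) / np.log(row["r0"]),
                0.0,
                1.0,
            )
        if spec.gaussian_sd > 0:
            k = np.clip(k + rng.normal(0.0, spec.gaussian_sd, k.size), 0.0, 1.0)
        for c, kk in zip(concs, k):
            out.append(
                ToxRecord(
                    chemical=spec.chemical, species=name,
                    endpoint_class=EndpointClass.ABUNDANCE,
                    concentration=float(c), response=float(1.0 - kk),
                )
            )
    return out


def _truth_fit(row, which):
    """A point-estimate DoseResponseFit built from a truth-table row."""
    from .doseresponse import DoseResponseFit

    if which == "reproduction":
        return DoseResponseFit(
            species=row["species"], endpoint_class=EndpointClass.REPRODUCTION,
            c50=row["ec50"], beta=row["beta_rep"],
        )
    if which == "survival":
        return DoseResponseFit(
            species=row["species"], endpoint_class=EndpointClass.SURVIVAL,
            c50=row["lc50"], beta=row["beta_surv"],
        )
    return DoseResponseFit(
        species=row["species"], endpoint_class=EndpointClass.ABUNDANCE,
        c50=row["c50"], beta=row["beta"], r0_used=row["r0"],
    )


def true_curves(truth: pd.DataFrame) -> list[AbundanceCurve]:
    """Species abundance curves built from the generating parameters."""
    curves = []
    for _, row in truth.iterrows():
        if row["kind"] == KIND_ALGAE:
            curves.append(AbundanceCurve.from_direct_fit(_truth_fit(row, "direct")))
        else:
            rep = None if np.isnan(row["ec50"]) else _truth_fit(row, "reproduction")
            surv = None if np.isnan(row["lc50"]) else _truth_fit(row, "survival")
            curves.append(
                AbundanceCurve.from_endpoint_fits(
                    row["species"], row["r0"], rep_fit=rep, surv_fit=surv
                )
            )
    return curves


def true_msar(
    truth: pd.DataFrame, grid: Sequence[float], chemical: str = "synthetic"
) -> MSARCurve:
    """The MSAR implied by the generating parameters: the recovery target."""
    return aggregate_msar(true_curves(truth), grid, chemical=chemical)
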