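"""End-to-end orchestration: fit -> abundance curves -> MSAR -> SSD -> envelope.

Mirrors the framework's workflow: (A) fit log-logistic exposure-response
curves per species and endpoint, (B) convert survival/reproduction fits to
exposure-abundance curves through the population-growth model, (C) fit
abundance/growth endpoints directly, (D) aggregate all species curves into
the community MSAR.  On top of that, the companion EC10-based SSD and the
Monte-Carlo uncertainty envelope are computed, and a comparison report
(MSAR HC5 vs SSD HC5-EC10, MSA loss at the SSD HC5) is produced.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io_toxdata as io
from .config import RunConfig
from .doseresponse import (
    DoseResponseFit,
    FitConvergenceError,
    FitError,
    fit_abundance_direct,
    fit_response,
)
from .io_toxdata import EndpointClass, SpeciesTraits, ToxRecord
from .msar_core import (
    MSARCurve,
    default_grid,
    fit_msar_loglogistic,
    hc5_from_msar,
    hc5_raw,
    msa_loss_at,
    msar_to_dict,
    variant_msar,
)
from .population import AllometryParams, r0_from_traits
from .ssd import bootstrap_hc5_ci, ec10_table, fit_ssd, hc5_from_ssd, ssd_to_dict
from .uncertainty import envelope_to_dict, msar_envelope

logger = logging.getLogger(__name__)

__all__ = ["fit_panel", "run_pipeline", "report_comparison", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def fit_panel(
    records: Sequence[ToxRecord],
    traits_by_species: Mapping[str, SpeciesTraits] | None = None,
    allometry: AllometryParams | None = None,
    weight_by_n: bool = False,
    validate: bool = True,
) -> dict[str, list[DoseResponseFit]]:
    """Fit every (species, endpoint) group of a panel; step A/C of the workflow.

    Survival and reproduction groups go through the response fit; abundance
    and population-growth groups through the direct carrying-capacity fit,
    which needs the species' R0 (resolved from traits).  Groups that fail
    their preconditions raise; convergence failures carry diagnostics.
    """
    traits_by_species = traits_by_species or {}
    groups = io.group_records(records)
    if validate:
        io.validate_groups(groups)
    fits: dict[str, list[DoseResponseFit]] = {}
    for (chem, species, endpoint), grp in groups.items():
        if endpoint.is_fraction_of_control:
            traits = traits_by_species.get(species)
            if traits is None:
                raise PipelineError(
                    f"fit stage: species {species!r} has a {endpoint.value} endpoint "
                    "but no traits to resolve its R0"
                )
            r0 = r0_from_traits(traits, allometry)
            fit = fit_abundance_direct(grp, r0, weight_by_n=weight_by_n)
        else:
            fit = fit_response(grp, weight_by_n=weight_by_n)
        fits.setdefault(species, []).append(fit)
        logger.info(
            "fitted %s / %s (%s): C50=%.4g beta=%.3g (n=%d)",
            chem, species, endpoint.value, fit.c50, fit.beta, fit.n_points,
        )
    return fits


def report_comparison(msar_result: Mapping, ssd_result: Mapping) -> dict:
    """Side-by-side HC5 comparison of the MSAR and SSD routes for one chemical.

    Rows: the MSAR-based HC5 (with its Monte-Carlo CI when available), the
    SSD HC5-EC10 (with its bootstrap CI), their ratio, and the community
    abundance loss at the SSD's own HC5-EC10.
    """
    if msar_result.get("chemical") != ssd_result.get("chemical"):
        raise ValueError(
            f"chemical mismatch: MSAR is for {msar_result.get('chemical')!r}, "
            f"SSD for {ssd_result.get('chemical')!r}"
        )
    msar_hc5 = msar_result["hc5"]
    ssd_hc5 = ssd_result["hc5"]
    fit = msar_result["fit"]
    c = ssd_hc5
    loss = 1.0 - 1.0 / (1.0 + (c / fit["a"]) ** fit["beta"])
    out = {
        "chemical": msar_result.get("chemical"),
        "msar_hc5": msar_hc5,
        "msar_hc5_ci": msar_result.get("hc5_ci"),
        "ssd_hc5_ec10": ssd_hc5,
        "ssd_hc5_ci": ssd_result.get("hc5_ci"),
        "hc5_ratio_msar_over_ssd": msar_hc5 / ssd_hc5 if ssd_hc5 > 0 else float("inf"),
        "msa_loss_at_hc5_ec10": loss,
    }
    if "loss_band" in msar_result:
        out["msa_loss_at_hc5_ec10_ci"] = msar_result["loss_band"]
    return out


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow and write fits/msar/ssd/env/report JSON files.

    Returns the report bundle (also written to ``report.json``).  Any stage
    failure raises :class:`PipelineError` naming the stage; files written by
    earlier stages are left in place.
    """
    config.validate_files()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()

    # --- read stage -------------------------------------------------------
    try:
        records = io.read_tox_table(
            config.input,
            schema=config.schema,
            endpoint_mapping=config.endpoint_table(),
            strict=config.strict_endpoints,
            unit_factor=config.unit_factor,
        )
        if config.chemical is not None:
            records = [r for r in records if r.chemical == config.chemical]
            if not records:
                raise io.ValidationError(
                    f"no records for chemical {config.chemical!r}"
                )
        if config.abbott:
            records = io.abbott_correct(records)
        traits_list = (
            io.read_traits_table(config.traits) if config.traits else []
        )
        traits = {t.species: t for t in traits_list}
    except Exception as err:
        raise PipelineError(f"read stage failed: {err}") from err

    chemical = records[0].chemical
    allometry = config.allometry_params()

    # --- fit stage (workflow steps A and C) -------------------------------
    try:
        fits = fit_panel(
            records, traits, allometry, weight_by_n=config.weight_by_n
        )
        conc = [r.concentration for r in records]
        io.write_fits_json(
            [f for fl in fits.values() for f in fl],
            outdir / "fits.json",
            meta={**meta, "chemical": chemical,
                  "concentration_range": [min(c for c in conc if c > 0), max(conc)]},
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"fit stage failed: {err}") from err

    # --- MSAR stage (workflow steps B and D) ------------------------------
    try:
        grid = default_grid(conc, n=config.grid_n)
        msar = variant_msar(
            fits, grid, variant=config.variant,
            traits_by_species=traits, allometry=allometry, chemical=chemical,
        )
        msar_fit = fit_msar_loglogistic(msar)
        hc5 = hc5_from_msar(msar_fit) if config.hc5_on == "fit" else hc5_raw(msar)
        msar_payload = msar_to_dict(msar, msar_fit)
        msar_payload["hc5"] = hc5
        msar_payload["hc5_on"] = config.hc5_on
        msar_payload["meta"] = meta
        _json_dump(msar_payload, outdir / "msar.json")
    except Exception as err:
        raise PipelineError(f"msar stage failed: {err}") from err

    # --- SSD stage --------------------------------------------------------
    try:
        ec10s = ec10_table(fits)
        ssd_fit = fit_ssd(list(ec10s.values()), chemical=chemical)
        ssd_hc5 = hc5_from_ssd(ssd_fit)
        ssd_ci = bootstrap_hc5_ci(
            list(ec10s.values()), n_boot=config.n_boot, seed=config.seed
        )
        ssd_payload = ssd_to_dict(ssd_fit, hc5=ssd_hc5, ci=ssd_ci)
        ssd_payload["ec10_by_species"] = ec10s
        ssd_payload["meta"] = meta
        _json_dump(ssd_payload, outdir / "ssd.json")
    except Exception as err:
        raise PipelineError(f"ssd stage failed: {err}") from err

    # --- uncertainty stage ------------------------------------------------
    try:
        env = msar_envelope(
            fits, grid, n_iter=config.n_iter, seed=config.seed,
            traits_by_species=traits, allometry=allometry, chemical=chemical,
            include_residual=config.include_residual,
        )
        env_payload = envelope_to_dict(env)
        env_payload["meta"] = meta
        _json_dump(env_payload, outdir / "env.json")
    except Exception as err:
        raise PipelineError(f"envelope stage failed: {err}") from err

    # --- report -----------------------------------------------------------
    try:
        msar_payload["hc5_ci"] = list(env.hc5_ci)
        # band of the community loss at the SSD HC5, from the envelope
        lo = float(np.interp(ssd_hc5, env.grid, env.upper95))
        hi = float(np.interp(ssd_hc5, env.grid, env.lower95))
        msar_payload["loss_band"] = [1.0 - lo, 1.0 - hi]
        report = report_comparison(msar_payload, ssd_payload)
        report["meta"] = meta
        _json_dump(report, outdir / "report.json")
    except Exception as err:
        raise PipelineError(f"report stage failed: {err}") from err
    return report
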