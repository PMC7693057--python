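"""Reading, validation and categorization of chronic toxicity test tables.

Input tables are tidy CSV/TSV files with one observed (concentration,
response) point per row.  Internally every response is stored in a single
canonical orientation -- *fraction affected* (0 at control, 1 at total
effect) -- regardless of how it arrived:

* survival data may arrive as survivor counts (``survivors`` of
  ``n_subjects``) and are converted to ``1 - survivors/n``;
* abundance and population-growth data arrive as fraction-of-control
  (K(c)/K(0)) and are stored as ``1 - fraction_of_control``.  The endpoint
  class records this so the direct abundance fit can invert exactly once.

One canonical orientation avoids sign bugs downstream; the conversion back
to K-ratios happens in a single place (:func:`msar.doseresponse.fit_abundance_direct`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EndpointClass",
    "ToxRecord",
    "SpeciesTraits",
    "SchemaError",
    "ValidationError",
    "read_tox_table",
    "write_tox_table",
    "read_traits_table",
    "write_traits_table",
    "categorize_endpoint",
    "abbott_correct",
    "group_records",
    "validate_groups",
    "DEFAULT_ENDPOINT_LABELS",
]


class SchemaError(ValueError):
    """Input table columns cannot be mapped to the expected fields."""


class ValidationError(ValueError):
    """Parsed values violate the record invariants."""


class EndpointClass(str, Enum):
    """The four chronic-test endpoint classes the framework consumes."""

    SURVIVAL = "survival"
    REPRODUCTION = "reproduction"
    ABUNDANCE = "abundance"
    POPULATION_GROWTH = "population_growth"

    @property
    def is_fraction_of_control(self) -> bool:
        """True for endpoints whose raw data are K(c)/K(0) ratios."""
        return self in (EndpointClass.ABUNDANCE, EndpointClass.POPULATION_GROWTH)


#: Default mapping from raw endpoint labels (lower-cased) to endpoint class.
#: Users extend or replace it via the YAML config; chronic-test literature
#: uses a wide range of labels for what is functionally the same endpoint.
DEFAULT_ENDPOINT_LABELS: dict[str, EndpointClass] = {
    "survival": EndpointClass.SURVIVAL,
    "mortality": EndpointClass.SURVIVAL,
    "lethality": EndpointClass.SURVIVAL,
    "immobilization": EndpointClass.SURVIVAL,
    "reproduction": EndpointClass.REPRODUCTION,
    "fecundity": EndpointClass.REPRODUCTION,
    "hatchability": EndpointClass.REPRODUCTION,
    "hatching success": EndpointClass.REPRODUCTION,
    "number of eggs": EndpointClass.REPRODUCTION,
    "number of offspring": EndpointClass.REPRODUCTION,
    "number of gravid adult females": EndpointClass.REPRODUCTION,
    "abundance": EndpointClass.ABUNDANCE,
    "frond count": EndpointClass.ABUNDANCE,
    "cell density": EndpointClass.ABUNDANCE,
    "biomass": EndpointClass.ABUNDANCE,
    "population_growth": EndpointClass.POPULATION_GROWTH,
    "population growth": EndpointClass.POPULATION_GROWTH,
    "growth rate": EndpointClass.POPULATION_GROWTH,
    "specific growth rate": EndpointClass.POPULATION_GROWTH,
}


@dataclass(frozen=True)
class ToxRecord:
    """One observed exposure-response point.

    ``response`` is always the fraction affected: for abundance /
    population-growth endpoints the stored value is ``1 - K(c)/K(0)``.
    """

    chemical: str
    species: str
    endpoint_class: EndpointClass
    concentration: float  # ug/L
    response: float  # fraction affected in [0, 1]
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"negative concentration {self.concentration} for {self.species}"
            )
        if not 0.0 <= self.response <= 1.0:
            raise ValidationError(
                f"response {self.response} outside [0, 1] for {self.species} "
                f"({self.endpoint_class.value}) at c={self.concentration}"
            )
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValidationError(f"n_subjects must be positive, got {self.n_subjects}")


@dataclass(frozen=True)
class SpeciesTraits:
    """Life-history traits used to obtain the undisturbed lifetime fecundity R0.

    At least one of an experimental ``r0``, ``is_clonal=True``, or a
    ``body_mass`` (for the allometric route) must be present for the species
    to enter the community aggregation.
    """

    species: str
    body_mass: float | None = None  # kg
    r0: float | None = None  # offspring per adult, dimensionless, > 1
    tg: float | None = None  # generation time, days
    is_clonal: bool = False

    def __post_init__(self) -> None:
        if self.r0 is not None and self.r0 <= 1:
            raise ValidationError(
                f"R0 must exceed 1 (ln R0 > 0 required), got {self.r0} for {self.species}"
            )
        if self.body_mass is not None and self.body_mass <= 0:
            raise ValidationError(f"body_mass must be positive for {self.species}")
        if self.tg is not None and self.tg <= 0:
            raise ValidationError(f"generation time must be positive for {self.species}")
        if self.r0 is None and self.body_mass is None and not self.is_clonal:
            raise ValidationError(
                f"species {self.species!r} has no usable trait: provide R0, "
                "body_mass, or is_clonal=True"
            )


def categorize_endpoint(
    raw_label: str,
    mapping: Mapping[str, EndpointClass] | None = None,
    strict: bool = True,
) -> EndpointClass | None:
    """Map a raw endpoint label to one of the four endpoint classes.

    Matching is case-insensitive on the stripped label.  With ``strict``
    an unmapped label raises; otherwise ``None`` is returned and the caller
    is expected to skip the record (a warning is logged).
    """
    table = DEFAULT_ENDPOINT_LABELS if mapping is None else mapping
    key = raw_label.strip().lower()
    if key in table:
        return EndpointClass(table[key])
    try:  # the canonical class names themselves always map
        return EndpointClass(key)
    except ValueError:
        pass
    if strict:
        raise SchemaError(f"unmapped endpoint label: {raw_label!r}")
    logger.warning("skipping records with unmapped endpoint label %r", raw_label)
    return None


_DEFAULT_SCHEMA = {
    "chemical": "chemical",
    "species": "species",
    "endpoint": "endpoint",
    "concentration": "concentration",
    "response": "response",
    "survivors": "survivors",
    "n_subjects": "n_subjects",
}


def read_tox_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    endpoint_mapping: Mapping[str, EndpointClass] | None = None,
    strict: bool = True,
    unit_factor: float = 1.0,
) -> list[ToxRecord]:
    """Read a tidy toxicity table (CSV/TSV) into validated records.

    Parameters
    ----------
    path
        CSV (or TSV, by ``.tsv`` suffix) file with a header row.
    schema
        Mapping from canonical field names (``chemical``, ``species``,
        ``endpoint``, ``concentration``, ``response``, ``survivors``,
        ``n_subjects``) to the file's column names.  Unmentioned fields keep
        their canonical name.
    endpoint_mapping
        Label table for :func:`categorize_endpoint`.
    strict
        Whether unmapped endpoint labels are an error or a skip.
    unit_factor
        Multiplier converting the file's concentration unit to ug/L.

    Count-type survival rows (``survivors`` of ``n_subjects``) are converted
    to fractions affected; abundance / population-growth responses, which
    arrive as fraction-of-control, are stored as ``1 - value``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)

    for required in ("chemical", "species", "endpoint", "concentration"):
        if cols[required] not in df.columns:
            raise SchemaError(
                f"missing required column {cols[required]!r} (for field {required!r}); "
                f"available: {list(df.columns)}"
            )
    has_response = cols["response"] in df.columns
    has_counts = cols["survivors"] in df.columns and cols["n_subjects"] in df.columns
    if not has_response and not has_counts:
        raise SchemaError(
            "table must provide either a response column or survivors + n_subjects"
        )

    records: list[ToxRecord] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        endpoint = categorize_endpoint(str(row[cols["endpoint"]]), endpoint_mapping, strict)
        if endpoint is None:
            continue
        n_subjects = None
        if has_counts and pd.notna(row.get(cols["survivors"], float("nan"))):
            n = int(row[cols["n_subjects"]])
            response = 1.0 - float(row[cols["survivors"]]) / n
            n_subjects = n
        else:
            response = float(row[cols["response"]])
            if has_counts is False and cols["n_subjects"] in df.columns and pd.notna(
                row[cols["n_subjects"]]
            ):
                n_subjects = int(row[cols["n_subjects"]])
            if endpoint.is_fraction_of_control:
                response = 1.0 - response
        try:
            records.append(
                ToxRecord(
                    chemical=str(row[cols["chemical"]]),
                    species=str(row[cols["species"]]),
                    endpoint_class=endpoint,
                    concentration=float(row[cols["concentration"]]) * unit_factor,
                    response=response,
                    n_subjects=n_subjects,
                )
            )
        except ValidationError as err:
            bad_rows.append(f"row {idx}: {err}")
    if bad_rows:
        raise ValidationError(
            "invalid rows in %s:\n%s" % (path, "\n".join(bad_rows))
        )
    return records


def write_tox_table(records: Iterable[ToxRecord], path: str | Path) -> None:
    """Write records to CSV in each endpoint's native orientation.

    Abundance / population-growth responses are written back as
    fraction-of-control (the form they are reported in), so reading the file
    with :func:`read_tox_table` reproduces the records exactly.
    """
    rows = []
    for r in records:
        row = asdict(r)
        row["endpoint"] = r.endpoint_class.value
        del row["endpoint_class"]
        if r.endpoint_class.is_fraction_of_control:
            row["response"] = 1.0 - r.response
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["chemical", "species", "endpoint", "concentration", "response",
                 "n_subjects"],
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_traits_table(path: str | Path) -> list[SpeciesTraits]:
    """Read a species traits CSV (species, body_mass_kg, R0, Tg_days, is_clonal)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "species" not in df.columns:
        raise SchemaError("traits table needs a 'species' column")
    aliases = {"body_mass_kg": "body_mass", "R0": "r0", "Tg_days": "tg"}
    df = df.rename(columns=aliases)
    out = []
    for _, row in df.iterrows():
        def opt(col: str) -> float | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        clonal = row.get("is_clonal", False)
        out.append(
            SpeciesTraits(
                species=str(row["species"]),
                body_mass=opt("body_mass"),
                r0=opt("r0"),
                tg=opt("tg"),
                is_clonal=bool(clonal) and str(clonal).lower() not in ("false", "0", "nan"),
            )
        )
    return out


def write_traits_table(traits: Iterable[SpeciesTraits], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in traits]).to_csv(
        path, index=False, float_format="%.17g"
    )


def abbott_correct(records: Sequence[ToxRecord]) -> list[ToxRecord]:
    """Normalize responses to the control group (Abbott's correction).

    Within each (chemical, species, endpoint) group, if the control (lowest
    concentration, ideally 0) shows a nonzero response r0, every response is
    replaced by ``max(0, (r - r0) / (1 - r0))``.  This is the standard
    correction for background mortality in chronic tests.  A control with
    r0 = 1 (total background effect) makes the group uninformative and raises.
    """
    corrected: list[ToxRecord] = []
    for _, group in group_records(records).items():
        r0 = min(group, key=lambda r: r.concentration).response
        if r0 == 0:
            corrected.extend(group)
            continue
        if r0 >= 1:
            raise ValidationError(
                f"control response is 1 for {group[0].species} "
                f"({group[0].endpoint_class.value}): group uninformative"
            )
        for r in group:
            corrected.append(
                ToxRecord(
                    chemical=r.chemical,
                    species=r.species,
                    endpoint_class=r.endpoint_class,
                    concentration=r.concentration,
                    response=max(0.0, (r.response - r0) / (1.0 - r0)),
                    n_subjects=r.n_subjects,
                )
            )
    return corrected


def group_records(
    records: Iterable[ToxRecord],
) -> dict[tuple[str, str, EndpointClass], list[ToxRecord]]:
    """Partition records by (chemical, species, endpoint_class), preserving order."""
    groups: dict[tuple[str, str, EndpointClass], list[ToxRecord]] = {}
    for r in records:
        groups.setdefault((r.chemical, r.species, r.endpoint_class), []).append(r)
    return groups


def validate_groups(
    groups: Mapping[tuple[str, str, EndpointClass], Sequence[ToxRecord]],
) -> None:
    """Check that every group can support a stable 2-parameter fit.

    Each (chemical, species, endpoint) group needs at least 3 distinct
    concentrations, one of which must be a control: either c = 0 or a
    concentration at which no effect was observed (response 0).
    """
    problems = []
    for key, group in groups.items():
        concs = sorted({r.concentration for r in group})
        if len(concs) < 3:
            problems.append(f"{key}: only {len(concs)} distinct concentrations")
            continue
        has_control = any(
            r.concentration == 0 or (r.concentration == concs[0] and r.response == 0)
            for r in group
        )
        if not has_control:
            problems.append(f"{key}: no control (c=0 or zero-effect lowest concentration)")
    if problems:
        raise ValidationError("groups failing fit preconditions:\n" + "\n".join(problems))


def write_fits_json(fits, path: str | Path, meta: Mapping | None = None) -> None:
    """Serialize dose-response fits (see :mod:`msar.doseresponse`) to JSON."""
    from .doseresponse import fit_to_dict

    payload = {"fits": [fit_to_dict(f) for f in fits]}
    if meta:
        payload["meta"] = dict(meta)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fits_json(path: str | Path):
    from .doseresponse import fit_from_dict

    payload = json.loads(Path(path).read_text())
    return [fit_from_dict(d) for d in payload["fits"]]
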