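"""Study-observation database: reading, validation, and screening filters.

The database holds one row per paired monoculture-vs-intercropping
observation (treatment = intercropping, control = monoculture), together
with the categorical moderators (nitrogen source, companion crop, sampling
compartment, ...) and continuous covariates (climate, nitrogen rate,
planting-density ratios, initial soil properties) used downstream.

Files are plain CSV (RFC-4180, UTF-8) with a fixed, case-sensitive header.
Missing values are empty fields on disk and ``NaN`` in memory.  The final
``schema_version`` column guards against dialect drift.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

TRAITS = frozenset({"shannon", "chao1", "richness", "beta_diversity", "structure", "yield"})
TAXON_GROUPS = frozenset({"bacteria", "fungi", "special_fungi", "unspecified"})
N_SOURCES = frozenset({"mineral", "organic", "mixed", "none"})
N_TIMINGS = frozenset({"basal", "topdressing", "none"})
COMPANION_TYPES = frozenset({"legume", "non_legume"})
SYSTEMS = frozenset({"soy_maize", "non_soy_maize"})
CONDITIONS = frozenset({"pot", "field"})
COMPARTMENTS = frozenset({"rhizosphere", "bulk"})
STRIPS = frozenset({"soybean", "non_soybean"})

_ENUM_LEVELS = {
    "trait": TRAITS,
    "taxon_group": TAXON_GROUPS,
    "n_source": N_SOURCES,
    "n_timing": N_TIMINGS,
    "companion_type": COMPANION_TYPES,
    "system": SYSTEMS,
    "condition": CONDITIONS,
    "compartment": COMPARTMENTS,
    "strip": STRIPS,
}

_OPTIONAL_FLOAT_FIELDS = (
    "map_mm", "mat_c", "duration_yr", "nfr_kg_ha", "rdt", "prdt",
    "phi", "soci", "tni", "rows_soybean", "dist_soybean_m",
)


@dataclass(eq=False)
class StudyObservation:
    """One paired monoculture/intercropping measurement.

    Equality is field-for-field with missing (NaN) treated as equal to
    missing, so a written-then-reloaded database compares equal; the
    in-memory imputation flags are excluded.
    """

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyObservation):
            return NotImplemented
        for f in dc_fields(self):
            if f.name.endswith("_imputed"):
                continue
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, float) and isinstance(b, float):
                if not (a == b or (math.isnan(a) and math.isnan(b))):
                    return False
            elif a != b:
                return False
        return True

    study_id: str
    obs_id: str
    trait: str
    taxon_group: str
    mean_treat: float
    mean_ctrl: float
    sd_treat: float  # NaN when unreported
    sd_ctrl: float
    n_treat: int
    n_ctrl: int
    n_source: str
    n_timing: str
    companion_type: str
    system: str
    condition: str
    compartment: str
    strip: str
    map_mm: float = math.nan
    mat_c: float = math.nan
    duration_yr: float = math.nan
    nfr_kg_ha: float = math.nan
    rdt: float = math.nan
    prdt: float = math.nan
    phi: float = math.nan
    soci: float = math.nan
    tni: float = math.nan
    rows_soybean: float = math.nan
    dist_soybean_m: float = math.nan
    is_final_year: bool = True
    # set by SD imputation; not part of the file schema
    sd_treat_imputed: bool = field(default=False, compare=False)
    sd_ctrl_imputed: bool = field(default=False, compare=False)


# column order of the on-disk schema (all StudyObservation fields except the
# in-memory imputation flags, plus the trailing schema_version guard)
COLUMNS: tuple[str, ...] = tuple(
    f.name for f in dc_fields(StudyObservation)
    if not f.name.endswith("_imputed")
) + ("schema_version",)


@dataclass(frozen=True)
class ValidationIssue:
    """One rejected row: 1-based data-row number, offending field, reason."""

    row: int
    field: str
    reason: str


class DatabaseError(ValueError):
    """Fatal database-level problem (unreadable file, bad header)."""


def _parse_float(text: str) -> float:
    return math.nan if text == "" else float(text)


def _parse_row(record: dict[str, str], row_num: int) -> tuple[StudyObservation | None, list[ValidationIssue]]:
    issues: list[ValidationIssue] = []

    def bad(field_name: str, reason: str) -> None:
        issues.append(ValidationIssue(row_num, field_name, reason))

    for name, levels in _ENUM_LEVELS.items():
        if record[name] not in levels:
            bad(name, f"unknown enum level {record[name]!r}")

    kwargs: dict[str, object] = {}
    for name in ("mean_treat", "mean_ctrl"):
        try:
            val = float(record[name])
        except ValueError:
            bad(name, f"not a number: {record[name]!r}")
            val = math.nan
        if not val > 0:
            bad(name, "non-positive mean")
        kwargs[name] = val
    for name in ("sd_treat", "sd_ctrl"):
        try:
            val = _parse_float(record[name])
        except ValueError:
            bad(name, f"not a number: {record[name]!r}")
            val = math.nan
        if val < 0:
            bad(name, "negative SD")
        kwargs[name] = val
    for name in ("n_treat", "n_ctrl"):
        try:
            ival = int(record[name])
        except ValueError:
            bad(name, f"not an integer: {record[name]!r}")
            ival = 0
        if ival < 1:
            bad(name, "sample size < 1")
        kwargs[name] = ival
    for name in _OPTIONAL_FLOAT_FIELDS:
        try:
            kwargs[name] = _parse_float(record[name])
        except ValueError:
            bad(name, f"not a number: {record[name]!r}")
    flag = record["is_final_year"].strip().lower()
    if flag in {"true", "1", "yes"}:
        kwargs["is_final_year"] = True
    elif flag in {"false", "0", "no"}:
        kwargs["is_final_year"] = False
    else:
        bad("is_final_year", f"not a boolean: {record['is_final_year']!r}")
    if record["schema_version"] != SCHEMA_VERSION:
        bad("schema_version", f"expected {SCHEMA_VERSION!r}, got {record['schema_version']!r}")

    if issues:
        return None, issues
    obs = StudyObservation(
        study_id=record["study_id"],
        obs_id=record["obs_id"],
        trait=record["trait"],
        taxon_group=record["taxon_group"],
        n_source=record["n_source"],
        n_timing=record["n_timing"],
        companion_type=record["companion_type"],
        system=record["system"],
        condition=record["condition"],
        compartment=record["compartment"],
        strip=record["strip"],
        **kwargs,  # type: ignore[arg-type]
    )
    return obs, []


def load_observations(path: str | Path) -> tuple[list[StudyObservation], list[ValidationIssue]]:
    """Read a study-observation CSV.

    Returns the accepted observations in file order plus a validation
    report of rejected rows.  Raises :class:`DatabaseError` on an
    unreadable file or a header that does not match the documented schema.
    """
    path = Path(path)
    try:
        handle = path.open(newline="", encoding="utf-8")
    except OSError as exc:
        raise DatabaseError(f"cannot read {path}: {exc}") from exc
    with handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or tuple(reader.fieldnames) != COLUMNS:
            raise DatabaseError(
                f"{path}: header does not match schema v{SCHEMA_VERSION} "
                f"(got {reader.fieldnames})"
            )
        observations: list[StudyObservation] = []
        issues: list[ValidationIssue] = []
        seen_ids: dict[str, int] = {}
        for row_num, record in enumerate(reader, start=1):
            obs, row_issues = _parse_row(record, row_num)
            if obs is None:
                issues.extend(row_issues)
                continue
            if obs.obs_id in seen_ids:
                issues.append(ValidationIssue(
                    row_num, "obs_id",
                    f"duplicate obs_id {obs.obs_id!r} (first seen at row {seen_ids[obs.obs_id]})",
                ))
                continue
            seen_ids[obs.obs_id] = row_num
            observations.append(obs)
    if issues:
        logger.warning("%s: rejected %d row(s); %d accepted", path, len(issues), len(observations))
    return observations, issues


def _format_value(value: object) -> str:
    if isinstance(value, float):
        return "" if math.isnan(value) else repr(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def write_observations(db: Sequence[StudyObservation], path: str | Path) -> None:
    """Write observations to CSV in the documented schema (round-trips with load)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COLUMNS)
        for obs in db:
            row = [_format_value(getattr(obs, name)) for name in COLUMNS[:-1]]
            row.append(SCHEMA_VERSION)
            writer.writerow(row)


def write_validation_report(issues: Iterable[ValidationIssue], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["row", "field", "reason"])
        for issue in issues:
            writer.writerow([issue.row, issue.field, issue.reason])


def filter_rdt(db: Sequence[StudyObservation]) -> list[StudyObservation]:
    """Drop observations whose measured relative density total is below 1.

    Replacement designs have RDT = 1 and additive designs RDT > 1; an RDT
    below 1 indicates the intercrop was planted thinner than its sole-crop
    reference and such comparisons are excluded.  Rows with unreported RDT
    are retained: the exclusion is by measured value, not by missingness.
    """
    kept = [obs for obs in db if math.isnan(obs.rdt) or obs.rdt >= 1]
    removed = len(db) - len(kept)
    if removed:
        logger.info("filter_rdt: removed %d observation(s) with RDT < 1", removed)
    return kept


def select_final_year(db: Sequence[StudyObservation]) -> list[StudyObservation]:
    """Keep only each study's final-year rows to limit temporal pseudo-replication.

    Studies with no flagged row are kept whole, with a warning.
    """
    flagged_studies = {obs.study_id for obs in db if obs.is_final_year}
    unflagged = {obs.study_id for obs in db} - flagged_studies
    if unflagged:
        logger.warning(
            "select_final_year: %d study(ies) have no final-year flag; keeping all their rows: %s",
            len(unflagged), ", ".join(sorted(unflagged)),
        )
    return [obs for obs in db if obs.is_final_year or obs.study_id in unflagged]
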