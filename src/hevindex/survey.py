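"""Facility survey tables: reading, validation and result writing.

The survey dialect is a UTF-8 comma-separated table with one header row and
one row per health-care facility.  Metadata columns come first
(``facility_id, name, type, cup_role, zone`` and optionally ``network``);
every remaining column is matched against the catalog's sub-indicator ids.
Empty cells are *missing* responses — semantically different from zero,
which means "no deficit".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import IndicatorCatalog
from .scoring import ImpactResult, round_display

FACILITY_TYPES = ("tertiary", "primary", "SHPH", "specialized")
CUP_ROLES = ("host", "unit", "external")
METADATA_COLUMNS = ("facility_id", "name", "type", "cup_role", "zone", "network")


class SurveyError(ValueError):
    """A survey file violates the documented dialect or a record invariant."""


@dataclass(frozen=True)
class FacilityRecord:
    """One facility's metadata plus raw sub-indicator responses.

    ``responses`` maps sub-indicator id to a raw numeric value (booleans
    coded 0/1); ``None`` marks a missing response.
    """

    facility_id: str
    name: str
    type: str
    cup_role: str
    zone: int
    responses: Mapping[str, float | None] = field(default_factory=dict)
    network: str = ""

    def __post_init__(self):
        if self.type not in FACILITY_TYPES:
            raise SurveyError(
                f"facility {self.facility_id}: unknown type {self.type!r} "
                f"(expected one of {FACILITY_TYPES})"
            )
        if self.cup_role not in CUP_ROLES:
            raise SurveyError(
                f"facility {self.facility_id}: unknown cup_role {self.cup_role!r}"
            )
        if not (1 <= int(self.zone) <= 4):
            raise SurveyError(
                f"facility {self.facility_id}: zone must be 1-4, got {self.zone}"
            )
        for key, value in self.responses.items():
            if value is None:
                continue
            if not math.isfinite(value) or value < 0:
                raise SurveyError(
                    f"facility {self.facility_id}: response {key}={value!r} "
                    "must be finite and >= 0"
                )


@dataclass(frozen=True)
class SurveyDataset:
    """A validated collection of facility records tied to a catalog."""

    records: tuple[FacilityRecord, ...]
    catalog: IndicatorCatalog
    provenance: str = ""
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [r.facility_id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise SurveyError(f"duplicate facility_id(s): {dupes}")
        hosts: dict[str, list[str]] = {}
        for r in self.records:
            if r.cup_role == "host":
                hosts.setdefault(r.network, []).append(r.facility_id)
        for net, members in hosts.items():
            if len(members) > 1:
                raise SurveyError(
                    f"network {net!r} has more than one host: {members}"
                )
        known = set(self.catalog.sub_indicator_ids())
        for r in self.records:
            unknown = sorted(set(r.responses) - known)
            if unknown:
                raise SurveyError(
                    f"facility {r.facility_id}: responses for unknown "
                    f"sub-indicator(s) {unknown}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def record(self, facility_id: str) -> FacilityRecord:
        for r in self.records:
            if r.facility_id == facility_id:
                return r
        raise KeyError(f"unknown facility {facility_id!r}")

    def with_records(self, records: Iterable[FacilityRecord]) -> "SurveyDataset":
        return replace(self, records=tuple(records))


def read_survey(path: str | Path, catalog: IndicatorCatalog) -> SurveyDataset:
    """Read and validate a facility survey table.

    Unknown columns are kept as warnings on the dataset; catalog
    sub-indicators absent from the header become missing responses and are
    handled by the missing-data rule at scoring time.  Duplicate facility
    ids and non-numeric or negative response cells are hard errors that
    name the offending row and column.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SurveyError(f"{path}: no records (file is empty)") from None
    if frame.empty:
        raise SurveyError(f"{path}: no records")
    frame.columns = [c.strip() for c in frame.columns]
    required = [c for c in METADATA_COLUMNS if c != "network"]
    missing_meta = [c for c in required if c not in frame.columns]
    if missing_meta:
        raise SurveyError(f"{path}: missing metadata column(s) {missing_meta}")

    known_subs = set(catalog.sub_indicator_ids())
    response_cols = [c for c in frame.columns if c in known_subs]
    unknown_cols = [
        c for c in frame.columns if c not in known_subs and c not in METADATA_COLUMNS
    ]
    warnings = tuple(f"ignoring unknown column {c!r}" for c in unknown_cols)

    records = []
    for row_index, row in frame.iterrows():
        responses: dict[str, float | None] = {}
        for col in response_cols:
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or str(cell).strip() == "":
                responses[col] = None
                continue
            try:
                responses[col] = float(cell)
            except ValueError:
                raise SurveyError(
                    f"{path}: row {row_index + 2}, column {col!r}: "
                    f"non-numeric response {cell!r}"
                ) from None
        try:
            zone = int(float(row["zone"]))
        except (TypeError, ValueError):
            raise SurveyError(
                f"{path}: row {row_index + 2}, column 'zone': "
                f"non-numeric value {row['zone']!r}"
            ) from None
        network = ""
        if "network" in frame.columns and isinstance(row.get("network"), str):
            network = row["network"].strip()
        records.append(
            FacilityRecord(
                facility_id=str(row["facility_id"]).strip(),
                name=str(row["name"]).strip(),
                type=str(row["type"]).strip(),
                cup_role=str(row["cup_role"]).strip(),
                zone=zone,
                responses=responses,
                network=network,
            )
        )
    return SurveyDataset(
        records=tuple(records),
        catalog=catalog,
        provenance=f"read from {path}",
        warnings=warnings,
    )


def write_results(
    results: Sequence[ImpactResult], path: str | Path, ndigits: int = 6
) -> None:
    """Write impact results as a CSV table plus a JSON report.

    The CSV is one row per assessed entity with pillar scores, impact and
    class; the JSON sibling (same stem, ``.json``) stores the identical
    values so a round-trip read reproduces them bit-exactly at the stored
    precision.
    """
    if not results:
        raise SurveyError("results collection is empty")
    path = Path(path)
    rows = []
    for r in results:
        d = r.as_dict()
        for k in ("H", "E", "V", "impact"):
            d[k] = round_display(d[k], ndigits)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump({"results": rows}, fh, indent=2)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(path)
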