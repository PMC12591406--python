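"""Reading, validation and standardization of photo-identification encounter records.

An *encounter* is one dated, georeferenced sighting of a group of
photo-identified individuals.  Downstream association analysis assumes one
sampling unit per (date, group): multiple reports of the same group on the
same day are consolidated to a single "daily encounter" keeping the earliest
reported location, and individuals seen fewer than a minimum number of times
are masked from association counting.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Individual",
    "EncounterRecord",
    "DailyEncounterSet",
    "RejectionReport",
    "SchemaError",
    "EmptyInputError",
    "EmptyNetworkError",
    "read_encounters",
    "consolidate_daily",
    "filter_for_network",
    "write_encounters",
]


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyInputError(ValueError):
    """The input table contains no rows."""


class EmptyNetworkError(ValueError):
    """Filtering removed every individual."""


@dataclass(frozen=True)
class Individual:
    """A cataloged whale: alphanumeric id, maternal group, optional sex class.

    Every individual belongs to exactly one matriline; a single adult male
    forms his own matriline.
    """

    id: str
    matriline_id: str
    sex_class: str = "unknown"  # {female, male, unknown}


@dataclass(frozen=True)
class EncounterRecord:
    """One fully parsed sighting of a group of identified whales.

    ``individuals`` is the set of alphanumeric identifiers (e.g. ``T011A``,
    ``OCT090``) photographed during the encounter.  ``all_identified`` is
    true when the reported group size matches the number of identified
    individuals — only those records enter association counting.
    ``predations`` holds observed kills as (prey_species, count) pairs.
    """

    encounter_id: str
    date: _dt.date
    time: _dt.time
    lon: float
    lat: float
    individuals: frozenset[str]
    reported_group_size: int
    all_identified: bool
    source: str = "opportunistic"
    predations: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if len(self.individuals) < 1:
            raise ValueError(f"{self.encounter_id}: empty individual set")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"{self.encounter_id}: latitude {self.lat} out of range")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"{self.encounter_id}: longitude {self.lon} out of range")
        if self.all_identified and self.reported_group_size != len(self.individuals):
            raise ValueError(
                f"{self.encounter_id}: all_identified but group size "
                f"{self.reported_group_size} != {len(self.individuals)} ids"
            )


@dataclass
class RejectionReport:
    """Rows that failed validation, with the reason; never silently dropped."""

    rows: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row_index: int, reason: str) -> None:
        self.rows.append((row_index, reason))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DailyEncounterSet:
    """Consolidated daily encounters plus the provenance of dropped duplicates.

    ``provenance`` maps each retained encounter_id to the list of encounter
    ids that were absorbed into it (same-day duplicate or subset reports).
    """

    records: list[EncounterRecord]
    provenance: dict[str, list[str]]

    @property
    def n_dropped(self) -> int:
        return sum(len(v) for v in self.provenance.values())


DEFAULT_SCHEMA = {
    "encounter_id": "encounter_id",
    "date": "date",
    "time": "time",
    "lat": "lat",
    "lon": "lon",
    "ids": "ids",
    "group_size": "group_size",
    "source": "source",
    "predations": "predations",
}

_REQUIRED = ("date", "lat", "lon", "ids", "group_size")


def _parse_predations(cell: object) -> tuple[tuple[str, int], ...]:
    # serialized as "species:count;species:count"
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return ()
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        species, _, cnt = part.partition(":")
        out.append((species.strip(), int(cnt) if cnt else 1))
    return tuple(out)


def read_encounters(
    path: str | Path,
    schema: dict[str, str] | None = None,
    *,
    id_delimiter: str = ";",
    date_format: str | None = None,
) -> tuple[list[EncounterRecord], RejectionReport]:
    """Read an encounter table (CSV or XLSX) into validated records.

    ``schema`` maps the canonical field names (see ``DEFAULT_SCHEMA``) to the
    column names used in the file.  Rows with unparseable dates or
    out-of-range coordinates are collected in the returned
    :class:`RejectionReport` rather than silently dropped.

    Raises
    ------
    SchemaError
        if a required column is absent.
    EmptyInputError
        if the table has no rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    for field_name in _REQUIRED:
        if colmap[field_name] not in df.columns:
            raise SchemaError(f"missing required column {colmap[field_name]!r} (field {field_name!r})")

    have_time = colmap["time"] in df.columns
    have_eid = colmap["encounter_id"] in df.columns
    have_source = colmap["source"] in df.columns
    have_pred = colmap["predations"] in df.columns

    records: list[EncounterRecord] = []
    rejected = RejectionReport()
    for i, row in df.iterrows():
        try:
            raw_date = str(row[colmap["date"]]).strip()
            if date_format:
                date = _dt.datetime.strptime(raw_date, date_format).date()
            else:
                date = _dt.date.fromisoformat(raw_date[:10])
            if have_time and not pd.isna(row[colmap["time"]]):
                t = str(row[colmap["time"]]).strip()
                time = _dt.time.fromisoformat(t if len(t) > 5 else t + ":00")
            else:
                time = _dt.time(0, 0)
            lat = float(row[colmap["lat"]])
            lon = float(row[colmap["lon"]])
            ids = frozenset(
                s.strip() for s in str(row[colmap["ids"]]).split(id_delimiter) if s.strip()
            )
            gs = int(float(row[colmap["group_size"]]))
            eid = str(row[colmap["encounter_id"]]) if have_eid else f"row{i}"
            source = str(row[colmap["source"]]) if have_source and not pd.isna(row[colmap["source"]]) else "opportunistic"
            pred = _parse_predations(row[colmap["predations"]]) if have_pred else ()
            records.append(
                EncounterRecord(
                    encounter_id=eid,
                    date=date,
                    time=time,
                    lon=lon,
                    lat=lat,
                    individuals=ids,
                    reported_group_size=gs,
                    all_identified=(gs == len(ids)),
                    source=source,
                    predations=pred,
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            rejected.add(int(i), str(exc))
    return records, rejected


def consolidate_daily(records: list[EncounterRecord]) -> DailyEncounterSet:
    """Collapse same-day reports of the same (or a partial) group.

    Within each calendar date records are processed in ascending time order
    (ties keep input order).  A record whose individual set is equal to — or
    a subset of — an already-retained record's set that day is dropped and
    logged in provenance; the retained record keeps its earliest location
    (the first initial sighting).  Same-day groups that genuinely differ
    (neither a subset of the other) are both retained.

    Idempotent: consolidating an already-consolidated set is a no-op.
    """
    by_date: dict[_dt.date, list[tuple[int, EncounterRecord]]] = {}
    for idx, rec in enumerate(records):
        by_date.setdefault(rec.date, []).append((idx, rec))

    retained: list[tuple[int, EncounterRecord]] = []
    provenance: dict[str, list[str]] = {}
    for date in sorted(by_date):
        day = sorted(by_date[date], key=lambda t: (t[1].time, t[0]))
        kept_today: list[EncounterRecord] = []
        for idx, rec in day:
            absorbed_by = next(
                (k for k in kept_today if rec.individuals <= k.individuals), None
            )
            if absorbed_by is not None:
                provenance.setdefault(absorbed_by.encounter_id, []).append(rec.encounter_id)
            else:
                kept_today.append(rec)
                retained.append((idx, rec))
                provenance.setdefault(rec.encounter_id, [])
    retained.sort(key=lambda t: t[0])  # stable: original input order
    return DailyEncounterSet(records=[r for _, r in retained], provenance=provenance)


def filter_for_network(
    records: list[EncounterRecord],
    min_sightings: int = 3,
) -> tuple[list[EncounterRecord], set[str], set[str]]:
    """Apply the complete-group and minimum-resighting filters.

    Records with ``all_identified`` false are excluded entirely.  Individual
    sighting counts are computed once on the remaining records (a single
    pass — no iterative re-thresholding); individuals seen fewer than
    ``min_sightings`` times are returned as ``excluded_ids`` and must be
    masked from association counting, but the encounters they appear in are
    kept for the retained individuals.

    Returns ``(records, retained_ids, excluded_ids)``.
    """
    usable = [r for r in records if r.all_identified]
    counts: dict[str, int] = {}
    for rec in usable:
        for ind in rec.individuals:
            counts[ind] = counts.get(ind, 0) + 1
    retained = {i for i, c in counts.items() if c >= min_sightings}
    excluded = set(counts) - retained
    if not retained:
        raise EmptyNetworkError(
            f"no individual reaches {min_sightings} sightings in {len(usable)} usable records"
        )
    kept_records = [r for r in usable if r.individuals & retained]
    return kept_records, retained, excluded


def write_encounters(records: list[EncounterRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (round-trips through
    :func:`read_encounters`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "encounter_id": r.encounter_id,
                "date": r.date.isoformat(),
                "time": r.time.strftime("%H:%M"),
                "lat": r.lat,
                "lon": r.lon,
                "ids": ";".join(sorted(r.individuals)),
                "group_size": r.reported_group_size,
                "source": r.source,
                "predations": ";".join(f"{s}:{c}" for s, c in r.predations),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
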