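"""Occurrence ingestion, automated QC flags, spatial dedup and auditable edits.

Records enter as Darwin-Core-style CSV rows, get a permanent unique
identifier, keep their provenance verbatim, and acquire two kinds of flags:

* *automated* flags, recomputed idempotently by a configurable rule engine
  (missing/zero coordinates, outside the reference region, likely lat/lon
  transposition, elevation–DEM mismatch, exact provenance duplicates,
  future dates);
* *manual* flags set by expert curators (suspect identification,
  georeferencing error, other).

Visibility is a pure function of state: a record is visible iff none of
its flags is in the active blocking set *and* it is the most-documented
record in its ~1-km grid cell.  Every expert edit is appended to an
append-only audit log; reverts append compensating entries, so the full
history is always reconstructible.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import warnings
from dataclasses import dataclass, field, fields as _dc_fields, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

from .geo_core import LocalProjection, Raster

__all__ = [
    "OccurrenceRecord",
    "AuditEntry",
    "FlagRule",
    "DOC_FIELDS",
    "EDITABLE_FIELDS",
    "DEFAULT_BLOCKING",
    "MANUAL_FLAGS",
    "default_rules",
    "standardize",
    "run_auto_checks",
    "apply_visibility_filter",
    "dedupe_spatial",
    "edit_record",
    "revert_record",
    "read_occurrences",
    "write_occurrences",
    "read_audit_log",
    "write_audit_log",
    "DEFAULT_FIELD_MAP",
]

# Fields counted toward the documentation score ("most documented record").
DOC_FIELDS = (
    "event_date",
    "elevation_m",
    "locality",
    "institution",
    "collection_code",
    "catalog_number",
    "recorded_by",
    "source_occurrence_id",
)

# Fields an expert curator may change; uid and provenance are immutable.
EDITABLE_FIELDS = ("lat", "lon", "taxon", "manual_flags")

MANUAL_FLAGS = ("SUSPECT_ID", "GEOREF_ERROR", "OTHER")

DEFAULT_BLOCKING = frozenset(
    {
        "MISSING_COORDS",
        "ZERO_COORDS",
        "OUT_OF_REGION",
        "DUPLICATE_EXACT",
        "SPATIAL_DUPLICATE",
        "SUSPECT_ID",
        "GEOREF_ERROR",
    }
)

DEFAULT_FIELD_MAP = {
    "scientificName": "taxon",
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "occurrenceID": "source_occurrence_id",
    "institutionCode": "institution",
    "collectionCode": "collection_code",
    "catalogNumber": "catalog_number",
    "eventDate": "event_date",
    "locality": "locality",
    "elevation": "elevation_m",
    "recordedBy": "recorded_by",
}


@dataclass
class OccurrenceRecord:
    uid: str
    taxon: str
    lat: float
    lon: float
    source_occurrence_id: str | None = None
    institution: str | None = None
    collection_code: str | None = None
    catalog_number: str | None = None
    recorded_by: str | None = None
    event_date: str | None = None
    locality: str | None = None
    elevation_m: float | None = None
    auto_flags: set = field(default_factory=set)
    manual_flags: set = field(default_factory=set)
    visible: bool = True

    @property
    def doc_score(self) -> int:
        """Number of populated documentation fields; deterministic."""
        return sum(1 for f in DOC_FIELDS if _populated(getattr(self, f)))

    @property
    def flags(self) -> set:
        return set(self.auto_flags) | set(self.manual_flags)

    def has_coords(self) -> bool:
        return _is_num(self.lat) and _is_num(self.lon)

    def state(self) -> dict:
        """Full field-by-field snapshot (flags sorted, NaN coords as None)."""
        out = {}
        for f in _dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, set):
                v = sorted(v)
            elif isinstance(v, float) and math.isnan(v):
                v = None
            out[f.name] = v
        out["doc_score"] = self.doc_score
        return out


@dataclass(frozen=True)
class AuditEntry:
    entry_id: int
    uid: str
    field: str
    old_value: object
    new_value: object
    actor: str
    timestamp: str


@dataclass(frozen=True)
class FlagRule:
    """One QC rule: ``predicate(record, reference) -> bool`` marks the flag.

    Automated rules must be pure functions of the record and the reference
    layers.  ``requires`` lists the reference keys the rule needs; rules
    whose requirements are missing are skipped with a warning.
    """

    code: str
    kind: str  # "automated" | "manual"
    predicate: Callable | None = None
    blocking: bool = True
    requires: tuple = ()


def _populated(v) -> bool:
    if v is None:
        return False
    if isinstance(v, float) and math.isnan(v):
        return False
    if isinstance(v, str) and v.strip() == "":
        return False
    return True


def _is_num(v) -> bool:
    return v is not None and isinstance(v, (int, float)) and not math.isnan(float(v))


def _in_region(lat, lon, region) -> bool:
    return bool(shapely.contains_xy(region, lon, lat))


def _rule_missing(rec, ref):
    return not rec.has_coords()


def _rule_zero(rec, ref):
    return rec.has_coords() and rec.lat == 0.0 and rec.lon == 0.0


def _rule_out_of_region(rec, ref):
    return rec.has_coords() and not _in_region(rec.lat, rec.lon, ref["region"])


def _rule_coord_swap(rec, ref):
    if not rec.has_coords():
        return False
    region = ref["region"]
    return (not _in_region(rec.lat, rec.lon, region)) and _in_region(
        rec.lon, rec.lat, region
    )


def _rule_elev(rec, ref):
    if not rec.has_coords() or not _is_num(rec.elevation_m):
        return False
    dem: Raster = ref["dem"]
    tol = ref.get("elev_tolerance_m", 500.0)
    val = dem.sample(rec.lon, rec.lat)[0]
    if math.isnan(val):
        return False
    return abs(float(rec.elevation_m) - val) > tol


def _rule_future(rec, ref):
    if not _populated(rec.event_date):
        return False
    try:
        d = _dt.date.fromisoformat(str(rec.event_date)[:10])
    except ValueError:
        return False
    return d > ref.get("today", _dt.date.today())


def default_rules() -> list[FlagRule]:
    return [
        FlagRule("MISSING_COORDS", "automated", _rule_missing),
        FlagRule("ZERO_COORDS", "automated", _rule_zero),
        FlagRule("OUT_OF_REGION", "automated", _rule_out_of_region,
                 requires=("region",)),
        FlagRule("COORD_SWAP", "automated", _rule_coord_swap,
                 blocking=False, requires=("region",)),
        FlagRule("ELEV_MISMATCH", "automated", _rule_elev,
                 blocking=False, requires=("dem",)),
        FlagRule("DUPLICATE_EXACT", "automated", None),  # cross-record, see below
        FlagRule("FUTURE_DATE", "automated", _rule_future, blocking=False),
        FlagRule("SUSPECT_ID", "manual"),
        FlagRule("GEOREF_ERROR", "manual"),
        FlagRule("OTHER", "manual", blocking=False),
    ]


# ---------------------------------------------------------------------------
# standardize + I/O
# ---------------------------------------------------------------------------


def standardize(raw_table: pd.DataFrame,
                field_map: Mapping[str, str] | None = None,
                *, uid_prefix: str = "occ") -> list[OccurrenceRecord]:
    """Turn a raw occurrence table into records with fresh permanent uids.

    ``field_map`` maps raw column names to record fields; unmapped columns
    are ignored.  Taxon and coordinate columns are mandatory.  Rows whose
    coordinates do not parse as numbers are kept (coords set to NaN) and
    flagged MISSING_COORDS rather than rejected.
    """
    field_map = dict(field_map or DEFAULT_FIELD_MAP)
    inverse = {v: k for k, v in field_map.items()}
    for needed in ("taxon", "lat", "lon"):
        if needed not in inverse or inverse[needed] not in raw_table.columns:
            raise KeyError(
                f"field map does not provide a column for {needed!r}")
    records: list[OccurrenceRecord] = []
    ndigits = max(6, len(str(len(raw_table))))
    for i, (_, row) in enumerate(raw_table.iterrows()):
        kwargs: dict = {}
        for raw_col, fld in field_map.items():
            if raw_col not in raw_table.columns:
                continue
            v = row[raw_col]
            if pd.isna(v):
                v = None
            kwargs[fld] = v
        flags: set = set()
        for coord in ("lat", "lon"):
            try:
                kwargs[coord] = float(kwargs[coord])
            except (TypeError, ValueError):
                kwargs[coord] = float("nan")
                flags.add("MISSING_COORDS")
        if kwargs.get("elevation_m") is not None:
            try:
                kwargs["elevation_m"] = float(kwargs["elevation_m"])
            except (TypeError, ValueError):
                kwargs["elevation_m"] = None
        for fld in ("taxon", "source_occurrence_id", "institution",
                    "collection_code", "catalog_number", "recorded_by",
                    "event_date", "locality"):
            if kwargs.get(fld) is not None:
                kwargs[fld] = str(kwargs[fld])
        rec = OccurrenceRecord(uid=f"{uid_prefix}-{i:0{ndigits}d}",
                               auto_flags=flags, **kwargs)
        records.append(rec)
    return records


_CSV_COLUMNS = {
    "uid": "uid",
    "scientificName": "taxon",
    "decimalLatitude": "lat",
    "decimalLongitude": "lon",
    "occurrenceID": "source_occurrence_id",
    "institutionCode": "institution",
    "collectionCode": "collection_code",
    "catalogNumber": "catalog_number",
    "recordedBy": "recorded_by",
    "eventDate": "event_date",
    "locality": "locality",
    "elevation": "elevation_m",
    "autoFlags": "auto_flags",
    "manualFlags": "manual_flags",
    "visible": "visible",
}


def write_occurrences(path, records: Sequence[OccurrenceRecord]) -> None:
    """Write curated records as Darwin-Core-style UTF-8 CSV (round-trip safe)."""
    rows = []
    for r in records:
        row = {}
        for col, fld in _CSV_COLUMNS.items():
            v = getattr(r, fld)
            if fld in ("auto_flags", "manual_flags"):
                v = "|".join(sorted(v))
            elif fld == "visible":
                v = str(bool(v))
            elif fld in ("lat", "lon", "elevation_m"):
                v = "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
            elif v is None:
                v = ""
            row[col] = v
        rows.append(row)
    pd.DataFrame(rows, columns=list(_CSV_COLUMNS)).to_csv(
        path, index=False, encoding="utf-8")


def read_occurrences(path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for col, fld in _CSV_COLUMNS.items():
            v = row.get(col, "")
            if fld in ("auto_flags", "manual_flags"):
                kwargs[fld] = set(v.split("|")) - {""}
            elif fld == "visible":
                kwargs[fld] = v == "True"
            elif fld in ("lat", "lon", "elevation_m"):
                if v == "":
                    kwargs[fld] = float("nan") if fld != "elevation_m" else None
                else:
                    kwargs[fld] = float(v)
            else:
                kwargs[fld] = v if v != "" else None
        records.append(OccurrenceRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# automated checks, visibility, dedup
# ---------------------------------------------------------------------------


def run_auto_checks(records: Sequence[OccurrenceRecord],
                    reference: Mapping | None = None,
                    rules: Sequence[FlagRule] | None = None,
                    ) -> list[OccurrenceRecord]:
    """Populate each record's automated flags; idempotent.

    ``reference`` may supply ``region`` (shapely polygon), ``dem``
    (:class:`~sdmflow.geo_core.Raster`), ``elev_tolerance_m`` and ``today``.
    Rules whose reference layers are missing are skipped with a warning.
    The engine owns exactly the codes of the automated rules passed in:
    re-running replaces those and leaves everything else (manual flags,
    SPATIAL_DUPLICATE) alone.
    """
    reference = dict(reference or {})
    rules = list(rules) if rules is not None else default_rules()
    auto_rules = [r for r in rules if r.kind == "automated"]
    owned = {r.code for r in auto_rules}
    active: list[FlagRule] = []
    for rule in auto_rules:
        missing = [k for k in rule.requires if k not in reference]
        if missing:
            warnings.warn(
                f"skipping rule {rule.code}: missing reference {missing}",
                stacklevel=2)
            continue
        active.append(rule)

    # cross-record exact-duplicate detection on the provenance tuple
    dup_uids: set[str] = set()
    if any(r.code == "DUPLICATE_EXACT" for r in active):
        seen: dict[tuple, str] = {}
        for rec in sorted(records, key=lambda r: r.uid):
            key = (rec.source_occurrence_id, rec.institution,
                   rec.collection_code, rec.catalog_number)
            if all(not _populated(k) for k in key):
                continue
            if key in seen:
                dup_uids.add(rec.uid)
            else:
                seen[key] = rec.uid

    for rec in records:
        new = set()
        for rule in active:
            if rule.code == "DUPLICATE_EXACT":
                if rec.uid in dup_uids:
                    new.add(rule.code)
            elif rule.predicate is not None and rule.predicate(rec, reference):
                new.add(rule.code)
        rec.auto_flags = (set(rec.auto_flags) - owned) | new
    return list(records)


def apply_visibility_filter(records: Sequence[OccurrenceRecord],
                            blocking: Iterable[str] = DEFAULT_BLOCKING,
                            rules: Sequence[FlagRule] | None = None,
                            ) -> list[OccurrenceRecord]:
    """Set pre-dedup visibility: visible iff no flag is in the blocking set.

    The blocking set is per-dataset configuration; unknown codes are a
    configuration error.
    """
    blocking = set(blocking)
    known = {r.code for r in (rules if rules is not None else default_rules())}
    known.add("SPATIAL_DUPLICATE")
    unknown = blocking - known
    if unknown:
        raise ValueError(f"unknown flag codes in blocking set: {sorted(unknown)}")
    for rec in records:
        rec.visible = not (rec.flags & blocking)
    return list(records)


def dedupe_spatial(records: Sequence[OccurrenceRecord],
                   cell_km: float = 1.0) -> list[OccurrenceRecord]:
    """Keep one visible record per ~1-km cell: the most documented one.

    Cells are a half-open km lattice in the local metric projection,
    anchored at the data bounding-box origin.  Ties on documentation score
    break to the earliest uid.  Records without valid coordinates are
    untouched; previous SPATIAL_DUPLICATE marks are recomputed.
    """
    coords = [(r.lon, r.lat) for r in records if r.has_coords()]
    for rec in records:
        rec.auto_flags.discard("SPATIAL_DUPLICATE")
    if not coords:
        return list(records)
    lon, lat = np.array(coords).T
    proj = LocalProjection.for_points(lon, lat)
    x, y = proj.forward(lon, lat)
    x0, y0 = x.min(), y.min()
    eligible = [r for r in records if r.has_coords() and r.visible]
    cells: dict[tuple[int, int], list[OccurrenceRecord]] = {}
    for rec in eligible:
        rx, ry = proj.forward(rec.lon, rec.lat)
        key = (int(math.floor((rx - x0) / cell_km)),
               int(math.floor((ry - y0) / cell_km)))
        cells.setdefault(key, []).append(rec)
    for members in cells.values():
        members.sort(key=lambda r: (-r.doc_score, r.uid))
        for loser in members[1:]:
            loser.auto_flags.add("SPATIAL_DUPLICATE")
            loser.visible = False
    return list(records)


def run_qc(records: Sequence[OccurrenceRecord],
           reference: Mapping | None = None,
           blocking: Iterable[str] = DEFAULT_BLOCKING,
           cell_km: float = 1.0,
           rules: Sequence[FlagRule] | None = None) -> list[OccurrenceRecord]:
    """Checks → visibility filter → spatial dedup, in the canonical order."""
    run_auto_checks(records, reference, rules)
    apply_visibility_filter(records, blocking, rules)
    dedupe_spatial(records, cell_km)
    return list(records)


# ---------------------------------------------------------------------------
# auditable edits
# ---------------------------------------------------------------------------


def _audit_value(v):
    return sorted(v) if isinstance(v, set) else v


def _now_iso() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def _find(records: Sequence[OccurrenceRecord], uid: str) -> OccurrenceRecord:
    for rec in records:
        if rec.uid == uid:
            return rec
    raise KeyError(f"no record with uid {uid!r}")


def edit_record(records: Sequence[OccurrenceRecord],
                audit_log: list[AuditEntry],
                uid: str, field_name: str, new_value, actor: str,
                *, timestamp: str | None = None) -> AuditEntry:
    """Apply one expert edit and append a log entry.

    Only coordinates, taxon and manual flags are editable; uid and
    provenance fields are immutable.  ``manual_flags`` takes any iterable
    of codes (stored as a set).
    """
    if field_name not in EDITABLE_FIELDS:
        raise ValueError(
            f"field {field_name!r} is not editable (allowed: {EDITABLE_FIELDS})")
    rec = _find(records, uid)
    old = getattr(rec, field_name)
    if field_name == "manual_flags":
        new_value = set(new_value)
    elif field_name in ("lat", "lon"):
        new_value = float(new_value)
    entry = AuditEntry(
        entry_id=(audit_log[-1].entry_id + 1) if audit_log else 1,
        uid=uid,
        field=field_name,
        old_value=_audit_value(old),
        new_value=_audit_value(new_value),
        actor=actor,
        timestamp=timestamp or _now_iso(),
    )
    setattr(rec, field_name, new_value)
    audit_log.append(entry)
    return entry


def revert_record(records: Sequence[OccurrenceRecord],
                  audit_log: list[AuditEntry],
                  uid: str, to_entry_id: int | None = None,
                  actor: str = "revert") -> OccurrenceRecord:
    """Restore a record to its state before ``to_entry_id``.

    Entries for the record at or after ``to_entry_id`` are replayed newest
    first as compensating edits; the log stays append-only.  With
    ``to_entry_id=None`` every edit of the record is undone.  A record with
    no matching entries is a no-op.
    """
    rec = _find(records, uid)
    mine = [e for e in audit_log if e.uid == uid]
    if to_entry_id is not None:
        if not any(e.entry_id == to_entry_id for e in mine):
            raise KeyError(f"no audit entry {to_entry_id} for record {uid!r}")
        mine = [e for e in mine if e.entry_id >= to_entry_id]
    if not mine:
        return rec
    for entry in sorted(mine, key=lambda e: e.entry_id, reverse=True):
        old = entry.old_value
        if entry.field == "manual_flags":
            old = set(old)
        edit_record(records, audit_log, uid, entry.field, old, actor)
    return rec


def write_audit_log(path, audit_log: Sequence[AuditEntry]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in audit_log:
            fh.write(json.dumps(e.__dict__, default=str) + "\n")


def read_audit_log(path) -> list[AuditEntry]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(AuditEntry(**json.loads(line)))
    return out
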