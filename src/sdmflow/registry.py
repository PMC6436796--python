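"""Model lifecycle registry, expert scoring, range statistics and summaries.

A model moves through a fixed lifecycle::

    under_development --feedback_processed--> pending_validation
    pending_validation --approved--> validated
    (external peer-reviewed submissions enter directly as published_external)

Experts score models on a 1–5 credibility scale (1: no credibility,
5: complete credibility); a model is approved when the arithmetic mean of
its scores reaches 3.  Validated models get fact-sheet range statistics
chosen for IUCN criterion B assessments: model area, extent of occurrence
(EOO, convex-hull area of the presence cells) and area of occupancy
(AOO, occupied 2×2-km cells × 4 km²), plus the elevation range over
presence cells when a DEM is available.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .geo_core import LocalProjection, Raster

__all__ = [
    "ModelRecord",
    "STATUSES",
    "TRANSITIONS",
    "transition",
    "score_and_decide",
    "add_scores",
    "intake_external",
    "distribution_stats",
    "group_summary",
    "read_group_table",
    "save_record",
    "load_record",
    "MANDATORY_EXTERNAL_METADATA",
]

STATUSES = ("under_development", "pending_validation", "validated",
            "published_external")

# event -> (from_status, to_status)
TRANSITIONS = {
    "model_generated": (None, "under_development"),
    "feedback_processed": ("under_development", "pending_validation"),
    "approved": ("pending_validation", "validated"),
    "external_submission_accepted": (None, "published_external"),
    "reopen": ("validated", "under_development"),
}

VALIDATION_MEAN = 3.0
MANDATORY_EXTERNAL_METADATA = ("species", "method", "sources", "methods_doc")


@dataclass
class ModelRecord:
    model_id: str
    species: str
    version: int = 1
    status: str = "under_development"
    scores: list = field(default_factory=list)  # [{"reviewer":..., "score":...}]
    authors: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def mean_score(self) -> float | None:
        if not self.scores:
            return None
        return float(np.mean([s["score"] for s in self.scores]))


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def transition(record: ModelRecord, event: str, *,
               timestamp: str | None = None) -> ModelRecord:
    """Advance a model along the lifecycle; illegal edges raise.

    ``approved`` additionally requires at least one score with mean ≥ 3;
    ``reopen`` starts a new version (re-validation after new data or
    taxonomy changes).
    """
    if event not in TRANSITIONS:
        raise ValueError(f"unknown lifecycle event {event!r}")
    src, dst = TRANSITIONS[event]
    if src is not None and record.status != src:
        raise ValueError(
            f"illegal transition: {event!r} requires status {src!r}, "
            f"record is {record.status!r}")
    if event == "approved":
        mean = record.mean_score()
        if mean is None or mean < VALIDATION_MEAN:
            raise ValueError(
                "cannot validate: requires >=1 expert score with mean >= 3 "
                f"(have {mean})")
    if event == "reopen":
        record.version += 1
        record.scores = []
    record.status = dst
    record.events.append({"event": event, "to": dst,
                          "timestamp": timestamp or _now()})
    return record


def add_scores(record: ModelRecord, scores: Iterable[int],
               reviewer: str = "anonymous") -> ModelRecord:
    for s in scores:
        s = int(s)
        if not 1 <= s <= 5:
            raise ValueError(f"score {s} outside the 1-5 credibility scale")
        record.scores.append({"reviewer": reviewer, "score": s})
    return record


def score_and_decide(record: ModelRecord, new_scores: Iterable[int],
                     reviewer: str = "anonymous", *,
                     min_scores: int = 1) -> str:
    """Register scores and apply the validation rule.

    Approved iff the arithmetic mean of all scores is ≥ 3 and at least
    ``min_scores`` scores exist (quorum configurable; one by default).
    Returns "approved" or "pending"; on approval the record transitions to
    validated.
    """
    add_scores(record, new_scores, reviewer)
    mean = record.mean_score()
    if len(record.scores) >= min_scores and mean is not None and mean >= VALIDATION_MEAN:
        if record.status == "pending_validation":
            transition(record, "approved")
        return "approved"
    return "pending"


def intake_external(model_id: str, metadata: Mapping, *,
                    peer_reviewed: bool,
                    artifacts: Mapping | None = None,
                    occurrences=None) -> ModelRecord:
    """Register a third-party model submission.

    Peer-reviewed submissions are published immediately without further
    review; others wait as pending_validation until the methodology review
    decision.  Mandatory metadata fields missing → rejection listing them.
    """
    missing = [k for k in MANDATORY_EXTERNAL_METADATA if not metadata.get(k)]
    if missing:
        raise ValueError(f"external submission rejected; missing metadata "
                         f"fields: {missing}")
    record = ModelRecord(
        model_id=model_id,
        species=str(metadata["species"]),
        status="pending_validation",
        metadata=dict(metadata, peer_reviewed=bool(peer_reviewed)),
        artifacts=dict(artifacts or {}),
    )
    if occurrences is not None:
        record.metadata["n_occurrences_supplied"] = int(len(occurrences))
    if peer_reviewed:
        transition(record, "external_submission_accepted")
    return record


# ---------------------------------------------------------------------------
# fact-sheet distribution statistics
# ---------------------------------------------------------------------------


def distribution_stats(binary: Raster, dem: Raster | None = None,
                       aoo_cell_km: float = 2.0) -> dict:
    """Range statistics of a binary distribution for conservation assessment.

    * ``area_km2`` — sum of presence-cell areas.
    * ``eoo_km2`` — convex-hull area of presence-cell centres (metric
      projection); with fewer than 3 presence cells the hull is degenerate
      and EOO falls back to the summed cell area.
    * ``aoo_km2`` — number of occupied 2×2-km cells × 4 km² (IUCN).
    * ``elev_min_m`` / ``elev_max_m`` — over presence cells, when a DEM is
      given.
    """
    present = np.asarray(binary.data) > 0
    stats: dict = {"n_cells": int(present.sum())}
    if not present.any():
        warnings.warn("empty distribution; statistics are zero", stacklevel=2)
        return {**stats, "area_km2": 0.0, "eoo_km2": 0.0, "aoo_km2": 0.0}
    grid = binary.grid
    stats["area_km2"] = float(grid.cell_area_km2()[present].sum())
    rows, cols = np.nonzero(present)
    lon, lat = grid.cell_center(rows, cols)
    proj = LocalProjection.for_grid(grid)
    x, y = proj.forward(lon, lat)
    if stats["n_cells"] >= 3:
        hull = MultiPoint(np.column_stack([x, y]).tolist()).convex_hull
        eoo = float(hull.area) if hull.geom_type == "Polygon" else 0.0
        stats["eoo_km2"] = max(eoo, stats["area_km2"]) if eoo == 0.0 else eoo
    else:
        stats["eoo_km2"] = stats["area_km2"]
    cellx = np.floor((x - x.min()) / aoo_cell_km)
    celly = np.floor((y - y.min()) / aoo_cell_km)
    occupied = len(set(zip(cellx.tolist(), celly.tolist())))
    stats["aoo_km2"] = float(occupied * aoo_cell_km ** 2)
    if dem is not None:
        if dem.grid != grid:
            raise ValueError("DEM not on the template grid")
        ev = np.asarray(dem.data, dtype=float)[present]
        ev = ev[~np.isnan(ev)]
        if ev.size:
            stats["elev_min_m"] = float(ev.min())
            stats["elev_max_m"] = float(ev.max())
    return stats


# ---------------------------------------------------------------------------
# group progress summaries
# ---------------------------------------------------------------------------

GROUP_COLUMNS = ("n_experts", "n_species", "n_under_development",
                 "n_pending", "n_validated")


def read_group_table(path) -> pd.DataFrame:
    """Read a group progress CSV (group name + count columns; blanks = 0)."""
    df = pd.read_csv(path)
    for col in GROUP_COLUMNS:
        if col not in df.columns:
            df[col] = 0
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    return df


def group_summary(table: pd.DataFrame) -> pd.Series:
    """Column-wise totals of a group progress table (blanks count as 0)."""
    totals = {}
    for col in GROUP_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce").fillna(0)
            if (vals < 0).any():
                raise ValueError(f"negative count in column {col!r}")
            totals[col] = int(vals.sum())
        else:
            totals[col] = 0
    return pd.Series(totals, name="TOTAL")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_record(path, record: ModelRecord) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(record), fh, indent=2, sort_keys=True, default=str)


def load_record(path) -> ModelRecord:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return ModelRecord(**doc)
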