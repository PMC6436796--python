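"""Reproducible whole-pipeline experiments on synthetic data.

Two canned protocols used for validation and benchmarking:

* :func:`recovery_trial` — can the presence–background model recover a
  virtual species' niche?  One trial builds a 100×100 landscape with two
  informative variables and one distractor, samples 100 presences from the
  true suitability, fits on three spatial blocks with 10,000 background
  points, and reports the held-out-block AUC and whether the informative
  variables carry the most coefficient mass.

* :func:`end_to_end_scenario` — the full collaborative workflow on one
  synthetic species: corrupted occurrence table → QC (flags, visibility,
  1-km dedup) → thinning → modeling ladder → tuning → thresholding →
  expert feedback → registry validation, optionally writing every artifact
  (GeoTIFFs, CSV, JSONs) to a directory.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import shapely

from . import occurrence_qc as qc
from .geo_core import AccessibleArea, Raster, write_geotiff
from .postprocess import ExpertFeedback, apply_feedback
from .registry import ModelRecord, distribution_stats, score_and_decide, transition
from .sdm_engine import (
    BackgroundConfig,
    ThinConfig,
    TuneGrid,
    evaluate,
    fit_maxent_like,
    run_pipeline,
    sample_background,
    spatial_partition,
)
from .synthetic_data import make_landscape, make_species, sample_occurrences

__all__ = ["recovery_trial", "end_to_end_scenario"]

_NICHE = {"env1": (1.0, 0.5), "env2": (-1.0, 0.5)}


def recovery_trial(seed: int, *, size: int = 100, n_presence: int = 100,
                   n_background: int = 10_000) -> dict:
    """One niche-recovery trial; deterministic per seed."""
    stack = make_landscape(seed=seed, size=size, n_vars=3).subset(
        ["env1", "env2", "env3"])
    species = make_species(stack, _NICHE)
    rng = np.random.default_rng(seed + 1)
    w = np.where(np.isnan(species.true_suitability.data), 0.0,
                 species.true_suitability.data).ravel()
    idx = rng.choice(w.size, size=n_presence, p=w / w.sum())
    rows, cols = np.divmod(idx, stack.grid.width)
    lon, lat = stack.grid.cell_center(rows, cols)
    M = AccessibleArea(shapely.box(*stack.grid.bounds))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lon_b, lat_b = sample_background(
            BackgroundConfig(n_background=n_background, seed=seed + 2),
            M, stack)
    Xp = stack.sample(lon, lat)
    Xb = stack.sample(lon_b, lat_b)
    labels = spatial_partition(lon, lat, 4)
    train, test = labels != 0, labels == 0
    model = fit_maxent_like(Xp[train], Xb, stack.names,
                            features=("linear", "quadratic", "hinge"),
                            reg_multiplier=1.0, seed=seed)
    auc = evaluate(model.score(Xp[test]), model.score(Xb))["auc"]
    imp = model.variable_importance()
    top2 = set(sorted(imp, key=imp.get, reverse=True)[:2])
    return {
        "holdout_auc": float(auc),
        "informative_on_top": top2 == set(_NICHE),
        "importance": {k: float(v) for k, v in imp.items()},
    }


def end_to_end_scenario(seed: int, outdir: str | Path | None = None, *,
                        size: int = 100, n_records: int = 150,
                        slider_percent: float = 10.0) -> dict:
    """Run the whole collaborative workflow on one synthetic species.

    Returns a summary with the chosen method, cross-validation results,
    training omission at the reviewer's slider setting, nesting checks and
    fact-sheet statistics; writes all artifacts when ``outdir`` is given.
    """
    landscape = make_landscape(seed=seed, size=size, n_vars=3)
    stack = landscape.subset(["env1", "env2", "env3"])
    dem = landscape.raster("dem")
    landcover = Raster(landscape.grid, landscape["landcover"])
    species = make_species(stack, _NICHE)
    table, truth = sample_occurrences(
        species, n_records,
        error_rates={"zero_coords": 0.05, "transposed": 0.05,
                     "duplicate": 0.05, "off_range_misID": 0.02},
        seed=seed + 1, dem=dem)

    # --- curation -------------------------------------------------------
    records = qc.standardize(table)
    region = shapely.box(*landscape.grid.bounds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc.run_qc(records, {"region": region, "dem": dem},
                  qc.DEFAULT_BLOCKING, cell_km=1.0)
    audit: list = []
    # an expert fixes one taxon name and flags one suspect record
    visible_uids = [r.uid for r in records if r.visible]
    qc.edit_record(records, audit, visible_uids[0], "taxon",
                   "Virtualis exempli", actor="expert-1")
    qc.edit_record(records, audit, visible_uids[-1], "manual_flags",
                   {"SUSPECT_ID"}, actor="expert-1")
    qc.apply_visibility_filter(records, qc.DEFAULT_BLOCKING)
    xy = np.array([(r.lon, r.lat) for r in records
                   if r.visible and r.has_coords()])

    # --- modeling -------------------------------------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(
            xy, stack,
            thin_config=ThinConfig(min_distance_km=2.0),
            background=BackgroundConfig(n_background=10_000, seed=seed + 3),
            tune_grid=TuneGrid(
                regularization_multipliers=(1.0, 2.0),
                feature_classes=(("linear", "quadratic"),
                                 ("linear", "quadratic", "hinge"))),
            seed=seed + 4)

    nested = all(
        (result.binaries[hi].data <= result.binaries[lo].data).all()
        for lo, hi in ((0, 10), (10, 20), (20, 30)))

    # --- expert feedback at the slider setting --------------------------
    from .postprocess import threshold_at_percentile

    train_xy = xy
    if result.suitability is not None:
        vals = result.suitability.sample(train_xy[:, 0], train_xy[:, 1])
        train_xy = train_xy[~np.isnan(vals)]
        binary, threshold = threshold_at_percentile(
            result.suitability, train_xy, slider_percent)
        vals = vals[~np.isnan(vals)]
        training_omission_pct = float((vals < threshold).mean() * 100)
    else:
        binary, threshold = result.binaries[0], None
        training_omission_pct = 0.0
    g = landscape.grid
    over = shapely.box(g.x0, g.y0 - 0.1 * g.dy * g.height,
                       g.x0 + 0.1 * g.dx * g.width, g.y0)  # NW corner strip
    feedback = ExpertFeedback(omission_percent=slider_percent,
                              over_polygons=[over],
                              habitat_classes={1, 2, 3, 4},
                              reviewer="expert-2")
    edited = apply_feedback(binary, feedback, landcover)

    # --- validation -----------------------------------------------------
    model = ModelRecord(model_id=f"syn-{seed}", species="Virtualis exempli",
                        metadata={"method": result.method,
                                  "seed": seed,
                                  "settings": result.metadata.get("settings"),
                                  "sources": ["synthetic"]})
    transition(model, "feedback_processed")
    decision = score_and_decide(model, [4, 3], reviewer="expert-2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = distribution_stats(edited, dem)

    summary = {
        "method": result.method,
        "n_raw_records": int(n_records),
        "n_visible": int(len(xy)),
        "n_modeled": int(result.metadata["n_occurrences"]),
        "cv": result.eval.get("chosen"),
        "threshold": threshold,
        "training_omission_pct": training_omission_pct,
        "binaries_nested": bool(nested),
        "decision": decision,
        "status": model.status,
        "distribution_stats": stats,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qc.write_occurrences(outdir / "occurrences.csv", records)
        qc.write_audit_log(outdir / "audit.jsonl", audit)
        if result.suitability is not None:
            write_geotiff(outdir / "suitability.tif", result.suitability)
        for p, rast in result.binaries.items():
            write_geotiff(outdir / f"binary_p{p}.tif", rast)
        write_geotiff(outdir / "binary_edited.tif", edited)
        meta = dict(result.metadata)
        meta["eval"] = {k: v for k, v in result.eval.items() if k != "cv_table"}
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        from .registry import save_record

        save_record(outdir / "model_record.json", model)
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
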