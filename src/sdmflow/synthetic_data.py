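"""Synthetic landscapes, virtual species and corrupted occurrence samples.

Everything the pipeline consumes can be generated offline and
deterministically from a seed: spatially autocorrelated environmental
fields (smoothed white noise), a linear-ramp DEM, a categorical land-cover
layer, a virtual species with a known Gaussian niche, and occurrence
tables with injected coordinate and identification errors plus spatial
duplicates and sampling bias — the error classes expert curation is meant
to catch.  Ground-truth corruption labels are returned beside (never
inside) the public record table, so QC benchmarks cannot cheat.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint

from .geo_core import EnvStack, Grid, Raster

__all__ = [
    "VirtualSpecies",
    "make_landscape",
    "make_species",
    "sample_occurrences",
    "make_group_table",
    "reference_group_table",
    "ERROR_TYPES",
]

ERROR_TYPES = ("zero_coords", "transposed", "duplicate", "off_range_misID")


@dataclass
class VirtualSpecies:
    """A species with a known niche on a synthetic landscape."""

    niche: dict  # variable -> (optimum, breadth)
    true_suitability: Raster
    true_range: Raster
    M_true: object  # polygon
    cutoff: float


def make_landscape(seed: int = 0, size: int = 100, n_vars: int = 2,
                   smoothness: float = 10.0,
                   x0: float = -75.0, y0: float = 6.0,
                   cell_deg: float = 0.01) -> EnvStack:
    """A synthetic environmental stack on a geographic grid.

    ``n_vars`` spatially autocorrelated standardized fields named
    ``env1..envN`` (white noise blurred with a Gaussian of radius
    ``smoothness`` cells), plus a south–north linear-ramp ``dem`` (0–3000 m
    with smooth relief) and a categorical ``landcover`` layer with classes
    1–5.  Deterministic per seed.  The default 0.01° cells are ~1.1 km —
    the national-scale resolution the pipeline targets.
    """
    if size < 10:
        raise ValueError("size must be at least 10")
    if n_vars < 1:
        raise ValueError("n_vars must be at least 1")
    grid = Grid(x0=x0, y0=y0, dx=cell_deg, dy=cell_deg,
                width=size, height=size)
    rng = np.random.default_rng(seed)
    layers: dict[str, np.ndarray] = {}
    for i in range(n_vars):
        f = gaussian_filter(rng.standard_normal((size, size)), smoothness,
                            mode="reflect")
        sd = f.std()
        layers[f"env{i + 1}"] = (f - f.mean()) / (sd if sd > 0 else 1.0)
    ramp = np.linspace(0.0, 3000.0, size)[:, None] * np.ones((1, size))
    relief = gaussian_filter(rng.standard_normal((size, size)), smoothness,
                             mode="reflect")
    sd = relief.std()
    layers["dem"] = ramp + 150.0 * (relief / (sd if sd > 0 else 1.0))
    lc_field = gaussian_filter(rng.standard_normal((size, size)),
                               smoothness / 2, mode="reflect")
    edges = np.quantile(lc_field, [0.2, 0.4, 0.6, 0.8])
    layers["landcover"] = (np.digitize(lc_field, edges) + 1).astype(float)
    return EnvStack(grid, layers)


def make_species(stack: EnvStack, niche: dict | None = None,
                 cutoff: float = 0.5) -> VirtualSpecies:
    """Define a virtual species by Gaussian responses on stack variables.

    ``niche`` maps variable names to (optimum, breadth); the true
    suitability is the product of per-variable Gaussian responses rescaled
    to maximum 1, and the true range is the cells at or above ``cutoff``.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must lie in (0, 1)")
    if niche is None:
        niche = {"env1": (1.0, 0.5), "env2": (-1.0, 0.5)}
    missing = set(niche) - set(stack.names)
    if missing:
        raise KeyError(f"niche variables not in stack: {sorted(missing)}")
    grid = stack.grid
    suit = np.ones(grid.shape)
    for var, (opt, breadth) in niche.items():
        if breadth <= 0:
            raise ValueError("niche breadth must be positive")
        suit *= np.exp(-0.5 * ((stack.layers[var] - opt) / breadth) ** 2)
    suit[~stack.valid_mask] = np.nan
    peak = np.nanmax(suit)
    if peak > 0:
        suit = suit / peak
    rng_mask = np.where(np.isnan(suit), False, suit >= cutoff)
    # accessible area: hull of the true range, generously buffered
    rows, cols = np.nonzero(rng_mask)
    if rows.size:
        lon, lat = grid.cell_center(rows, cols)
        hull = MultiPoint(np.column_stack([lon, lat]).tolist()).convex_hull
        M = hull.buffer(0.25)
    else:
        M = shapely.box(*grid.bounds)
    w, s, e, n = grid.bounds
    M = M.intersection(shapely.box(w, s, e, n))
    return VirtualSpecies(
        niche=dict(niche),
        true_suitability=Raster(grid, suit, nodata=float("nan")),
        true_range=Raster(grid, rng_mask.astype(np.uint8), nodata=None),
        M_true=M,
        cutoff=cutoff,
    )


_INSTITUTIONS = ("MHN", "UNAL", "ICN", "IAvH")
_COLLECTORS = ("A. Rios", "B. Mora", "C. Duarte", "D. Pabon")


def sample_occurrences(species: VirtualSpecies, n: int,
                       bias_raster: Raster | None = None,
                       error_rates: dict | None = None,
                       seed: int = 0,
                       taxon: str = "Virtualis exempli",
                       dem: Raster | None = None,
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a raw Darwin-Core-style occurrence table from a virtual species.

    Clean records are drawn with cell probability proportional to
    ``true_suitability × bias`` and jittered inside their cell.  Errors are
    injected per record at the requested rates, each labelled in the
    returned side array (never in the table itself):

    * ``zero_coords`` — coordinates replaced by (0, 0);
    * ``transposed`` — latitude and longitude swapped;
    * ``duplicate`` — a copy of an earlier record (same coordinates and
      provenance, less documentation);
    * ``off_range_misID`` — the point is moved to a low-suitability cell,
      mimicking a misidentified specimen.

    Returns ``(table, labels)`` with ``labels[i]`` in
    ``{"clean"} ∪ ERROR_TYPES``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    error_rates = dict(error_rates or {})
    unknown = set(error_rates) - set(ERROR_TYPES)
    if unknown:
        raise ValueError(f"unknown error types: {sorted(unknown)}")
    rates = np.array([error_rates.get(t, 0.0) for t in ERROR_TYPES])
    if (rates < 0).any() or rates.sum() > 1:
        raise ValueError("error rates must be in [0,1] and sum to <= 1")

    rng = np.random.default_rng(seed)
    suit = species.true_suitability
    grid = suit.grid
    w = np.where(np.isnan(suit.data), 0.0, suit.data).ravel()
    if bias_raster is not None:
        b = np.where(np.isnan(np.asarray(bias_raster.data, dtype=float)),
                     0.0, bias_raster.data).ravel()
        w = w * np.clip(b, 0.0, None)
    if w.sum() == 0:
        raise ValueError("nowhere to sample: suitability x bias is zero")
    p = w / w.sum()

    # low-suitability cells for misidentification injections
    valid = ~np.isnan(suit.data.ravel())
    low = valid & (suit.data.ravel() <= np.nanquantile(suit.data, 0.05))
    low_idx = np.flatnonzero(low)

    labels = np.array(["clean"] * n, dtype=object)
    draws = rng.random(n)
    cum = np.cumsum(rates)
    for i in range(n):
        for j, t in enumerate(ERROR_TYPES):
            if draws[i] < cum[j]:
                labels[i] = t
                break
    # a duplicate needs a predecessor
    if labels[0] == "duplicate":
        labels[0] = "clean"

    flat = rng.choice(p.size, size=n, p=p)
    rows_, cols_ = np.divmod(flat, grid.width)
    lon, lat = grid.cell_center(rows_, cols_)
    lon = lon + rng.uniform(-0.5, 0.5, n) * grid.dx
    lat = lat + rng.uniform(-0.5, 0.5, n) * grid.dy

    recs = []
    for i in range(n):
        has_date = rng.random() < 0.8
        year = int(rng.integers(1990, 2019))
        month = int(rng.integers(1, 13))
        day = int(rng.integers(1, 28))
        inst = str(rng.choice(_INSTITUTIONS))
        rec = {
            "scientificName": taxon,
            "decimalLatitude": float(lat[i]),
            "decimalLongitude": float(lon[i]),
            "occurrenceID": f"src:{seed}:{i}",
            "institutionCode": inst,
            "collectionCode": f"{inst}-COL",
            "catalogNumber": f"{int(rng.integers(1000, 99999))}",
            "recordedBy": str(rng.choice(_COLLECTORS)) if rng.random() < 0.7 else None,
            "eventDate": f"{year:04d}-{month:02d}-{day:02d}" if has_date else None,
            "locality": f"site-{int(rng.integers(1, 200))}" if rng.random() < 0.6 else None,
            "elevation": None,
        }
        if dem is not None and rng.random() < 0.6:
            ev = dem.sample(rec["decimalLongitude"], rec["decimalLatitude"])[0]
            if not np.isnan(ev):
                rec["elevation"] = float(round(ev + rng.normal(0, 30)))
        lab = labels[i]
        if lab == "zero_coords":
            rec["decimalLatitude"] = 0.0
            rec["decimalLongitude"] = 0.0
        elif lab == "transposed":
            rec["decimalLatitude"], rec["decimalLongitude"] = (
                rec["decimalLongitude"], rec["decimalLatitude"])
        elif lab == "duplicate":
            j = int(rng.integers(0, i))
            src = recs[j]
            for k in ("decimalLatitude", "decimalLongitude", "occurrenceID",
                      "institutionCode", "collectionCode", "catalogNumber"):
                rec[k] = src[k]
            rec["recordedBy"] = None
            rec["locality"] = None
            rec["elevation"] = None
        elif lab == "off_range_misID":
            k = int(rng.choice(low_idx))
            r0, c0 = divmod(k, grid.width)
            lo, la = grid.cell_center(r0, c0)
            rec["decimalLongitude"] = float(lo + rng.uniform(-0.5, 0.5) * grid.dx)
            rec["decimalLatitude"] = float(la + rng.uniform(-0.5, 0.5) * grid.dy)
        recs.append(rec)
    return pd.DataFrame(recs), labels


# ---------------------------------------------------------------------------
# group progress tables
# ---------------------------------------------------------------------------

# Fixed 18-group reference table (expert-network progress snapshot) used by
# the reporting acceptance checks; blanks in the source are zeros.
_REFERENCE_GROUP_CSV = """\
group,n_experts,n_species,n_under_development,n_pending,n_validated
Bees of Colombia,12,16,0,0,0
Aquatic birds of Colombia,48,80,2,0,14
Birds of Colombia,36,277,49,156,4
Beetles,18,4,1,0,0
Introduced fauna,24,21,17,0,1
Plants of paramo,21,212,212,0,0
Herps of Colombia,60,67,60,1,2
Introduced plants of Colombia,33,32,31,0,0
Dragonflies Colombia,5,13,11,0,0
Magnolias of Colombia,17,34,17,13,0
Mammals of Colombia,81,52,6,1,0
Orchids of Colombia,25,5,0,0,0
Palms,8,51,46,0,0
Freshwater fishes,10,1,1,0,0
Carnivorous plants of Colombia,4,4,1,0,0
Plants of dry forest,28,53,48,0,0
Primates of Colombia,28,38,0,1,37
Zamias of Colombia,17,20,0,0,20
"""


def reference_group_table() -> pd.DataFrame:
    """The fixed 18-row expert-group progress table."""
    return pd.read_csv(StringIO(_REFERENCE_GROUP_CSV))


def make_group_table(seed: int = 0, n_groups: int = 10) -> pd.DataFrame:
    """A random group progress table (non-negative integer counts)."""
    if n_groups < 1:
        raise ValueError("n_groups must be at least 1")
    rng = np.random.default_rng(seed)
    n_species = rng.integers(1, 300, n_groups)
    under = rng.binomial(n_species, 0.4)
    pending = rng.binomial(n_species - under, 0.2)
    validated = rng.binomial(n_species - under - pending, 0.3)
    return pd.DataFrame({
        "group": [f"group-{i + 1}" for i in range(n_groups)],
        "n_experts": rng.integers(1, 100, n_groups),
        "n_species": n_species,
        "n_under_development": under,
        "n_pending": pending,
        "n_validated": validated,
    })
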