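"""The tiered modeling engine.

The method used for a species is decided by how many clean occurrences
survive curation and thinning:

====================  =======================================
occurrences           method
====================  =======================================
1–2                   10-km buffer around the points (binary)
3–4                   convex hull of the points (binary)
5–9                   Bioclim environmental envelope
10+                   MaxEnt-style presence–background model
====================  =======================================

The MaxEnt-style model is an L1-regularized logistic presence–background
fit over an expanded feature basis (linear, quadratic, pairwise-product
and hinge features), i.e. the standard open equivalence of MaxEnt's Gibbs
model; its output is passed through the complementary log-log transform,
normalised over the background, so suitability is bounded in [0, 1].
Settings (regularization multiplier × feature classes) are chosen by
spatial-block cross-validation: minimum mean test omission at the
10th-percentile training threshold, ties broken by higher mean test AUC,
then by the smaller regularization multiplier.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.linear_model import LogisticRegression

from .geo_core import (
    AccessibleArea,
    EnvStack,
    Grid,
    Raster,
    buffer_points,
    convex_hull,
    default_accessible_area,
    haversine_km,
    rasterize_geometry,
)
from .postprocess import percentile_threshold_value

__all__ = [
    "ThinConfig",
    "BackgroundConfig",
    "TuneGrid",
    "SDMResult",
    "thin",
    "select_method",
    "sample_background",
    "BioclimModel",
    "fit_bioclim",
    "MaxentLikeModel",
    "fit_maxent_like",
    "spatial_partition",
    "tune",
    "fit_final",
    "evaluate",
    "run_pipeline",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = (0, 10, 20, 30)
FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")

# per-observation L1 weight at reg_multiplier = 1 (see fit_maxent_like)
_BASE_PENALTY_PER_OBS = 2e-4


@dataclass(frozen=True)
class ThinConfig:
    """Spatial thinning: minimum pairwise distance between retained points.

    The threshold is a user choice (picked from exploratory analysis of
    record density and spatial autocorrelation); there is no default that
    suits every dataset.
    """

    min_distance_km: float = 1.0

    def __post_init__(self) -> None:
        if self.min_distance_km <= 0:
            raise ValueError("min_distance_km must be positive")


@dataclass(frozen=True)
class BackgroundConfig:
    mode: str = "random"  # random | target_group | bias_surface
    n_background: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "target_group", "bias_surface"):
            raise ValueError(f"unknown background mode {self.mode!r}")
        if self.n_background <= 0:
            raise ValueError("n_background must be positive")


@dataclass(frozen=True)
class TuneGrid:
    regularization_multipliers: tuple = (0.5, 1.0, 2.0)
    feature_classes: tuple = (("linear", "quadratic"),
                              ("linear", "quadratic", "hinge"))
    k_partitions: int = 4

    def __post_init__(self) -> None:
        if not self.regularization_multipliers or not self.feature_classes:
            raise ValueError("tuning grid must be non-empty")
        if any(m <= 0 for m in self.regularization_multipliers):
            raise ValueError("regularization multipliers must be positive")
        if self.k_partitions < 2:
            raise ValueError("k_partitions must be at least 2")
        for fc in self.feature_classes:
            bad = set(fc) - set(FEATURE_CLASSES)
            if bad:
                raise ValueError(f"unknown feature classes {sorted(bad)}")


@dataclass
class SDMResult:
    """Everything one modeling run produced."""

    method: str
    suitability: Raster | None
    binaries: dict[int, Raster]
    eval: dict
    trained_params: dict
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# thinning and the ladder
# ---------------------------------------------------------------------------


def thin(lon, lat, min_distance_km: float, seed: int = 0) -> np.ndarray:
    """Greedy spatial thinning; returns indices of retained points.

    Repeatedly drops the point with the most neighbours closer than the
    threshold (ties broken by a seeded shuffle), until no pair violates the
    minimum distance — the spThin-style heuristic that tends to keep the
    most points.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = lon.size
    if n == 0:
        raise ValueError("thin requires at least one point")
    if min_distance_km <= 0:
        raise ValueError("min_distance_km must be positive")
    dist = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    close = (dist < min_distance_km) & ~np.eye(n, dtype=bool)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n)
    alive = np.ones(n, dtype=bool)
    while True:
        counts = np.where(alive, (close & alive[None, :]).sum(axis=1), -1)
        worst = counts.max()
        if worst <= 0:
            break
        cands = np.flatnonzero(counts == worst)
        drop = cands[np.argmin(tiebreak[cands])]
        alive[drop] = False
    return np.flatnonzero(alive)


def select_method(n_occurrences: int) -> str:
    """Map a clean-occurrence count to the modeling method.

    1–2 → buffer, 3–4 → hull, 5–9 → bioclim, ≥10 → maxent_like.  The count
    of five, which sits on the printed boundary between hull and envelope,
    goes to the envelope: the statistical model is preferred whenever it is
    feasible.
    """
    if n_occurrences <= 0:
        raise ValueError("need at least one occurrence")
    if n_occurrences <= 2:
        return "buffer"
    if n_occurrences <= 4:
        return "hull"
    if n_occurrences <= 9:
        return "bioclim"
    return "maxent_like"


# ---------------------------------------------------------------------------
# background sampling
# ---------------------------------------------------------------------------


def sample_background(config: BackgroundConfig, M: AccessibleArea,
                      stack: EnvStack,
                      bias_raster: Raster | None = None,
                      target_group_points: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Draw background points inside M on valid data cells.

    random: uniform over valid cells; bias_surface: cell probability
    proportional to the bias raster; target_group: the supplied occurrences
    of related, comparably-sampled taxa, filtered to M.  One point per
    sampled cell, at the cell centroid, without replacement; n is capped at
    the number of valid cells (with a warning).  Reproducible per seed.
    """
    grid = stack.grid
    inM = M.mask_on(grid) & stack.valid_mask
    if not inM.any():
        raise ValueError("accessible area does not intersect valid data cells")

    if config.mode == "target_group":
        if target_group_points is None:
            raise ValueError("target_group mode needs target_group_points")
        pts = np.asarray(target_group_points, dtype=float)
        lon, lat = pts[:, 0], pts[:, 1]
        keep = grid.contains(lon, lat)
        row, col = grid.cell_of(lon[keep], lat[keep])
        keep2 = inM[row, col]
        return lon[keep][keep2], lat[keep][keep2]

    rows, cols = np.nonzero(inM)
    n_valid = rows.size
    n = config.n_background
    if n > n_valid:
        warnings.warn(
            f"requested {n} background points but only {n_valid} valid cells "
            "in M; using every valid cell", stacklevel=2)
        n = n_valid
    rng = np.random.default_rng(config.seed)
    if config.mode == "random":
        idx = rng.choice(n_valid, size=n, replace=False)
    else:  # bias_surface
        if bias_raster is None:
            raise ValueError("bias_surface mode needs a bias raster")
        w = np.asarray(bias_raster.data, dtype=float)[rows, cols]
        w = np.where(np.isfinite(w) & (w > 0), w, 0.0)
        if w.sum() == 0:
            raise ValueError("bias raster is zero everywhere inside M")
        n_pos = int((w > 0).sum())
        if n > n_pos:
            warnings.warn(
                f"only {n_pos} cells have positive bias weight; capping",
                stacklevel=2)
            n = n_pos
        idx = rng.choice(n_valid, size=n, replace=False, p=w / w.sum())
    lon, lat = grid.cell_center(rows[idx], cols[idx])
    return lon, lat


# ---------------------------------------------------------------------------
# Bioclim envelope
# ---------------------------------------------------------------------------


class BioclimModel:
    """Percentile environmental envelope.

    For each variable the suitability contribution of a value ``x`` is
    ``2 * min(p, 1-p)`` where ``p`` is the percentile rank of ``x`` among
    the training presences (mean convention for ties); values outside the
    presence min–max envelope contribute 0.  Cell suitability is the
    minimum contribution over variables, so the surface is 1 at the
    multivariate presence median and falls to 0 at the envelope edge.
    """

    def __init__(self, presence_values: np.ndarray,
                 names: Sequence[str] | None = None,
                 constant_tol: float = 1e-9) -> None:
        X = np.asarray(presence_values, dtype=float)
        if X.ndim != 2 or X.shape[0] < 5:
            raise ValueError("Bioclim needs >= 5 presences with env values")
        if np.isnan(X).any():
            raise ValueError("presence env values contain NaN")
        self.names = list(names) if names is not None else [
            f"var{i}" for i in range(X.shape[1])]
        self._sorted = [np.sort(X[:, j]) for j in range(X.shape[1])]
        self._constant = []
        for j, s in enumerate(self._sorted):
            const = s[-1] - s[0] <= constant_tol * max(1.0, abs(s[0]))
            if const:
                warnings.warn(
                    f"variable {self.names[j]!r} is constant across presences; "
                    "its envelope is degenerate and scores 1 near that value",
                    stacklevel=2)
            self._constant.append(const)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0,1] for rows of env values; NaN rows → NaN."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = self._sorted[0].size
        out = np.ones(X.shape[0])
        for j, s in enumerate(self._sorted):
            x = X[:, j]
            if self._constant[j]:
                tol = 1e-6 * max(1.0, abs(s[0]))
                sj = np.where(np.abs(x - s[0]) <= tol, 1.0, 0.0)
            else:
                less = np.searchsorted(s, x, side="left")
                leq = np.searchsorted(s, x, side="right")
                p = (less + leq) / (2.0 * n)
                sj = 2.0 * np.minimum(p, 1.0 - p)
                sj = np.where((x < s[0]) | (x > s[-1]), 0.0, sj)
            sj = np.where(np.isnan(x), np.nan, sj)
            out = np.fmin(out, sj) if j else sj
        return np.clip(out, 0.0, 1.0) if X.shape[1] > 0 else out

    def predict_raster(self, stack: EnvStack) -> Raster:
        X = np.column_stack([stack.layers[n].ravel() for n in self.names])
        vals = self.score(X).reshape(stack.grid.shape)
        vals[~stack.valid_mask] = np.nan
        return Raster(stack.grid, vals, nodata=float("nan"))


def fit_bioclim(presence_values: np.ndarray,
                names: Sequence[str] | None = None) -> BioclimModel:
    return BioclimModel(presence_values, names)


# ---------------------------------------------------------------------------
# MaxEnt-style model
# ---------------------------------------------------------------------------


class _FeatureExpansion:
    """Expand raw env values into linear/quadratic/product/hinge features.

    Variables are min–max scaled to [0,1] on the training data; hinge
    knots sit at presence-value quantiles (both hinge directions).
    """

    def __init__(self, classes: Sequence[str], n_hinge_knots: int = 50) -> None:
        self.classes = tuple(classes)
        self.n_hinge_knots = n_hinge_knots

    def fit(self, X_all: np.ndarray, X_presence: np.ndarray,
            names: Sequence[str]) -> "_FeatureExpansion":
        X_all = np.asarray(X_all, dtype=float)
        self.names = list(names)
        self.lo = X_all.min(axis=0)
        span = X_all.max(axis=0) - self.lo
        self.span = np.where(span > 0, span, 1.0)
        if "hinge" in self.classes:
            Zp = (np.asarray(X_presence, dtype=float) - self.lo) / self.span
            qs = np.linspace(0, 1, self.n_hinge_knots + 2)[1:-1]
            self.knots = [np.unique(np.quantile(Zp[:, j], qs))
                          for j in range(Zp.shape[1])]
        return self

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, list[tuple]]:
        """Returns (features, provenance) where provenance[i] is a tuple of
        source-variable indices for coefficient attribution."""
        Z = (np.asarray(X, dtype=float) - self.lo) / self.span
        nvar = Z.shape[1]
        cols: list[np.ndarray] = []
        prov: list[tuple] = []
        if "linear" in self.classes:
            for j in range(nvar):
                cols.append(Z[:, j])
                prov.append((j,))
        if "quadratic" in self.classes:
            for j in range(nvar):
                cols.append(Z[:, j] ** 2)
                prov.append((j,))
        if "product" in self.classes:
            for i, j in itertools.combinations(range(nvar), 2):
                cols.append(Z[:, i] * Z[:, j])
                prov.append((i, j))
        if "hinge" in self.classes:
            for j in range(nvar):
                for k in self.knots[j]:
                    if k < 1.0:
                        cols.append(np.maximum(0.0, (Z[:, j] - k) / (1.0 - k)))
                        prov.append((j,))
                    if k > 0.0:
                        cols.append(np.maximum(0.0, (k - Z[:, j]) / k))
                        prov.append((j,))
        return np.column_stack(cols), prov


class MaxentLikeModel:
    """L1-penalized presence–background model with cloglog output.

    ``suitability = 1 - exp(-exp(H) * raw)`` where ``raw`` is the Gibbs
    density ``exp(eta)`` normalised over the background sample and ``H``
    its entropy — the normalisation that pins a typical background cell
    near suitability ``1 - 1/e``.
    """

    def __init__(self, expansion: _FeatureExpansion, coef: np.ndarray,
                 prov: list[tuple], names: Sequence[str],
                 log_z: float, entropy: float,
                 reg_multiplier: float) -> None:
        self.expansion = expansion
        self.coef = coef
        self.prov = prov
        self.names = list(names)
        self.log_z = log_z
        self.entropy = entropy
        self.reg_multiplier = reg_multiplier

    def _eta(self, X: np.ndarray) -> np.ndarray:
        F, _ = self.expansion.transform(X)
        return F @ self.coef

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        bad = np.isnan(X).any(axis=1)
        Xf = np.where(np.isnan(X), 0.0, X)
        log_raw = self._eta(Xf) - self.log_z
        out = 1.0 - np.exp(-np.exp(self.entropy + log_raw))
        out[bad] = np.nan
        return np.clip(out, 0.0, 1.0, out=out)

    def predict_raster(self, stack: EnvStack) -> Raster:
        X = np.column_stack([stack.layers[n].ravel() for n in self.names])
        vals = self.score(X).reshape(stack.grid.shape)
        vals[~stack.valid_mask] = np.nan
        return Raster(stack.grid, vals, nodata=float("nan"))

    def variable_importance(self) -> dict[str, float]:
        """Sum of |coefficient| attributed to each variable (products split
        evenly between their two sources)."""
        mass = np.zeros(len(self.names))
        for c, src in zip(self.coef, self.prov):
            for j in src:
                mass[j] += abs(c) / len(src)
        return dict(zip(self.names, mass))


def fit_maxent_like(X_presence: np.ndarray, X_background: np.ndarray,
                    names: Sequence[str],
                    features: Sequence[str] = ("linear", "quadratic", "hinge"),
                    reg_multiplier: float = 1.0,
                    n_hinge_knots: int = 50,
                    seed: int = 0) -> MaxentLikeModel:
    """Fit the presence–background model.

    The L1 penalty strength scales with ``reg_multiplier`` (sklearn
    ``C = 1/reg_multiplier``); a very large multiplier shrinks every
    coefficient to zero and the suitability surface to a constant.
    Deterministic given the inputs and seed.
    """
    Xp = np.asarray(X_presence, dtype=float)
    Xb = np.asarray(X_background, dtype=float)
    if Xp.shape[0] < 10:
        raise ValueError("maxent_like needs >= 10 presences")
    if np.isnan(Xp).any() or np.isnan(Xb).any():
        raise ValueError("env values contain NaN")
    expansion = _FeatureExpansion(features, n_hinge_knots)
    expansion.fit(np.vstack([Xp, Xb]), Xp, names)
    Fp, prov = expansion.transform(Xp)
    Fb, _ = expansion.transform(Xb)
    F = np.vstack([Fp, Fb])
    y = np.concatenate([np.ones(len(Fp)), np.zeros(len(Fb))])
    # the L1 weight is per observation (sklearn's C folds sample count into
    # the loss), so regularization strength does not vanish as the
    # background grows; the base weight plays the role of maxnet's default
    # feature-class regularization magnitude
    C = 1.0 / (reg_multiplier * _BASE_PENALTY_PER_OBS * len(F))
    clf = LogisticRegression(
        penalty="l1", C=C, solver="liblinear",
        max_iter=1000, tol=1e-6, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(F, y)
    coef = clf.coef_.ravel()
    eta_b = Fb @ coef
    log_z = float(logsumexp(eta_b))
    log_raw_b = eta_b - log_z
    raw_b = np.exp(log_raw_b)
    entropy = float(-(raw_b * log_raw_b).sum())
    return MaxentLikeModel(expansion, coef, prov, names, log_z, entropy,
                           reg_multiplier)


# ---------------------------------------------------------------------------
# spatial partitioning, evaluation, tuning
# ---------------------------------------------------------------------------


def _balanced_split(values: np.ndarray, order_key: np.ndarray) -> np.ndarray:
    """Rank-split into two halves of sizes differing by at most one."""
    order = np.lexsort((order_key, values))
    half = values.size // 2
    side = np.zeros(values.size, dtype=int)
    side[order[half:]] = 1
    return side


def spatial_partition(lon, lat, k: int = 4, *, return_edges: bool = False):
    """Geographic block folds from median splits (lon, then lat per half).

    Supported k: 2 (west/east) and 4 (quadrants).  Fold sizes differ by at
    most one per split; ties on a coordinate are broken by point order, so
    the labelling is deterministic.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = lon.size
    if k not in (2, 4):
        raise ValueError("spatial_partition supports k=2 or k=4 blocks")
    if n < k:
        raise ValueError(f"need at least {k} points for {k} blocks")
    idx = np.arange(n)
    ew = _balanced_split(lon, idx)
    if np.unique(lon).size == 1 and n > 1:
        warnings.warn("all longitudes identical; block split is arbitrary",
                      stacklevel=2)
    if k == 2:
        labels = ew
        edges = {"lon_split": float(np.median(lon))}
    else:
        labels = np.zeros(n, dtype=int)
        edges = {"lon_split": None, "lat_split": [None, None]}
        order = np.lexsort((idx, lon))
        half = n // 2
        lon_edge = (lon[order[half - 1]] + lon[order[min(half, n - 1)]]) / 2.0
        edges["lon_split"] = float(lon_edge)
        for side in (0, 1):
            sel = np.flatnonzero(ew == side)
            ns = _balanced_split(lat[sel], sel)
            labels[sel] = side * 2 + ns
            so = sel[np.lexsort((sel, lat[sel]))]
            h = sel.size // 2
            if sel.size >= 2:
                lat_edge = (lat[so[h - 1]] + lat[so[min(h, sel.size - 1)]]) / 2.0
            else:
                lat_edge = float(lat[so[0]])
            edges["lat_split"][side] = float(lat_edge)
    if return_edges:
        return labels, edges
    return labels


def assign_blocks(lon, lat, edges: Mapping) -> np.ndarray:
    """Assign arbitrary points (e.g. background) to the partition blocks."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    ew = (lon >= edges["lon_split"]).astype(int)
    if "lat_split" not in edges:
        return ew
    labels = np.zeros(lon.size, dtype=int)
    for side in (0, 1):
        sel = ew == side
        labels[sel] = side * 2 + (lat[sel] >= edges["lat_split"][side])
    return labels


def evaluate(presence_scores, background_scores,
             thresholds: Mapping[str, float] | None = None) -> dict:
    """Rank AUC and omission rates of a score vector pair.

    AUC is the probability that a random presence outranks a random
    background point (ties count half).  ``omission[t]`` is the fraction of
    presences scoring strictly below ``t``.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0:
        raise ValueError("empty test presence set")
    if b.size == 0:
        raise ValueError("empty background set")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[: p.size].sum() - p.size * (p.size + 1) / 2) / (p.size * b.size)
    out = {"auc": float(auc), "n_presence": int(p.size),
           "n_background": int(b.size), "omission": {}}
    for name, t in (thresholds or {}).items():
        out["omission"][name] = float((p < t).mean())
    return out


def tune(presence_xy: np.ndarray, background_xy: np.ndarray,
         stack: EnvStack, grid: TuneGrid = TuneGrid(), *,
         seed: int = 0, n_hinge_knots: int = 50,
         omission_percentile: float = 10.0) -> tuple[dict, pd.DataFrame]:
    """Spatial-block cross-validated settings search for the MaxEnt-style model.

    Returns (best settings, full eval table).  Best = lowest mean test
    omission at the ``omission_percentile`` training threshold, ties by
    highest mean test AUC, then by smallest regularization multiplier,
    then by feature-set order in the grid.
    """
    presence_xy = np.asarray(presence_xy, dtype=float)
    background_xy = np.asarray(background_xy, dtype=float)
    names = stack.names
    Xp = stack.sample(presence_xy[:, 0], presence_xy[:, 1])
    Xb = stack.sample(background_xy[:, 0], background_xy[:, 1])
    okp = ~np.isnan(Xp).any(axis=1)
    okb = ~np.isnan(Xb).any(axis=1)
    Xp, pxy = Xp[okp], presence_xy[okp]
    Xb, bxy = Xb[okb], background_xy[okb]
    k = min(grid.k_partitions, 4)
    labels, edges = spatial_partition(pxy[:, 0], pxy[:, 1], k, return_edges=True)
    blabels = assign_blocks(bxy[:, 0], bxy[:, 1], edges)

    rows = []
    for fc in grid.feature_classes:
        for rm in grid.regularization_multipliers:
            aucs, omis = [], []
            for fold in range(k):
                tr_p, te_p = labels != fold, labels == fold
                tr_b, te_b = blabels != fold, blabels == fold
                if te_p.sum() == 0 or tr_p.sum() < 10:
                    warnings.warn(f"fold {fold} lacks presences; skipped",
                                  stacklevel=2)
                    continue
                if te_b.sum() == 0 or tr_b.sum() == 0:
                    te_b = np.ones(len(Xb), dtype=bool)
                    tr_b = te_b
                model = fit_maxent_like(Xp[tr_p], Xb[tr_b], names, fc, rm,
                                        n_hinge_knots, seed)
                train_scores = model.score(Xp[tr_p])
                thr = percentile_threshold_value(train_scores,
                                                 omission_percentile)
                ev = evaluate(model.score(Xp[te_p]), model.score(Xb[te_b]),
                              {"t": thr})
                aucs.append(ev["auc"])
                omis.append(ev["omission"]["t"])
            rows.append({
                "features": ",".join(fc),
                "reg_multiplier": rm,
                "mean_test_auc": float(np.mean(aucs)) if aucs else np.nan,
                "mean_test_omission": float(np.mean(omis)) if omis else np.nan,
                "n_folds": len(aucs),
            })
    table = pd.DataFrame(rows)
    order = table.assign(_i=np.arange(len(table))).sort_values(
        ["mean_test_omission", "mean_test_auc", "reg_multiplier", "_i"],
        ascending=[True, False, True, True], kind="stable")
    best_row = order.iloc[0]
    best = {"features": tuple(best_row["features"].split(",")),
            "reg_multiplier": float(best_row["reg_multiplier"])}
    return best, table


# ---------------------------------------------------------------------------
# final fit + full pipeline
# ---------------------------------------------------------------------------


def _binary_raster(mask: np.ndarray, grid: Grid) -> Raster:
    return Raster(grid, mask.astype(np.uint8), nodata=None)


def _binaries_from_suitability(suit: Raster, presence_xy: np.ndarray,
                               percentiles=DEFAULT_PERCENTILES) -> tuple[dict, dict]:
    vals = suit.sample(presence_xy[:, 0], presence_xy[:, 1])
    vals = vals[~np.isnan(vals)]
    binaries, thresholds = {}, {}
    for p in percentiles:
        t = percentile_threshold_value(vals, p)
        data = np.where(np.isnan(suit.data), 0, suit.data >= t)
        binaries[int(p)] = _binary_raster(data.astype(bool), suit.grid)
        thresholds[int(p)] = float(t)
    return binaries, thresholds


def fit_final(presence_xy: np.ndarray, stack: EnvStack,
              M: AccessibleArea, method: str, *,
              background_xy: np.ndarray | None = None,
              settings: Mapping | None = None,
              buffer_km: float = 10.0,
              percentiles=DEFAULT_PERCENTILES,
              eval_stats: dict | None = None,
              seed: int = 0) -> SDMResult:
    """Refit on the full occurrence set and assemble the deliverables.

    Buffer and hull methods yield a binary directly (clipped to M); the
    statistical methods yield a suitability raster clipped to M plus
    thresholded binaries at the minimum/10/20/30 percentile training
    presence.
    """
    presence_xy = np.asarray(presence_xy, dtype=float)
    grid = stack.grid
    Mmask = M.mask_on(grid) & stack.valid_mask
    settings = dict(settings or {})
    meta = {"method": method, "n_occurrences": int(len(presence_xy)),
            "seed": seed, "settings": {k: (list(v) if isinstance(v, tuple) else v)
                                       for k, v in settings.items()}}

    if method in ("buffer", "hull"):
        if method == "hull":
            try:
                geom = convex_hull(presence_xy[:, 0], presence_xy[:, 1])
            except ValueError:
                warnings.warn("degenerate hull; falling back to buffer method",
                              stacklevel=2)
                method = "buffer"
                meta["method"] = "buffer (hull fallback)"
        if method == "buffer":
            geom = buffer_points(presence_xy[:, 0], presence_xy[:, 1], buffer_km)
        mask = rasterize_geometry(geom, grid) & Mmask
        binary = _binary_raster(mask, grid)
        return SDMResult(method=method, suitability=None,
                         binaries={int(p): binary for p in percentiles},
                         eval=eval_stats or {}, trained_params={},
                         metadata=meta)

    Xp = stack.sample(presence_xy[:, 0], presence_xy[:, 1])
    ok = ~np.isnan(Xp).any(axis=1)
    Xp, pxy = Xp[ok], presence_xy[ok]
    if method == "bioclim":
        model = fit_bioclim(Xp, stack.names)
        trained = {"envelopes": {n: [float(s[0]), float(s[-1])]
                                 for n, s in zip(model.names, model._sorted)}}
    elif method == "maxent_like":
        if background_xy is None:
            raise ValueError("maxent_like needs background points")
        Xb = stack.sample(background_xy[:, 0], background_xy[:, 1])
        Xb = Xb[~np.isnan(Xb).any(axis=1)]
        model = fit_maxent_like(
            Xp, Xb, stack.names,
            features=settings.get("features", ("linear", "quadratic", "hinge")),
            reg_multiplier=settings.get("reg_multiplier", 1.0),
            n_hinge_knots=settings.get("n_hinge_knots", 50),
            seed=seed)
        trained = {"coef_l1_norm": float(np.abs(model.coef).sum()),
                   "variable_importance": model.variable_importance(),
                   "reg_multiplier": model.reg_multiplier}
    else:
        raise ValueError(f"unknown method {method!r}")

    suit = model.predict_raster(stack)
    data = suit.data.copy()
    data[~Mmask] = np.nan
    suit = Raster(grid, data, nodata=float("nan"))
    binaries, thresholds = _binaries_from_suitability(suit, pxy, percentiles)
    meta["thresholds"] = thresholds
    ev = dict(eval_stats or {})
    return SDMResult(method=method, suitability=suit, binaries=binaries,
                     eval=ev, trained_params=trained, metadata=meta)


def run_pipeline(occ_xy: np.ndarray, stack: EnvStack, *,
                 M: AccessibleArea | None = None,
                 thin_config: ThinConfig | None = None,
                 background: BackgroundConfig | None = None,
                 tune_grid: TuneGrid | None = None,
                 bias_raster: Raster | None = None,
                 buffer_km: float = 10.0,
                 M_buffer_km: float = 200.0,
                 seed: int = 0) -> SDMResult:
    """End-to-end modeling for one species: thin → ladder → background →
    tune → final fit.  All stochastic steps derive from ``seed`` and every
    choice is recorded in the result metadata."""
    occ_xy = np.asarray(occ_xy, dtype=float)
    if thin_config is not None:
        keep = thin(occ_xy[:, 0], occ_xy[:, 1],
                    thin_config.min_distance_km, seed)
        occ_xy = occ_xy[keep]
    if M is None:
        M = default_accessible_area(occ_xy[:, 0], occ_xy[:, 1], stack.grid,
                                    M_buffer_km)
    method = select_method(len(occ_xy))
    eval_stats: dict = {}
    settings: dict = {}
    background_xy = None
    if method == "maxent_like":
        bg_conf = background or BackgroundConfig(seed=seed)
        lon_b, lat_b = sample_background(bg_conf, M, stack,
                                         bias_raster=bias_raster)
        background_xy = np.column_stack([lon_b, lat_b])
        grid_cfg = tune_grid or TuneGrid()
        best, table = tune(occ_xy, background_xy, stack, grid_cfg, seed=seed)
        settings = best
        eval_stats = {"cv_table": table.to_dict(orient="records"),
                      "chosen": {"features": list(best["features"]),
                                 "reg_multiplier": best["reg_multiplier"]}}
    elif method == "bioclim":
        bg_conf = background or BackgroundConfig(seed=seed)
        lon_b, lat_b = sample_background(bg_conf, M, stack,
                                         bias_raster=bias_raster)
        background_xy = np.column_stack([lon_b, lat_b])
        # evaluated (not tuned): spatial-block CV when enough points
        if len(occ_xy) >= 8:
            labels, edges = spatial_partition(occ_xy[:, 0], occ_xy[:, 1], 4,
                                              return_edges=True)
            Xall = stack.sample(occ_xy[:, 0], occ_xy[:, 1])
            ok = ~np.isnan(Xall).any(axis=1)
            aucs = []
            for fold in range(4):
                tr = ok & (labels != fold)
                te = ok & (labels == fold)
                if tr.sum() < 5 or te.sum() == 0:
                    continue
                m = fit_bioclim(Xall[tr], stack.names)
                Xb = stack.sample(lon_b, lat_b)
                okb = ~np.isnan(Xb).any(axis=1)
                aucs.append(evaluate(m.score(Xall[te]),
                                     m.score(Xb[okb]))["auc"])
            if aucs:
                eval_stats = {"cv_auc_mean": float(np.mean(aucs)),
                              "n_folds": len(aucs)}
    result = fit_final(occ_xy, stack, M, method,
                       background_xy=background_xy, settings=settings,
                       buffer_km=buffer_km, eval_stats=eval_stats, seed=seed)
    result.metadata["M_provenance"] = M.provenance
    return result
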