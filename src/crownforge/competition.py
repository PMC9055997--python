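"""Competition indices for stem-mapped plots.

Distance-independent indices (per 20 x 20 m plot):

* SD  — sum of DBH of all trees (cm)
* SDD — sum of DBH of the dominant trees (cm)
* SRD — sum of relative DBH, sum(D_i) / MDD with MDD the mean dominant DBH
* SBA — sum of basal area, sum(pi * (D_i/200)^2) in m^2

Distance-dependent indices sum the Hegyi index
``sum_j D_j / (D_i * (L_ij + 1))`` of every subject tree of the plot, with
competitors either the nearest tree in each of the four Cartesian quadrants
around the subject (SHGN, fixed number) or every tree within a fixed search
radius (SHGR, default 5 m, boundary closed).

Edge effects are removed by translation: the stand is conceptually tiled
with 8 shifted copies of itself, which for search radii below half the
stand dimension is exactly the minimum-image (torus) distance.  The torus
metric is the default; the explicit 3 x 3 tiling is retained as an oracle.
Subjects are always original-stand trees; competitors may be translated
images, so a subject near the stand boundary sees a full neighborhood.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stem_map import (
    ConfigurationError,
    DominantRule,
    StemMap,
    TreeRecord,
    stand_covariates,
)

__all__ = [
    "CompetitionConfig",
    "InsufficientNeighborsError",
    "pairwise_distance",
    "find_competitors_fixed_radius",
    "find_competitors_fixed_number",
    "hegyi_index",
    "plot_competition_index",
    "compute_plot_indices",
    "hegyi_per_tree",
]

INDEX_NAMES = ("SD", "SDD", "SRD", "SBA", "SHGN", "SHGR")

TILE_OFFSETS = [(ix, iy) for ix in (-1, 0, 1) for iy in (-1, 0, 1)]


class InsufficientNeighborsError(ValueError):
    """Fewer candidate competitors exist than the fixed-number rule needs."""


@dataclass(frozen=True)
class CompetitionConfig:
    """Settings for competitor identification and edge correction."""

    radius: float = 5.0  # m, fixed-radius search (SHGR)
    n_competitors: int = 4  # fixed-number search (SHGN)
    edge_correction: str = "torus"  # torus | tiling | none

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigurationError("radius must be > 0")
        if self.n_competitors < 1:
            raise ConfigurationError("n_competitors must be >= 1")
        if self.edge_correction not in ("torus", "tiling", "none"):
            raise ConfigurationError(f"unknown edge correction {self.edge_correction!r}")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _min_image(delta: np.ndarray, period: float) -> np.ndarray:
    """Signed minimum-image offset on a periodic axis."""
    return delta - period * np.round(delta / period)


def pairwise_distance(
    a: TreeRecord | tuple[float, float],
    b: TreeRecord | tuple[float, float],
    geometry: str = "euclidean",
    stand_dims: tuple[float, float] | None = None,
) -> float:
    """Distance between two trees, Euclidean or torus minimum-image.

    The torus metric with stand dimensions (W, H) equals the distance to the
    nearest of the 9 translated copies of ``b``, i.e. the 8-copy edge
    correction, whenever the relevant radius is below half the stand size.
    """
    ax, ay = (a.x, a.y) if isinstance(a, TreeRecord) else a
    bx, by = (b.x, b.y) if isinstance(b, TreeRecord) else b
    dx, dy = bx - ax, by - ay
    if geometry == "torus":
        if stand_dims is None:
            raise ConfigurationError("torus geometry requires stand_dims")
        dx = float(_min_image(np.array(dx), stand_dims[0]))
        dy = float(_min_image(np.array(dy), stand_dims[1]))
    elif geometry != "euclidean":
        raise ConfigurationError(f"unknown geometry {geometry!r}")
    return float(np.hypot(dx, dy))


def _displacements(
    sx: np.ndarray, sy: np.ndarray, x: np.ndarray, y: np.ndarray,
    stand_dims: tuple[float, float], edge: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(dx, dy) from each subject (rows) to each candidate (columns)."""
    dx = x[None, :] - sx[:, None]
    dy = y[None, :] - sy[:, None]
    if edge == "torus":
        dx = _min_image(dx, stand_dims[0])
        dy = _min_image(dy, stand_dims[1])
    return dx, dy


def _tiled_arrays(stem_map: StemMap) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coordinates, DBH and source index for the 3 x 3 tiling of the stand."""
    df = stem_map.df
    x0 = df["x"].to_numpy(float)
    y0 = df["y"].to_numpy(float)
    d0 = df["dbh"].to_numpy(float)
    xs, ys, ds, src = [], [], [], []
    for ix, iy in TILE_OFFSETS:
        xs.append(x0 + ix * stem_map.stand_width)
        ys.append(y0 + iy * stem_map.stand_height)
        ds.append(d0)
        src.append(np.arange(len(df)))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(ds), np.concatenate(src)


# ---------------------------------------------------------------------------
# Competitor identification (per-tree API)
# ---------------------------------------------------------------------------

def _subject_index(subject: TreeRecord, stem_map: StemMap) -> int:
    hits = np.flatnonzero((stem_map.df["tree_id"] == subject.tree_id).to_numpy())
    if len(hits) != 1:
        raise ConfigurationError(f"subject {subject.tree_id!r} not uniquely in stand")
    return int(hits[0])


def find_competitors_fixed_radius(
    subject: TreeRecord, stem_map: StemMap, config: CompetitionConfig | None = None
) -> list[tuple[TreeRecord, float]]:
    """All trees within ``config.radius`` of the subject (boundary closed),
    excluding the subject, under the configured edge correction."""
    config = config or CompetitionConfig()
    i = _subject_index(subject, stem_map)
    idx, dist = _radius_neighbors(stem_map, np.array([i]), config)[0]
    recs = list(stem_map.records())
    return [(recs[j], float(L)) for j, L in zip(idx, dist)]


def find_competitors_fixed_number(
    subject: TreeRecord, stem_map: StemMap, config: CompetitionConfig | None = None
) -> list[tuple[TreeRecord, float]]:
    """The nearest tree within each Cartesian quadrant around the subject
    (quadrants half-open in angle), with empty quadrants filled by the
    overall next-nearest unused tree so exactly ``n_competitors`` return.
    Distance ties break by tree_id."""
    config = config or CompetitionConfig()
    i = _subject_index(subject, stem_map)
    idx, dist = _quadrant_neighbors(stem_map, np.array([i]), config)[0]
    recs = list(stem_map.records())
    return [(recs[j], float(L)) for j, L in zip(idx, dist)]


def hegyi_index(
    subject: TreeRecord, competitors: list[tuple[TreeRecord, float]]
) -> float:
    """Hegyi competition index sum_j D_j / (D_i * (L_ij + 1)); 0 if no
    competitors.  DBH in cm, distance in m; the +1 m offset keeps the term
    finite for coincident stems."""
    if subject.dbh <= 0:
        raise ValueError("subject dbh must be > 0")
    return float(sum(c.dbh / (subject.dbh * (L + 1.0)) for c, L in competitors))


# ---------------------------------------------------------------------------
# Vectorized neighbor searches
# ---------------------------------------------------------------------------

def _id_rank(stem_map: StemMap) -> np.ndarray:
    """Rank of each tree's id in sorted order — the deterministic tie-break."""
    ids = stem_map.df["tree_id"].to_numpy()
    return np.argsort(np.argsort(ids, kind="mergesort"), kind="mergesort")


def _radius_neighbors(
    stem_map: StemMap, subjects: np.ndarray, config: CompetitionConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """For each subject row index: (competitor row indices, distances)."""
    df = stem_map.df
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    dims = (stem_map.stand_width, stem_map.stand_height)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    if config.edge_correction == "tiling":
        tx, ty, _, src = _tiled_arrays(stem_map)
        for i in subjects:
            dd = np.hypot(tx - x[i], ty - y[i])
            keep = (dd <= config.radius) & ~((src == i) & (dd == 0.0))
            out.append((src[keep], dd[keep]))
        return out
    edge = "torus" if config.edge_correction == "torus" else "none"
    for chunk in np.array_split(subjects, max(1, len(subjects) // 512)):
        dx, dy = _displacements(x[chunk], y[chunk], x, y, dims, edge)
        dd = np.hypot(dx, dy)
        for r, i in enumerate(chunk):
            keep = dd[r] <= config.radius
            keep[i] = False
            out.append((np.flatnonzero(keep), dd[r][np.flatnonzero(keep)]))
    return out


def _quadrant_neighbors(
    stem_map: StemMap, subjects: np.ndarray, config: CompetitionConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Nearest-in-quadrant competitors (with fallback fill) per subject."""
    df = stem_map.df
    n = len(df)
    k = config.n_competitors
    if n - 1 < k:
        raise InsufficientNeighborsError(
            f"stand has {n - 1} candidate competitors, need {k}"
        )
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    dims = (stem_map.stand_width, stem_map.stand_height)
    rank = _id_rank(stem_map)

    if config.edge_correction == "tiling":
        tx, ty, _, src = _tiled_arrays(stem_map)
    edge = "torus" if config.edge_correction == "torus" else "none"

    out: list[tuple[np.ndarray, np.ndarray]] = []
    for i in subjects:
        if config.edge_correction == "tiling":
            dx = tx - x[i]
            dy = ty - y[i]
            cand_src = src
            self_mask = (src == i) & (dx == 0) & (dy == 0)
        else:
            dx = _min_image(x - x[i], dims[0]) if edge == "torus" else x - x[i]
            dy = _min_image(y - y[i], dims[1]) if edge == "torus" else y - y[i]
            cand_src = np.arange(n)
            self_mask = cand_src == i
        dd = np.hypot(dx, dy)
        valid = ~self_mask
        # quadrants half-open in angle: [0,90), [90,180), [180,270), [270,360)
        ang = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
        quad = np.minimum((ang / (0.5 * np.pi)).astype(int), 3)
        order = np.lexsort((rank[cand_src], dd))
        order = order[valid[order]]
        chosen: list[int] = []
        chosen_src: set[int] = set()
        for q in range(4)[: min(4, k)]:
            for j in order:
                if quad[j] == q and cand_src[j] not in chosen_src:
                    chosen.append(j)
                    chosen_src.add(cand_src[j])
                    break
        for j in order:  # fallback: overall next-nearest unused trees
            if len(chosen) >= k:
                break
            if cand_src[j] not in chosen_src:
                chosen.append(j)
                chosen_src.add(cand_src[j])
        ch = np.asarray(chosen, dtype=int)
        out.append((cand_src[ch], dd[ch]))
    return out


def hegyi_per_tree(
    stem_map: StemMap,
    subjects: np.ndarray | None = None,
    *,
    rule: str = "fixed_number",
    config: CompetitionConfig | None = None,
) -> np.ndarray:
    """Hegyi index of each subject tree (default: all trees) under the
    fixed-number or fixed-radius competitor rule."""
    config = config or CompetitionConfig()
    if subjects is None:
        subjects = np.arange(stem_map.n_trees)
    d = stem_map.df["dbh"].to_numpy(float)
    search = _quadrant_neighbors if rule == "fixed_number" else _radius_neighbors
    neigh = search(stem_map, subjects, config)
    return np.array(
        [
            float(np.sum(d[idx] / (d[i] * (dist + 1.0)))) if len(idx) else 0.0
            for i, (idx, dist) in zip(subjects, neigh)
        ]
    )


# ---------------------------------------------------------------------------
# Plot-level indices
# ---------------------------------------------------------------------------

def plot_competition_index(
    plot_trees: pd.DataFrame,
    stem_map: StemMap,
    index_name: str,
    config: CompetitionConfig | None = None,
    dominant_rule: DominantRule | None = None,
) -> float:
    """One competition index for the trees of a single plot.

    Subjects of the distance-dependent indices are only the plot's own
    trees, but their competitors come from the whole (edge-corrected) stand.
    """
    if index_name not in INDEX_NAMES:
        raise ConfigurationError(f"unknown competition index {index_name!r}")
    config = config or CompetitionConfig()
    rule = dominant_rule or DominantRule()
    d = plot_trees["dbh"].to_numpy(float)
    if index_name == "SD":
        return float(d.sum())
    if index_name == "SDD":
        return float(rule.select(plot_trees)["dbh"].sum())
    if index_name == "SRD":
        mdd = stand_covariates(plot_trees, rule).ci_values["MDD"]
        return float(d.sum() / mdd)
    if index_name == "SBA":
        return float(np.sum(np.pi * (d / 200.0) ** 2))
    subjects = plot_trees.index.to_numpy()
    kind = "fixed_number" if index_name == "SHGN" else "fixed_radius"
    return float(hegyi_per_tree(stem_map, subjects, rule=kind, config=config).sum())


def compute_plot_indices(
    stem_map: StemMap,
    config: CompetitionConfig | None = None,
    dominant_rule: DominantRule | None = None,
) -> pd.DataFrame:
    """All six competition indices (plus MDD) for every non-empty plot."""
    config = config or CompetitionConfig()
    rule = dominant_rule or DominantRule()
    d = stem_map.df["dbh"].to_numpy(float)
    hg_n = hegyi_per_tree(stem_map, rule="fixed_number", config=config)
    hg_r = hegyi_per_tree(stem_map, rule="fixed_radius", config=config)
    rows = []
    for pid in stem_map.plot_ids():
        trees = stem_map.trees_of_plot(pid)
        idx = trees.index.to_numpy()
        dom = rule.select(trees)
        mdd = float(dom["dbh"].mean())
        rows.append(
            {
                "plot_id": pid,
                "n_trees": len(trees),
                "SD": float(d[idx].sum()),
                "SDD": float(dom["dbh"].sum()),
                "SRD": float(d[idx].sum() / mdd),
                "SBA": float(np.sum(np.pi * (d[idx] / 200.0) ** 2)),
                "SHGN": float(hg_n[idx].sum()),
                "SHGR": float(hg_r[idx].sum()),
                "MDD": mdd,
            }
        )
    return pd.DataFrame(rows)
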