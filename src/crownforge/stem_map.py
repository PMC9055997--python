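"""Stem-mapped stand data model: I/O, species grouping, plot gridding,
stand covariates and the calibration/validation split.

A stem map is one contiguous rectangular stand (default 120 x 140 m,
coordinates in local Cartesian meters) in which every tree with DBH >= 1 cm
is mapped.  The stand is gridded into square plots (default 20 x 20 m) and
all plot-level quantities — stand density (DEN, stems/ha), mean total height
(MTH, m), mean dominant height (MDH, m), Shannon diversity of species groups
(SHN, nats) and the competition indices — are computed per grid cell.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("crownforge")

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "EmptyPlotError",
    "SPECIES_GROUPS",
    "DEFAULT_GROUP_TABLE",
    "DominantRule",
    "TreeRecord",
    "PlotSummary",
    "StemMap",
    "classify_species_group",
    "growth_stage",
    "read_stem_map",
    "write_stem_map",
    "assign_plots",
    "stand_covariates",
    "plot_summaries",
    "split_calibration_validation",
]


class ConfigurationError(ValueError):
    """A configuration value (column map, fraction, index name...) is invalid."""


class ValidationError(ValueError):
    """Input data violate a stem-map invariant; message names the rows."""


class EmptyPlotError(ValueError):
    """A plot-level computation was requested for a plot with no trees."""


#: The six species groups of the study design: the five most numerous species
#: plus a pooled remainder.
SPECIES_GROUPS = ("BL", "PS", "PM", "LF", "PD", "Others")

#: Default Latin-name -> group table; any unlisted name falls back to Others.
DEFAULT_GROUP_TABLE: Mapping[str, str] = {
    "Betula luminifera": "BL",
    "Platycarya strobilacea": "PS",
    "Pinus massoniana": "PM",
    "Liquidambar formosana": "LF",
    "Populus davidiana": "PD",
}

#: Canonical column order of a normalized stem-map table.
COLUMNS = (
    "tree_id",
    "plot_id",
    "species_name",
    "species_group",
    "x",
    "y",
    "dbh",
    "th",
    "hcb",
    "cw",
    "growth_stage",
)

SAPLING_MAX_DBH = 5.0  # cm; below this a marked tree is a sapling
MIN_DBH = 1.0  # cm marking threshold


def classify_species_group(species_name: str, group_table: Mapping[str, str] | None = None) -> str:
    """Map a species name to one of the six species groups.

    Unlisted names map to ``"Others"``; the mapping is total and never raises.
    """
    table = DEFAULT_GROUP_TABLE if group_table is None else group_table
    bad = set(table.values()) - set(SPECIES_GROUPS)
    if bad:
        raise ConfigurationError(f"group_table maps to unknown groups: {sorted(bad)}")
    return table.get(species_name, "Others")


def growth_stage(dbh: float) -> str:
    """Sapling (1 <= DBH < 5 cm) or adult (DBH >= 5 cm)."""
    return "sapling" if dbh < SAPLING_MAX_DBH else "adult"


@dataclass(frozen=True)
class DominantRule:
    """How the dominant trees of a plot are selected.

    The ``count`` largest-DBH trees per plot (ties broken by tree_id) are
    dominant; a plot with fewer trees uses all of them.  ``count=None``
    selects every tree.  The default of 4 per 20 x 20 m plot matches the
    common 100-dominant-stems-per-hectare convention.
    """

    count: int | None = 4

    def select(self, trees: pd.DataFrame) -> pd.DataFrame:
        if self.count is None or len(trees) <= self.count:
            return trees
        order = trees.sort_values(["dbh", "tree_id"], ascending=[False, True], kind="mergesort")
        return order.iloc[: self.count]


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem."""

    tree_id: str
    plot_id: str | None
    species_name: str
    species_group: str
    x: float
    y: float
    dbh: float  # cm
    th: float  # m, total height
    hcb: float  # m, height to crown base
    cw: float  # m, crown width

    @property
    def growth_stage(self) -> str:
        return growth_stage(self.dbh)


@dataclass
class PlotSummary:
    """Per-plot stand covariates and competition indices."""

    plot_id: str
    grid_row: int
    grid_col: int
    n_trees: int
    den: float  # stems/ha
    mth: float  # m
    mdh: float  # m
    shn: float  # nats
    ci_values: dict[str, float] = field(default_factory=dict)


@dataclass
class StemMap:
    """A stand of mapped trees backed by a normalized pandas DataFrame."""

    df: pd.DataFrame
    stand_width: float = 120.0
    stand_height: float = 140.0
    plot_size: float = 20.0

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"stem map frame missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_trees(self) -> int:
        return len(self.df)

    @property
    def n_grid(self) -> tuple[int, int]:
        """(n_cols_along_x, n_rows_along_y) of the plot grid."""
        return (
            int(round(self.stand_width / self.plot_size)),
            int(round(self.stand_height / self.plot_size)),
        )

    def trees_of_plot(self, plot_id: str) -> pd.DataFrame:
        return self.df[self.df["plot_id"] == plot_id]

    def plot_ids(self) -> list[str]:
        return sorted(self.df["plot_id"].dropna().unique())

    def subset(self, mask: np.ndarray | pd.Series) -> "StemMap":
        return replace(self, df=self.df[mask].reset_index(drop=True))

    def records(self) -> Iterable[TreeRecord]:
        for row in self.df.itertuples(index=False):
            yield TreeRecord(
                tree_id=row.tree_id,
                plot_id=row.plot_id,
                species_name=row.species_name,
                species_group=row.species_group,
                x=row.x,
                y=row.y,
                dbh=row.dbh,
                th=row.th,
                hcb=row.hcb,
                cw=row.cw,
            )


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "tree_id": "tree_id",
    "species_name": "species_name",
    "x": "x",
    "y": "y",
    "dbh": "dbh",
    "th": "th",
    "hcb": "hcb",
    "cw": "cw",
}


def _validate_rows(df: pd.DataFrame, stand_width: float, stand_height: float) -> pd.Series:
    """Return a Series of row-indexed diagnostic strings (empty if clean)."""
    problems: dict[int, str] = {}

    def flag(mask: pd.Series, msg: str) -> None:
        for idx in df.index[mask.fillna(True)]:
            problems.setdefault(idx, msg)

    num = df[["x", "y", "dbh", "th", "hcb", "cw"]]
    flag(~np.isfinite(num).all(axis=1), "non-finite numeric value")
    flag(df["dbh"] < MIN_DBH, f"dbh below {MIN_DBH} cm marking threshold")
    flag(df["hcb"] <= 0, "hcb must be > 0")
    flag(df["hcb"] >= df["th"], "hcb >= th")
    flag(df["cw"] <= 0, "cw must be > 0")
    flag((df["x"] < 0) | (df["x"] > stand_width), "x outside stand")
    flag((df["y"] < 0) | (df["y"] > stand_height), "y outside stand")
    return pd.Series(problems, dtype="object")


def read_stem_map(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    group_table: Mapping[str, str] | None = None,
    stand_width: float = 120.0,
    stand_height: float = 140.0,
    plot_size: float = 20.0,
    mode: str = "strict",
) -> StemMap:
    """Read a delimited text file (CSV, or TSV by ``.tsv``/``.txt`` extension)
    into a validated :class:`StemMap`.

    ``column_map`` maps canonical field names (tree_id, species_name, x, y,
    dbh, th, hcb, cw; optionally plot_id) to the file's column headers.
    In ``strict`` mode any invariant violation raises a
    :class:`ValidationError` naming the offending rows; in ``lenient`` mode
    offending rows are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")

    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"columns not found in {path.name}: {missing}")

    df = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    for col in ("x", "y", "dbh", "th", "hcb", "cw"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["tree_id"] = df["tree_id"].astype(str)
    df["species_name"] = df["species_name"].astype(str)
    if "plot_id" not in df.columns:
        df["plot_id"] = None

    problems = _validate_rows(df, stand_width, stand_height)
    if len(problems):
        if mode == "strict":
            detail = "; ".join(f"row {i}: {msg}" for i, msg in problems.items())
            raise ValidationError(f"{len(problems)} invalid rows in {path.name}: {detail}")
        logger.warning("dropping %d invalid rows from %s", len(problems), path.name)
        df = df.drop(index=problems.index)

    df["species_group"] = [classify_species_group(s, group_table) for s in df["species_name"]]
    df["growth_stage"] = [growth_stage(d) for d in df["dbh"]]
    sm = StemMap(
        df[list(COLUMNS)].copy(),
        stand_width=stand_width,
        stand_height=stand_height,
        plot_size=plot_size,
    )
    if df["plot_id"].isna().all():
        sm = assign_plots(sm)
    return sm


def write_stem_map(stem_map: StemMap, path: str | Path) -> None:
    """Write the normalized stem map as CSV (full float precision)."""
    stem_map.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plot gridding
# ---------------------------------------------------------------------------

def _grid_cell(v: np.ndarray, cell: float, n_cells: int) -> np.ndarray:
    """Half-open cells [k*cell, (k+1)*cell); the last cell closed above."""
    k = np.floor(np.asarray(v, dtype=float) / cell).astype(int)
    return np.minimum(k, n_cells - 1)


def plot_id_of(grid_row: int, grid_col: int) -> str:
    return f"P{grid_row:02d}-{grid_col:02d}"


def assign_plots(stem_map: StemMap) -> StemMap:
    """Assign every tree to its square grid cell.

    Rows index the x direction, columns the y direction, so the default
    120 x 140 m stand yields a 6 x 7 grid of 42 plots.  Cells are half-open
    with the outermost row/column closed on the stand boundary; a coordinate
    outside the stand raises :class:`ValidationError`.
    """
    df = stem_map.df.copy()
    w, h = stem_map.stand_width, stem_map.stand_height
    out = (df["x"] < 0) | (df["x"] > w) | (df["y"] < 0) | (df["y"] > h)
    if out.any():
        raise ValidationError(f"coordinates outside stand for rows {list(df.index[out])}")
    n_x, n_y = stem_map.n_grid
    rows = _grid_cell(df["x"].to_numpy(), stem_map.plot_size, n_x)
    cols = _grid_cell(df["y"].to_numpy(), stem_map.plot_size, n_y)
    df["plot_id"] = [plot_id_of(r, c) for r, c in zip(rows, cols)]
    return replace(stem_map, df=df)


def grid_cell_of(x: float, y: float, stem_map: StemMap) -> tuple[int, int]:
    """(row, col) grid cell of a coordinate pair under the closure rule."""
    n_x, n_y = stem_map.n_grid
    r = int(_grid_cell(np.array([x]), stem_map.plot_size, n_x)[0])
    c = int(_grid_cell(np.array([y]), stem_map.plot_size, n_y)[0])
    return r, c


# ---------------------------------------------------------------------------
# Stand covariates
# ---------------------------------------------------------------------------

def shannon_index(groups: Iterable[str]) -> float:
    """Shannon diversity (natural log) of species-group stem proportions."""
    counts = pd.Series(list(groups)).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def stand_covariates(
    plot_trees: pd.DataFrame,
    dominant_rule: DominantRule | None = None,
    *,
    plot_area_ha: float = 0.04,
) -> PlotSummary:
    """Compute DEN, MTH, MDH, SHN (and MDD, stored in ci_values) for the
    trees of a single plot.

    DEN is stems per hectare (count / plot area); MDH and MDD are the mean
    height and mean DBH of the dominant trees under ``dominant_rule``.
    An empty plot raises :class:`EmptyPlotError` (empty plots are excluded
    from all plot-level analyses).
    """
    if len(plot_trees) == 0:
        raise EmptyPlotError("plot contains no trees")
    rule = dominant_rule or DominantRule()
    dom = rule.select(plot_trees)
    pid = plot_trees["plot_id"].iloc[0]
    row, col = 0, 0
    if isinstance(pid, str) and pid.startswith("P") and "-" in pid:
        try:
            row, col = (int(t) for t in pid[1:].split("-"))
        except ValueError:
            pass
    return PlotSummary(
        plot_id=str(pid),
        grid_row=row,
        grid_col=col,
        n_trees=len(plot_trees),
        den=len(plot_trees) / plot_area_ha,
        mth=float(plot_trees["th"].mean()),
        mdh=float(dom["th"].mean()),
        shn=shannon_index(plot_trees["species_group"]),
        ci_values={"MDD": float(dom["dbh"].mean())},
    )


def plot_summaries(
    stem_map: StemMap, dominant_rule: DominantRule | None = None
) -> pd.DataFrame:
    """Stand covariates for every non-empty plot, one row per plot."""
    area_ha = (stem_map.plot_size**2) / 1e4
    rows = []
    for pid in stem_map.plot_ids():
        s = stand_covariates(
            stem_map.trees_of_plot(pid), dominant_rule, plot_area_ha=area_ha
        )
        rows.append(
            {
                "plot_id": s.plot_id,
                "grid_row": s.grid_row,
                "grid_col": s.grid_col,
                "n_trees": s.n_trees,
                "DEN": s.den,
                "MTH": s.mth,
                "MDH": s.mdh,
                "SHN": s.shn,
                "MDD": s.ci_values["MDD"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration/validation split
# ---------------------------------------------------------------------------

def split_calibration_validation(
    stem_map: StemMap, fraction: float = 0.8, seed: int = 0
) -> tuple[StemMap, StemMap]:
    """Randomly split the non-empty plots into calibration and validation
    stem maps.

    The split is at plot level (trees of one plot are never separated);
    ``round(fraction * n_plots)`` plots go to calibration.  Deterministic
    given ``seed``; the union of the two parts reproduces the input.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    plots = stem_map.plot_ids()
    if len(plots) < 2:
        raise ValidationError("need at least 2 non-empty plots to split")
    rng = np.random.default_rng(seed)
    n_cal = int(round(fraction * len(plots)))
    n_cal = min(max(n_cal, 1), len(plots) - 1)
    cal_plots = set(rng.choice(plots, size=n_cal, replace=False))
    in_cal = stem_map.df["plot_id"].isin(cal_plots)
    logger.info(
        "split: %d calibration plots (%d trees), %d validation plots (%d trees), seed=%d",
        n_cal, int(in_cal.sum()), len(plots) - n_cal, int((~in_cal).sum()), seed,
    )
    return stem_map.subset(in_cal), stem_map.subset(~in_cal)
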