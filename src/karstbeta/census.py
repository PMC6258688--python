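"""Census-table I/O, quadrat aggregation and between-census dynamics.

A census table holds one row per free-standing woody stem with diameter at
breast height (dbh) >= 1 cm: tag, species code, map coordinates ``gx``/``gy``
(metres from the SW corner), dbh (cm) and a census id.  Stems are binned into
square quadrats ("cells") of a chosen grain; grains that do not divide the
plot extent use the largest origin-anchored sub-plot that is a multiple of
the grain, discarding the far (east/north) margin.

Conventions fixed here and relied on everywhere downstream:

* coordinates are half-open: a stem belongs to cell
  ``(floor(gx/g), floor(gy/g))``; ``gx == x_extent`` is invalid input;
* sites are identified by ``(ix, iy)`` cell indices and ordered
  lexicographically by ``(ix, iy)`` — the same order used for centroids,
  environmental tables and spatial eigenvectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .grid import PlotGeometry

REQUIRED_COLUMNS = ("tag", "species", "gx", "gy", "dbh", "census")

#: minimum dbh (cm) for a stem to enter the census
DBH_MIN = 1.0


def validate_census(df: pd.DataFrame, geometry: PlotGeometry) -> pd.DataFrame:
    """Validate a census table against the plot geometry.

    Returns a copy with stems below the dbh inclusion rule removed; the
    number removed is recorded in ``df.attrs['excluded_small_dbh']``.

    Raises
    ------
    FormatError
        if a required column is missing.
    ValidationError
        for out-of-bounds coordinates (listing offending tags) or tags
        duplicated within a census.
    """
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"census table missing columns: {sorted(missing)}")
    df = df.copy()
    gx = df["gx"].to_numpy(float)
    gy = df["gy"].to_numpy(float)
    oob = (gx < 0) | (gx >= geometry.x_extent) | (gy < 0) | (gy >= geometry.y_extent)
    oob |= ~np.isfinite(gx) | ~np.isfinite(gy)
    if oob.any():
        bad = df.loc[oob, "tag"].astype(str).tolist()
        shown = ", ".join(bad[:10]) + ("..." if len(bad) > 10 else "")
        raise ValidationError(
            f"{len(bad)} stems outside [0, extent) bounds (half-open convention): {shown}"
        )
    for cid, grp in df.groupby("census"):
        dup = grp["tag"][grp["tag"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicated tags in census {cid}: {sorted(set(dup.astype(str)))[:10]}"
            )
    small = df["dbh"].to_numpy(float) < DBH_MIN
    n_small = int(small.sum())
    if n_small:
        warnings.warn(f"excluded {n_small} stems with dbh < {DBH_MIN} cm", stacklevel=2)
    out = df.loc[~small].reset_index(drop=True)
    out.attrs["excluded_small_dbh"] = n_small
    return out


def read_census(path, geometry: PlotGeometry) -> pd.DataFrame:
    """Read and validate a census CSV (columns tag,species,gx,gy,dbh,census)."""
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:  # pragma: no cover - I/O
        raise FormatError(f"cannot read census CSV {path}: {exc}") from exc
    return validate_census(df, geometry)


def write_census(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def sub_extent_for_grain(geometry: PlotGeometry, grain: float) -> tuple[float, float]:
    """Largest origin-anchored (sub_x, sub_y) with both multiples of ``grain``.

    E.g. on 500 x 300 m: grain 30 -> (480, 300); grain 40 -> (480, 280);
    grain 60 -> (480, 300).  Stems beyond the sub-extent are discarded by
    :func:`aggregate` (the far margin is the one dropped).
    """
    if grain <= 0:
        raise ConfigurationError("grain must be positive")
    if grain > min(geometry.x_extent, geometry.y_extent):
        raise ConfigurationError(
            f"grain {grain} exceeds the smaller plot extent "
            f"({min(geometry.x_extent, geometry.y_extent)} m)"
        )
    sub_x = np.floor(geometry.x_extent / grain + 1e-9) * grain
    sub_y = np.floor(geometry.y_extent / grain + 1e-9) * grain
    return float(sub_x), float(sub_y)


def site_ids_for_grain(geometry: PlotGeometry, grain: float) -> list[tuple[int, int]]:
    """All (ix, iy) cell ids of the grain's sub-extent, in canonical order."""
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)
    ncx, ncy = int(round(sub_x / grain)), int(round(sub_y / grain))
    return [(ix, iy) for ix in range(ncx) for iy in range(ncy)]


@dataclass
class AbundanceMatrix:
    """Quadrat x species count matrix at one grain.

    ``counts`` rows are indexed by (ix, iy) cell ids in canonical order and
    include every cell of the sub-extent (possibly with an all-zero row);
    columns are sorted species codes.
    """

    grain: float
    sub_extent: tuple[float, float]
    counts: pd.DataFrame
    discarded_margin_stems: int = 0

    @property
    def site_ids(self) -> list[tuple[int, int]]:
        return list(self.counts.index)

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "ix", "level_1": "iy", "level_2": "species"})
        )
        long.columns = ["ix", "iy", "species", "count"]
        return long[long["count"] > 0].reset_index(drop=True)

    def write(self, path_csv, path_meta=None) -> None:
        self.to_long().to_csv(path_csv, index=False)
        if path_meta is not None:
            meta = {
                "grain": self.grain,
                "sub_extent": list(self.sub_extent),
                "n_sites": self.n_sites,
                "discarded_margin_stems": self.discarded_margin_stems,
            }
            with open(path_meta, "w") as fh:
                json.dump(meta, fh, indent=2)


def aggregate(
    census: pd.DataFrame,
    geometry: PlotGeometry,
    grain: float,
    species: list | None = None,
) -> AbundanceMatrix:
    """Bin stems into grain-sized cells; stems beyond the sub-extent are dropped.

    ``species`` optionally fixes the column set/order (so the two censuses can
    share one species space); otherwise the species present are used, sorted.
    """
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)
    ids = site_ids_for_grain(geometry, grain)
    if len(census) == 0:
        warnings.warn("aggregating an empty census", stacklevel=2)
    gx = census["gx"].to_numpy(float)
    gy = census["gy"].to_numpy(float)
    inside = (gx < sub_x) & (gy < sub_y)
    kept = census.loc[inside]
    ix = np.floor(kept["gx"].to_numpy(float) / grain).astype(int)
    iy = np.floor(kept["gy"].to_numpy(float) / grain).astype(int)
    if species is None:
        species = sorted(census["species"].astype(str).unique())
    index = pd.MultiIndex.from_tuples(ids)
    if len(kept):
        tab = pd.crosstab(index=[ix, iy], columns=kept["species"].astype(str).to_numpy())
        counts = tab.reindex(index=index, columns=list(species), fill_value=0).astype(np.int64)
    else:
        counts = pd.DataFrame(0, index=index, columns=list(species), dtype=np.int64)
    return AbundanceMatrix(
        grain=float(grain),
        sub_extent=(sub_x, sub_y),
        counts=counts,
        discarded_margin_stems=int((~inside).sum()),
    )


@dataclass
class DynamicsSummary:
    """Dead/new stem bookkeeping between two censuses at one grain.

    Dead = tags present in census 1 and absent from census 2; new = the
    converse.  Per-cell counts cover the grain's sub-extent, and the
    per-species tallies are restricted to the same sub-extent so that the two
    margins of the summary add up to the same totals.
    """

    grain: float
    species_dead: pd.Series
    species_new: pd.Series
    cell_dead: pd.Series
    cell_new: pd.Series
    species_lost: set
    species_gained: set

    @property
    def n_dead(self) -> int:
        return int(self.species_dead.sum())

    @property
    def n_new(self) -> int:
        return int(self.species_new.sum())


def census_dynamics(
    c1: pd.DataFrame, c2: pd.DataFrame, geometry: PlotGeometry, grain: float
) -> DynamicsSummary:
    """Tag-set dynamics between two validated censuses sharing a tag namespace."""
    for cdf, label in ((c1, "census 1"), (c2, "census 2")):
        if cdf["tag"].duplicated().any():
            raise ValidationError(f"duplicated tags within {label}")
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)

    tags1 = set(c1["tag"])
    tags2 = set(c2["tag"])
    dead = c1[c1["tag"].isin(tags1 - tags2)]
    new = c2[c2["tag"].isin(tags2 - tags1)]

    def _per_cell(df: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
        inside = (df["gx"].to_numpy(float) < sub_x) & (df["gy"].to_numpy(float) < sub_y)
        kept = df.loc[inside]
        ix = np.floor(kept["gx"].to_numpy(float) / grain).astype(int)
        iy = np.floor(kept["gy"].to_numpy(float) / grain).astype(int)
        index = pd.MultiIndex.from_tuples(site_ids_for_grain(geometry, grain))
        per_cell = (
            pd.Series(1, index=pd.MultiIndex.from_arrays([ix, iy]))
            .groupby(level=[0, 1])
            .sum()
            .reindex(index, fill_value=0)
            .astype(np.int64)
        )
        return per_cell, kept

    cell_dead, dead_kept = _per_cell(dead)
    cell_new, new_kept = _per_cell(new)
    species_dead = dead_kept.groupby(dead_kept["species"].astype(str)).size().astype(np.int64)
    species_new = new_kept.groupby(new_kept["species"].astype(str)).size().astype(np.int64)

    sp1 = set(c1["species"].astype(str))
    sp2 = set(c2["species"].astype(str))
    return DynamicsSummary(
        grain=float(grain),
        species_dead=species_dead,
        species_new=species_new,
        cell_dead=cell_dead,
        cell_new=cell_new,
        species_lost=sp1 - sp2,
        species_gained=sp2 - sp1,
    )
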