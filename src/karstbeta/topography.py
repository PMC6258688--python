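"""Per-quadrat topographic variables from a node elevation grid.

Eight variables describe each quadrat: elevation (ELE, m), slope (SLO,
degrees), convexity (CON, m), the sine and cosine of aspect (SIN, COS),
topographic wetness index (TWI), altitude above channels (ACH, m) and rock
bareness rate (RBR, fraction).  Conventions (all operating on the cell grid
of a chosen grain, with cells ordered as in :mod:`karstbeta.census`):

* ELE is the mean of the cell's four corner-node elevations.
* SLO is the mean, in degrees, of the slopes of the four planes through
  three of the cell's four corners (the classic forest-plot convention).
* Aspect is the compass direction of steepest ascent of the least-squares
  plane through the four corners, measured clockwise from north
  (SIN = sin(aspect), COS = cos(aspect)); cells flatter than 1e-6 degrees
  get SIN = COS = 0 and a ``flat`` flag.
* CON is the focal cell's ELE minus the mean ELE of its 8 neighbours;
  cells missing neighbours use centre-node elevation minus their own ELE.
* TWI and ACH are simplified D8 (single-flow-direction) stand-ins:
  TWI = ln(a.g / tan(max(SLO, 0.1 deg))) with a the D8 flow-accumulation
  count (upslope cells including self), and ACH the focal ELE minus the ELE
  of the Euclidean-nearest channel cell (cells with a >= channel_threshold).
  Externally measured TWI/ACH/RBR columns can override these.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial.distance import pdist

from .census import site_ids_for_grain, sub_extent_for_grain
from .distmat import DistMatrix
from .errors import ComputationError, ConfigurationError
from .grid import ElevationGrid, PlotGeometry

FLAT_SLOPE_DEG = 1e-6

#: canonical order of the expanded predictor columns
POLY_VARIABLES = ("ELE", "SLO", "CON", "TWI", "ACH", "RBR")

# D8 neighbour offsets, fixed tie-break order: E, NE, N, NW, W, SW, S, SE
_D8_OFFSETS = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]


def _cell_corners(dem: ElevationGrid, geometry: PlotGeometry, grain: float):
    """Corner elevations (z00, z10, z01, z11), each (ncx, ncy).

    Cell corners that coincide with lattice nodes take the node value;
    grains that are not node multiples (e.g. 25 m on a 10 m lattice) get
    bilinearly interpolated corner elevations from the node grid.
    """
    if abs(dem.resolution - geometry.base_resolution) > 1e-9:
        raise ConfigurationError("dem resolution differs from geometry base resolution")
    step = grain / dem.resolution
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)
    ncx, ncy = int(round(sub_x / grain)), int(round(sub_y / grain))
    if (
        dem.values.shape[0] - 1 + 1e-9 < ncx * step
        or dem.values.shape[1] - 1 + 1e-9 < ncy * step
    ):
        raise ComputationError(
            f"dem ({dem.values.shape}) does not cover the {ncx}x{ncy} cell grid at grain {grain}"
        )
    u = np.minimum(np.arange(ncx + 1) * step, dem.values.shape[0] - 1)
    v = np.minimum(np.arange(ncy + 1) * step, dem.values.shape[1] - 1)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    corners = map_coordinates(dem.values, [uu.ravel(), vv.ravel()], order=1).reshape(
        ncx + 1, ncy + 1
    )
    z00 = corners[:-1, :-1]
    z10 = corners[1:, :-1]
    z01 = corners[:-1, 1:]
    z11 = corners[1:, 1:]
    return z00, z10, z01, z11


def cell_elevation(dem: ElevationGrid, geometry: PlotGeometry, grain: float) -> np.ndarray:
    """Mean corner-node elevation per cell, shape (ncx, ncy)."""
    z00, z10, z01, z11 = _cell_corners(dem, geometry, grain)
    return (z00 + z10 + z01 + z11) / 4.0


def cell_slope_aspect(dem: ElevationGrid, geometry: PlotGeometry, grain: float):
    """(SLO degrees, SIN, COS, flat flag) per cell, each (ncx, ncy)."""
    g = float(grain)
    z00, z10, z01, z11 = _cell_corners(dem, geometry, grain)
    # the four planes through three of the four corners
    grads = [
        ((z10 - z00) / g, (z01 - z00) / g),
        ((z10 - z00) / g, (z11 - z10) / g),
        ((z11 - z01) / g, (z01 - z00) / g),
        ((z11 - z01) / g, (z11 - z10) / g),
    ]
    slo = np.degrees(
        np.mean([np.arctan(np.hypot(dx, dy)) for dx, dy in grads], axis=0)
    )
    # least-squares plane through the four corners (symmetric design -> closed form)
    a = ((z10 + z11) - (z00 + z01)) / (2 * g)  # eastward gradient
    b = ((z01 + z11) - (z00 + z10)) / (2 * g)  # northward gradient
    mag = np.hypot(a, b)
    flat = (slo < FLAT_SLOPE_DEG) | (mag < 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_a = np.where(flat, 0.0, a / np.where(mag == 0, 1.0, mag))
        cos_a = np.where(flat, 0.0, b / np.where(mag == 0, 1.0, mag))
    return slo, sin_a, cos_a, flat


def convexity(cell_ele: np.ndarray, center_ele: np.ndarray) -> np.ndarray:
    """Focal ELE minus mean neighbour ELE; border cells use centre minus own ELE.

    ``center_ele`` supplies the elevation at each cell's centre point, used
    only for cells that do not have all eight neighbours.
    """
    ele = np.asarray(cell_ele, dtype=float)
    ncx, ncy = ele.shape
    padded = np.full((ncx + 2, ncy + 2), np.nan)
    padded[1:-1, 1:-1] = ele
    stacks = [
        padded[1 + dx : ncx + 1 + dx, 1 + dy : ncy + 1 + dy]
        for dx, dy in _D8_OFFSETS
    ]
    nb = np.stack(stacks)
    interior = ~np.isnan(nb).any(axis=0)
    con_interior = ele - np.nanmean(nb, axis=0)
    return np.where(interior, con_interior, np.asarray(center_ele, dtype=float) - ele)


def _center_elevation(dem: ElevationGrid, geometry: PlotGeometry, grain: float) -> np.ndarray:
    """Bilinear node-grid elevation at each cell centre."""
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)
    ncx, ncy = int(round(sub_x / grain)), int(round(sub_y / grain))
    step = grain / dem.resolution
    u = (np.arange(ncx) + 0.5) * step
    v = (np.arange(ncy) + 0.5) * step
    uu, vv = np.meshgrid(u, v, indexing="ij")
    return map_coordinates(dem.values, [uu.ravel(), vv.ravel()], order=1).reshape(ncx, ncy)


def topo_variables(dem: ElevationGrid, geometry: PlotGeometry, grain: float) -> pd.DataFrame:
    """ELE, SLO, CON, SIN, COS (plus a ``flat`` flag) per cell, in site order."""
    ele = cell_elevation(dem, geometry, grain)
    slo, sin_a, cos_a, flat = cell_slope_aspect(dem, geometry, grain)
    con = convexity(ele, _center_elevation(dem, geometry, grain))
    ids = site_ids_for_grain(geometry, grain)
    index = pd.MultiIndex.from_tuples(ids)

    def flatten(arr):
        # canonical site order is lexicographic (ix, iy) = C order of (ncx, ncy)
        return arr.ravel(order="C")

    return pd.DataFrame(
        {
            "ELE": flatten(ele),
            "SLO": flatten(slo),
            "CON": flatten(con),
            "SIN": flatten(sin_a),
            "COS": flatten(cos_a),
            "flat": flatten(flat),
        },
        index=index,
    )


def d8_flow(cell_ele: np.ndarray, grain: float):
    """D8 receivers and flow accumulation on a cell-elevation grid.

    Returns (receiver, accumulation): ``receiver[i, j]`` is the flat index of
    the steepest-descent neighbour (ties broken by the fixed E, NE, N, NW, W,
    SW, S, SE order; -1 for pits), and ``accumulation`` counts upslope cells
    including the cell itself.
    """
    ele = np.asarray(cell_ele, dtype=float)
    ncx, ncy = ele.shape
    best_slope = np.full(ele.shape, 0.0)
    receiver = np.full(ele.shape, -1, dtype=np.int64)
    for dx, dy in _D8_OFFSETS:
        dist = grain * np.hypot(dx, dy)
        nb = np.full(ele.shape, np.nan)
        xs = np.arange(ncx) + dx
        ys = np.arange(ncy) + dy
        valid_x = (xs >= 0) & (xs < ncx)
        valid_y = (ys >= 0) & (ys < ncy)
        sub = np.ix_(valid_x, valid_y)
        nb[sub] = ele[np.ix_(xs[valid_x], ys[valid_y])]
        with np.errstate(invalid="ignore"):
            slope = (ele - nb) / dist
        better = np.isfinite(slope) & (slope > best_slope + 1e-15)
        best_slope = np.where(better, slope, best_slope)
        nb_flat = (np.arange(ncx)[:, None] + dx) * ncy + (np.arange(ncy)[None, :] + dy)
        receiver = np.where(better, nb_flat, receiver)

    acc = np.ones(ncx * ncy, dtype=np.int64)
    order = np.argsort(ele.ravel(), kind="stable")[::-1]
    recv = receiver.ravel()
    for idx in order:
        r = recv[idx]
        if r >= 0:
            acc[r] += acc[idx]
    return receiver, acc.reshape(ncx, ncy)


def twi_ach(
    dem: ElevationGrid,
    geometry: PlotGeometry,
    grain: float,
    channel_threshold: int = 10,
) -> pd.DataFrame:
    """Simplified TWI and ACH columns (site order), from D8 flow on cell ELE."""
    ele = cell_elevation(dem, geometry, grain)
    slo, _, _, _ = cell_slope_aspect(dem, geometry, grain)
    _, acc = d8_flow(ele, grain)
    slope_floor = np.maximum(slo, 0.1)
    twi = np.log(acc * grain / np.tan(np.radians(slope_floor)))

    channel = acc >= channel_threshold
    if not channel.any():
        raise ComputationError(
            f"no channel cell with accumulation >= {channel_threshold}; "
            "lower channel_threshold"
        )
    ncx, ncy = ele.shape
    xs, ys = np.meshgrid(np.arange(ncx), np.arange(ncy), indexing="ij")
    ch_x, ch_y = xs[channel], ys[channel]
    ch_ele = ele[channel]
    d2 = (xs.ravel()[:, None] - ch_x[None, :]) ** 2 + (ys.ravel()[:, None] - ch_y[None, :]) ** 2
    nearest = np.argmin(d2, axis=1)
    ach = (ele.ravel() - ch_ele[nearest]).reshape(ncx, ncy)

    index = pd.MultiIndex.from_tuples(site_ids_for_grain(geometry, grain))
    return pd.DataFrame(
        {"TWI": twi.ravel(order="C"), "ACH": ach.ravel(order="C")}, index=index
    )


def env_table(
    dem: ElevationGrid,
    geometry: PlotGeometry,
    grain: float,
    channel_threshold: int = 10,
    rbr: np.ndarray | pd.Series | None = None,
    overrides: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the eight-variable environmental table for one grain.

    ``rbr`` supplies the rock-bareness column (a field-survey quantity with
    no terrain algorithm); ``overrides`` may replace any computed column
    (typically externally measured TWI/ACH) by name.
    """
    env = topo_variables(dem, geometry, grain)
    env = env.join(twi_ach(dem, geometry, grain, channel_threshold))
    if rbr is None:
        rbr = np.zeros(len(env))
        warnings.warn("no RBR column supplied; filled with zeros", stacklevel=2)
    env["RBR"] = np.asarray(rbr, dtype=float)
    if (env["RBR"] < 0).any() or (env["RBR"] > 1).any():
        raise ConfigurationError("RBR must lie in [0, 1]")
    for name, values in (overrides or {}).items():
        if name not in env.columns:
            raise ConfigurationError(f"unknown environmental column override: {name}")
        env[name] = np.asarray(values, dtype=float)
    return env[["ELE", "SLO", "CON", "SIN", "COS", "TWI", "ACH", "RBR", "flat"]]


def polynomial_expand(env: pd.DataFrame) -> pd.DataFrame:
    """Third-degree polynomial expansion to the fixed 20-column predictor set.

    Each of ELE, SLO, CON, TWI, ACH, RBR is centred (column mean zero) and
    emitted with its square and cube; SIN and COS are appended unchanged.
    Column order: ELE, ELE2, ELE3, SLO, ..., RBR3, SIN, COS.  A constant
    column yields zero polynomial columns (with a warning) so the 20-column
    contract always holds.
    """
    missing = [v for v in POLY_VARIABLES + ("SIN", "COS") if v not in env.columns]
    if missing:
        raise ConfigurationError(f"environmental table missing columns: {missing}")
    out = {}
    for var in POLY_VARIABLES:
        v = env[var].to_numpy(float)
        centred = v - v.mean()
        if np.allclose(centred, 0):
            warnings.warn(f"constant column {var}: polynomial terms are zero", stacklevel=2)
        out[var] = centred
        out[f"{var}2"] = centred**2
        out[f"{var}3"] = centred**3
    out["SIN"] = env["SIN"].to_numpy(float)
    out["COS"] = env["COS"].to_numpy(float)
    return pd.DataFrame(out, index=env.index)


def env_distance(env: pd.DataFrame | pd.Series, metric_label: str | None = None) -> DistMatrix:
    """Standardised Euclidean distance between sites.

    Each column is z-scored (mean 0, SD 1 with the n-1 denominator) before
    computing pairwise Euclidean distances; a single Series gives the
    per-variable distances used for driver-by-driver Mantel tests.
    Zero-variance columns are excluded with a warning.
    """
    if isinstance(env, pd.Series):
        env = env.to_frame(env.name or "var")
    env = env.drop(columns=["flat"], errors="ignore")
    if len(env) < 2:
        raise ConfigurationError("need at least two sites for a distance matrix")
    X = env.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(env.columns, keep) if not k]
        warnings.warn(f"zero-variance columns excluded from distance: {dropped}", stacklevel=2)
    if not keep.any():
        raise ComputationError("all environmental columns have zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    label = metric_label or "euclidean(z-scored:" + ",".join(map(str, env.columns[keep])) + ")"
    return DistMatrix(list(env.index), pdist(Z, metric="euclidean"), label)
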