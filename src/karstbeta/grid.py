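"""Plot geometry and the node-based elevation grid.

A forest-dynamics plot is a rectangle of ``x_extent`` x ``y_extent`` metres,
surveyed on a regular lattice of elevation nodes every ``resolution`` metres
(a 500 x 300 m plot at 10 m resolution has 51 x 31 nodes).  Coordinates are
metres from the south-west corner; x runs east, y runs north.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot extent with a base survey resolution (metres)."""

    x_extent: float = 500.0
    y_extent: float = 300.0
    base_resolution: float = 10.0

    def __post_init__(self) -> None:
        if self.x_extent <= 0 or self.y_extent <= 0 or self.base_resolution <= 0:
            raise ConfigurationError("extents and resolution must be positive")
        for name, ext in (("x_extent", self.x_extent), ("y_extent", self.y_extent)):
            if abs(ext / self.base_resolution - round(ext / self.base_resolution)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={ext} is not divisible by base_resolution={self.base_resolution}"
                )


@dataclass
class ElevationGrid:
    """Node elevations on a regular lattice.

    ``values[i, j]`` is the elevation (m) of the node at
    ``(i * resolution, j * resolution)``; shape is (nx + 1, ny + 1) for a
    plot of ``nx * resolution`` by ``ny * resolution`` metres.
    """

    values: np.ndarray
    resolution: float = 10.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ConfigurationError("elevation grid needs at least 2x2 nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("elevation grid contains non-finite values")

    @property
    def x_extent(self) -> float:
        return (self.values.shape[0] - 1) * self.resolution

    @property
    def y_extent(self) -> float:
        return (self.values.shape[1] - 1) * self.resolution

    def geometry(self) -> PlotGeometry:
        return PlotGeometry(self.x_extent, self.y_extent, self.resolution)

    def to_frame(self) -> pd.DataFrame:
        """Long-form (x, y, elev) table, one row per node."""
        nx, ny = self.values.shape
        xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame(
            {
                "x": xi.ravel() * self.resolution,
                "y": yi.ravel() * self.resolution,
                "elev": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution: float | None = None) -> "ElevationGrid":
        df = pd.read_csv(path)
        missing = {"x", "y", "elev"} - set(df.columns)
        if missing:
            raise FormatError(f"elevation CSV missing columns: {sorted(missing)}")
        xs = np.unique(df["x"].to_numpy(float))
        ys = np.unique(df["y"].to_numpy(float))
        if resolution is None:
            if len(xs) < 2:
                raise FormatError("cannot infer resolution from a single x value")
            resolution = float(np.diff(xs).min())
        nx, ny = len(xs), len(ys)
        if nx * ny != len(df):
            raise FormatError("elevation CSV is not a complete regular lattice")
        vals = np.full((nx, ny), np.nan)
        ix = np.searchsorted(xs, df["x"].to_numpy(float))
        iy = np.searchsorted(ys, df["y"].to_numpy(float))
        vals[ix, iy] = df["elev"].to_numpy(float)
        if np.isnan(vals).any():
            raise FormatError("elevation CSV has missing lattice nodes")
        return cls(vals, resolution)
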