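"""Virtual karst fengcong-depression plot generator.

Everything downstream of the raw census is deterministic, so this module is
the pipeline's only source of randomness.  It emulates a 15-ha (500 x 300 m)
gridded forest-census plot on clustered karst peaks around a central
depression: a smooth DEM built from Gaussian hills plus one negative bowl,
a species community whose expected abundance per 10-m cell mixes a
deterministic niche response to elevation and slope with a spatially
autocorrelated Gaussian random field (the "neutral" component), and a second
census linked to the first by elevation-dependent birth-death dynamics with
turnover concentrated in the depression.

All random draws descend from ``SyntheticConfig.seed`` through fixed
``numpy.random.SeedSequence`` spawn keys (one per operation), so each stage
is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .grid import ElevationGrid, PlotGeometry
from . import topography

# spawn keys of the per-operation random streams
_KEY_DEM = 0
_KEY_COMMUNITY = 1
_KEY_ADVANCE = 2
_KEY_RBR = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the virtual plot.

    ``niche_weight`` mixes the deterministic (niche) and stochastic (random
    field) parts of log expected abundance; ``neutral_range`` is the
    correlation length (m) of the random field, with values <= 0 meaning no
    neutral heterogeneity at all.  ``mortality_base``/``recruitment_base``
    are plot-wide per-census-interval fractions; ``turnover_elevation_bias``
    concentrates both in low-lying cells (0 disables the elevation effect).
    """

    seed: int = 0
    x_extent: float = 500.0
    y_extent: float = 300.0
    dem_resolution: float = 10.0
    n_peaks: int = 6
    relief: float = 190.0
    base_elevation: float = 180.0
    n_species: int = 220
    n_stems_target: int = 68000
    niche_weight: float = 0.6
    neutral_range: float = 40.0
    neutral_sd: float = 1.2
    niche_tolerance: float = 0.18
    species_abundance_sd: float = 1.0
    mortality_base: float = 0.144
    recruitment_base: float = 0.057
    turnover_elevation_bias: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.niche_weight <= 1.0:
            raise ConfigurationError("niche_weight must lie in [0, 1]")
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if self.relief < 0 or self.n_peaks < 0:
            raise ConfigurationError("relief and n_peaks must be non-negative")
        if not 0.0 <= self.mortality_base <= 1.0:
            raise ConfigurationError("mortality_base must lie in [0, 1]")
        if self.recruitment_base < 0:
            raise ConfigurationError("recruitment_base must be non-negative")
        self.geometry()  # validates divisibility of extents

    def geometry(self) -> PlotGeometry:
        return PlotGeometry(self.x_extent, self.y_extent, self.dem_resolution)

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def generate_dem(config: SyntheticConfig) -> ElevationGrid:
    """Fengcong-depression DEM: Gaussian hills + one bowl + smooth noise.

    The raw surface is rescaled affinely so the realised elevations span
    exactly ``[base_elevation, base_elevation + relief]`` (degenerate configs
    with zero relief give a flat grid).
    """
    geom = config.geometry()
    res = config.dem_resolution
    nx = int(round(config.x_extent / res)) + 1
    ny = int(round(config.y_extent / res)) + 1
    rng = config.rng(_KEY_DEM)
    X, Y = np.meshgrid(np.arange(nx) * res, np.arange(ny) * res, indexing="ij")
    z = np.zeros((nx, ny))
    diag = np.hypot(config.x_extent, config.y_extent)
    for _ in range(config.n_peaks):
        cx = rng.uniform(0, config.x_extent)
        cy = rng.uniform(0, config.y_extent)
        width = rng.uniform(0.08, 0.2) * diag
        amp = rng.uniform(0.5, 1.0)
        z += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2))
    # one central-ish depression: clustered peaks share a low common base
    cx = rng.uniform(0.3, 0.7) * config.x_extent
    cy = rng.uniform(0.3, 0.7) * config.y_extent
    width = rng.uniform(0.15, 0.3) * diag
    z -= 0.8 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * width**2))
    # low-frequency roughness
    noise = gaussian_filter(rng.standard_normal((nx, ny)), sigma=4.0, mode="reflect")
    if noise.std() > 0:
        z += 0.08 * noise / noise.std()
    zmin, zmax = z.min(), z.max()
    if config.relief <= 0 or zmax - zmin < 1e-12:
        values = np.full((nx, ny), config.base_elevation)
    else:
        values = config.base_elevation + (z - zmin) * (config.relief / (zmax - zmin))
    return ElevationGrid(values, res)


def _neutral_fields(
    rng: np.random.Generator, n_species: int, shape: tuple[int, int], config: SyntheticConfig
) -> np.ndarray:
    """Per-species Gaussian random fields (kernel-smoothed white noise).

    Standardised to mean 0 / SD ``neutral_sd`` across cells; a non-positive
    ``neutral_range`` returns zero fields (no neutral heterogeneity).
    """
    if config.neutral_range <= 0:
        return np.zeros((n_species,) + shape)
    sigma = config.neutral_range / config.dem_resolution
    white = rng.standard_normal((n_species,) + shape)
    smooth = gaussian_filter(white, sigma=(0, sigma, sigma), mode="wrap")
    sd = smooth.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    mean = smooth.mean(axis=(1, 2), keepdims=True)
    return (smooth - mean) / sd * config.neutral_sd


def generate_community(dem: ElevationGrid, config: SyntheticConfig) -> pd.DataFrame:
    """First census: niche x neutral Poisson community on the 10-m cell grid.

    Expected abundance of species s in cell c is
    ``exp(alpha_s + w * niche_s(ELE_c, SLO_c) + (1 - w) * GRF_s(c))``, scaled
    so the expected total equals ``n_stems_target``; counts are Poisson and
    stems are placed uniformly inside their cell.
    """
    geom = config.geometry()
    rng = config.rng(_KEY_COMMUNITY)
    res = config.dem_resolution
    ele = topography.cell_elevation(dem, geom, res)
    slo, _, _, _ = topography.cell_slope_aspect(dem, geom, res)
    ncx, ncy = ele.shape

    ele_lo, ele_hi = ele.min(), ele.max()
    ele_span = max(ele_hi - ele_lo, 1e-9)
    slo_lo, slo_hi = slo.min(), slo.max()
    slo_span = max(slo_hi - slo_lo, 1e-9)

    S = config.n_species
    alpha = rng.normal(0.0, config.species_abundance_sd, size=S)
    opt_ele = rng.uniform(ele_lo, ele_hi, size=S)
    opt_slo = rng.uniform(slo_lo, slo_hi, size=S)
    tol_ele = config.niche_tolerance * ele_span
    tol_slo = 2.0 * config.niche_tolerance * slo_span

    niche = -0.5 * (
        ((ele[None, :, :] - opt_ele[:, None, None]) / tol_ele) ** 2
        + 0.5 * ((slo[None, :, :] - opt_slo[:, None, None]) / tol_slo) ** 2
    )
    grf = _neutral_fields(rng, S, (ncx, ncy), config)
    w = config.niche_weight
    lam = np.exp(alpha[:, None, None] + w * niche + (1.0 - w) * grf)
    lam *= config.n_stems_target / lam.sum()

    counts = rng.poisson(lam)  # (S, ncx, ncy)
    sp_idx, cx, cy = np.nonzero(counts)
    reps = counts[sp_idx, cx, cy]
    sp_idx = np.repeat(sp_idx, reps)
    cx = np.repeat(cx, reps)
    cy = np.repeat(cy, reps)
    n = len(sp_idx)
    gx = (cx + rng.uniform(0, 1, size=n)) * res
    gy = (cy + rng.uniform(0, 1, size=n)) * res
    # uniform placement must stay strictly inside the half-open plot
    gx = np.minimum(gx, np.nextafter(config.x_extent, 0.0))
    gy = np.minimum(gy, np.nextafter(config.y_extent, 0.0))
    dbh = 1.0 + rng.lognormal(mean=0.7, sigma=0.8, size=n)

    width = len(str(max(n, 1)))
    df = pd.DataFrame(
        {
            "tag": [f"c1-{i:0{width}d}" for i in range(n)],
            "species": [f"sp{j:03d}" for j in sp_idx],
            "gx": gx,
            "gy": gy,
            "dbh": dbh,
            "census": 1,
        }
    )
    return df.sort_values("tag", ignore_index=True)


def _relative_cell_elevation(dem: ElevationGrid, config: SyntheticConfig) -> np.ndarray:
    geom = config.geometry()
    ele = topography.cell_elevation(dem, geom, config.dem_resolution)
    span = ele.max() - ele.min()
    if span < 1e-12:
        return np.full(ele.shape, 0.5)
    return (ele - ele.min()) / span


def advance_census(
    census1: pd.DataFrame, dem: ElevationGrid, config: SyntheticConfig
) -> pd.DataFrame:
    """Second census: elevation-biased deaths and recruitment.

    A stem in a cell with relative elevation e dies with probability
    ``1 - (1 - mortality_base)**g(e)`` where
    ``g(e) = exp(turnover_elevation_bias * (0.5 - e))``, so turnover
    concentrates in depressions while the plot-wide death fraction stays
    close to ``mortality_base``.  Recruits are Poisson per cell with
    expected total ``recruitment_base * n_stems``, allocated proportionally
    to ``N_cell * g(e)`` and drawing species from the cell's composition.
    Survivors keep their tag, coordinates, species and dbh.
    """
    rng = config.rng(_KEY_ADVANCE)
    res = config.dem_resolution
    e_rel = _relative_cell_elevation(dem, config)
    g = np.exp(config.turnover_elevation_bias * (0.5 - e_rel))

    cx = np.floor(census1["gx"].to_numpy(float) / res).astype(int)
    cy = np.floor(census1["gy"].to_numpy(float) / res).astype(int)
    p_death = 1.0 - (1.0 - config.mortality_base) ** g[cx, cy]
    dies = rng.uniform(size=len(census1)) < p_death
    survivors = census1.loc[~dies].copy()
    survivors["census"] = 2

    n1 = len(census1)
    recruits = []
    if config.recruitment_base > 0 and n1 > 0:
        cell_n = np.zeros(e_rel.shape)
        np.add.at(cell_n, (cx, cy), 1)
        weight = cell_n * g
        lam = config.recruitment_base * n1 * weight / weight.sum()
        counts = rng.poisson(lam)
        # cell composition of census 1, for drawing recruit species
        sp_codes = sorted(census1["species"].astype(str).unique())
        sp_pos = {s: i for i, s in enumerate(sp_codes)}
        comp = np.zeros(e_rel.shape + (len(sp_codes),))
        np.add.at(
            comp,
            (cx, cy, [sp_pos[s] for s in census1["species"].astype(str)]),
            1,
        )
        global_comp = comp.sum(axis=(0, 1))
        global_comp = global_comp / global_comp.sum()
        tag_no = 0
        for (ix, iy), k in np.ndenumerate(counts):
            if k == 0:
                continue
            local = comp[ix, iy]
            probs = local / local.sum() if local.sum() > 0 else global_comp
            sp_draw = rng.choice(len(sp_codes), size=k, p=probs)
            ux = (ix + rng.uniform(0, 1, size=k)) * res
            uy = (iy + rng.uniform(0, 1, size=k)) * res
            for j in range(k):
                recruits.append(
                    (
                        f"c2-{tag_no:06d}",
                        sp_codes[sp_draw[j]],
                        min(ux[j], np.nextafter(config.x_extent, 0.0)),
                        min(uy[j], np.nextafter(config.y_extent, 0.0)),
                        1.0 + rng.lognormal(mean=-0.5, sigma=0.4),
                        2,
                    )
                )
                tag_no += 1
    if recruits:
        rec_df = pd.DataFrame(
            recruits, columns=["tag", "species", "gx", "gy", "dbh", "census"]
        )
        out = pd.concat([survivors, rec_df], ignore_index=True)
    else:
        out = survivors
    return out.sort_values("tag", ignore_index=True)


def generate_rbr(dem: ElevationGrid, config: SyntheticConfig) -> np.ndarray:
    """Synthetic rock-bareness rate per 10-m cell (ncx, ncy), in [0, 1].

    A stand-in for the field survey: exposed rock increases with slope
    (logistic in SLO) plus seeded smooth noise.
    """
    geom = config.geometry()
    slo, _, _, _ = topography.cell_slope_aspect(dem, geom, config.dem_resolution)
    rng = config.rng(_KEY_RBR)
    noise = gaussian_filter(rng.standard_normal(slo.shape), sigma=2.0, mode="reflect")
    if noise.std() > 0:
        noise = noise / noise.std()
    logit = (slo - 30.0) / 8.0 + 0.8 * noise
    return 1.0 / (1.0 + np.exp(-logit))


def aggregate_rbr(
    rbr10: np.ndarray, geometry: PlotGeometry, grain: float
) -> np.ndarray:
    """Mean 10-m RBR over each grain-sized cell of the sub-extent (site order).

    Fine cells are assigned to the coarse cell containing their centre, which
    also handles grains that are not multiples of the base resolution (25 m).
    """
    from .census import sub_extent_for_grain

    res = geometry.base_resolution
    sub_x, sub_y = sub_extent_for_grain(geometry, grain)
    ncx, ncy = int(round(sub_x / grain)), int(round(sub_y / grain))
    nfx, nfy = rbr10.shape
    centers_x = (np.arange(nfx) + 0.5) * res
    centers_y = (np.arange(nfy) + 0.5) * res
    ix = np.floor(centers_x / grain).astype(int)
    iy = np.floor(centers_y / grain).astype(int)
    ok_x, ok_y = centers_x < sub_x, centers_y < sub_y
    total = np.zeros((ncx, ncy))
    count = np.zeros((ncx, ncy))
    np.add.at(total, (ix[ok_x][:, None], iy[ok_y][None, :]), rbr10[np.ix_(ok_x, ok_y)])
    np.add.at(count, (ix[ok_x][:, None], iy[ok_y][None, :]), 1.0)
    return (total / count).ravel(order="C")
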