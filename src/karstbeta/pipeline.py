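"""End-to-end orchestration: data -> grains -> partitioning -> Mantel battery
-> dbMEM -> variation partitioning -> report.

The report is a plain JSON/CSV bundle in which every number comes from a
stage output, and a fixed master seed makes the whole run byte-reproducible.
Per-stage random streams are derived from the master seed by hashing a stage
label (CRC-32 of e.g. ``"mantel/20/census1/bc/ELE"``) into a
``numpy.random.SeedSequence`` spawn key; each stage's derived seed is
recorded in the report so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta, dbmem, matrix_stats, synthetic, topography, varpart as vp
from .census import aggregate, census_dynamics, read_census, sub_extent_for_grain
from .distmat import DistMatrix
from .errors import ConfigurationError, KarstBetaError
from .grid import ElevationGrid, PlotGeometry
from .synthetic import SyntheticConfig

log = logging.getLogger("karstbeta")

DEFAULT_GRAINS = (10, 20, 25, 30, 40, 50, 60)

#: environmental drivers tested one at a time in the Mantel battery
MANTEL_DRIVERS = ("ELE", "SLO", "CON", "TWI", "ACH", "RBR", "SIN", "COS")


def child_seed(master: int, label: str) -> int:
    """Deterministic per-stage seed: CRC-32 of the label spawns a child stream."""
    ss = np.random.SeedSequence(master, spawn_key=(zlib.crc32(label.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic mode or user-data mode)."""

    seed: int = 0
    outdir: str = "karstbeta_out"
    synthetic: SyntheticConfig | None = None
    census1_path: str | None = None
    census2_path: str | None = None
    dem_path: str | None = None
    env_overrides_path: str | None = None  # per-site TWI/ACH/RBR columns, optional
    grains: tuple = DEFAULT_GRAINS
    mantel_grains: tuple | None = None  # default: all grains
    varpart_grains: tuple | None = None
    n_perm_mantel: int = 9999
    n_perm_forward: int = 9999
    alpha: float = 0.05
    mantel_alternative: str = "greater"
    channel_threshold: int | None = None  # None: max(3, n_cells // 25) per grain
    write_pair_tables: bool = False

    def __post_init__(self) -> None:
        if self.n_perm_mantel < 99 or self.n_perm_forward < 99:
            raise ConfigurationError("permutation counts must be >= 99")
        self.grains = tuple(float(g) for g in self.grains)
        if self.synthetic is None and self.census1_path is None:
            self.synthetic = SyntheticConfig(seed=child_seed(self.seed, "synthetic"))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        syn = data.pop("synthetic", None)
        cfg = cls(**data)
        if syn is not None:
            syn.setdefault("seed", child_seed(cfg.seed, "synthetic"))
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _stage(label: str):
    t0 = time.perf_counter()
    log.info("stage=%s status=start", label)
    return t0


def _stage_done(label: str, t0: float) -> None:
    log.info("stage=%s status=done wall=%.2fs", label, time.perf_counter() - t0)


def _load_data(config: PipelineConfig, outdir: Path):
    """Returns (geometry, dem, census1, census2, rbr10 or None)."""
    if config.census1_path is not None:
        if config.dem_path is None:
            raise ConfigurationError("user-data mode requires dem_path")
        dem = ElevationGrid.from_csv(config.dem_path)
        geometry = dem.geometry()
        c1 = read_census(config.census1_path, geometry)
        c2 = (
            read_census(config.census2_path, geometry)
            if config.census2_path
            else None
        )
        return geometry, dem, c1, c2, None
    syn = config.synthetic
    geometry = syn.geometry()
    dem = synthetic.generate_dem(syn)
    c1 = synthetic.generate_community(dem, syn)
    c2 = synthetic.advance_census(c1, dem, syn)
    rbr10 = synthetic.generate_rbr(dem, syn)
    dem.to_csv(outdir / "dem.csv")
    c1.to_csv(outdir / "census1.csv", index=False)
    c2.to_csv(outdir / "census2.csv", index=False)
    return geometry, dem, c1, c2, rbr10


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pre_geometry = (
        config.synthetic.geometry() if config.synthetic else _peek_geometry(config)
    )
    for grain in config.grains:  # validate every grain before any computation
        sub_extent_for_grain(pre_geometry, grain)

    report: dict = {
        "config": _config_dict(config),
        "seeds": {},
        "grains": {},
    }

    t0 = _stage("data")
    geometry, dem, c1, c2, rbr10 = _load_data(config, outdir)
    censuses = {"census1": c1}
    if c2 is not None:
        censuses["census2"] = c2
    report["data"] = {
        name: {
            "n_stems": int(len(c)),
            "n_species": int(c["species"].nunique()),
        }
        for name, c in censuses.items()
    }
    _stage_done("data", t0)

    if c2 is not None:
        t0 = _stage("dynamics")
        dyn_grain = 20.0 if 20.0 in config.grains else config.grains[0]
        dyn = census_dynamics(c1, c2, geometry, dyn_grain)
        report["dynamics"] = {
            "grain": dyn_grain,
            "n_dead": dyn.n_dead,
            "n_new": dyn.n_new,
            "n_species_with_deaths": int((dyn.species_dead > 0).sum()),
            "n_species_with_recruits": int((dyn.species_new > 0).sum()),
            "species_lost": sorted(dyn.species_lost),
            "species_gained": sorted(dyn.species_gained),
        }
        pd.DataFrame(
            {"dead": dyn.species_dead, "new": dyn.species_new}
        ).fillna(0).astype(int).to_csv(outdir / "dynamics_species.csv")
        _stage_done("dynamics", t0)

    mantel_grains = set(config.mantel_grains or config.grains)
    varpart_grains = set(config.varpart_grains or config.grains)
    species_union = sorted(
        set().union(*(set(c["species"].astype(str)) for c in censuses.values()))
    )

    simplex_rows = []
    mantel_rows = []
    varpart_rows = []
    for grain in config.grains:
        glabel = f"{grain:g}"
        t0 = _stage(f"grain/{glabel}")
        sub_extent = sub_extent_for_grain(geometry, grain)
        abunds = {
            name: aggregate(c, geometry, grain, species=species_union)
            for name, c in censuses.items()
        }
        n_sites = next(iter(abunds.values())).n_sites

        # sites empty in any census are excluded from all matrix analyses
        active = np.ones(n_sites, dtype=bool)
        for ab in abunds.values():
            active &= ab.values().sum(axis=1) > 0

        greport: dict = {
            "sub_extent": list(sub_extent),
            "n_sites": n_sites,
            "n_active_sites": int(active.sum()),
            "n_pairs": int(active.sum() * (active.sum() - 1) // 2),
        }

        components: dict[str, dict[str, DistMatrix]] = {}
        for name, ab in abunds.items():
            comp = beta.decompose(ab.counts.loc[active])
            summary = beta.simplex_summary(comp)
            greport[name] = {
                "beta_mean": {
                    "bc": 1.0 - summary.mean[0],
                    "bal": summary.mean[1],
                    "gra": summary.mean[2],
                },
                "beta_sd": {
                    "bc": summary.sd[0],
                    "bal": summary.sd[1],
                    "gra": summary.sd[2],
                },
                "n_defined_pairs": summary.n_pairs,
            }
            simplex_rows.append(
                {
                    "grain": grain,
                    "census": name,
                    **{f"mean_{k}": v for k, v in greport[name]["beta_mean"].items()},
                    **{f"sd_{k}": v for k, v in greport[name]["beta_sd"].items()},
                }
            )
            components[name] = {k: comp.matrix(k) for k in ("bc", "bal", "gra")}
            if config.write_pair_tables:
                comp.to_frame().to_csv(
                    outdir / f"beta_pairs_grain{glabel}_{name}.csv", index=False
                )

        # environment at this grain
        n_cells_grain = n_sites
        thr = config.channel_threshold or max(3, n_cells_grain // 25)
        rbr = (
            synthetic.aggregate_rbr(rbr10, geometry, grain) if rbr10 is not None else None
        )
        env = topography.env_table(dem, geometry, grain, channel_threshold=thr, rbr=rbr)
        env_active = env.loc[active]
        env_active.to_csv(outdir / f"env_grain{glabel}.csv")

        if grain in mantel_grains:
            t1 = _stage(f"mantel/{glabel}")
            dist_all = topography.env_distance(
                env_active[list(MANTEL_DRIVERS)], metric_label="ALL"
            )
            driver_dists = {"ALL": dist_all}
            for drv in MANTEL_DRIVERS:
                try:
                    driver_dists[drv] = topography.env_distance(env_active[drv])
                except KarstBetaError:
                    continue  # constant driver at this grain
            mantel_report = {}
            for name in censuses:
                mantel_report[name] = {}
                for comp_name in ("bc", "bal", "gra"):
                    row = {}
                    for drv, dmat in driver_dists.items():
                        label = f"mantel/{glabel}/{name}/{comp_name}/{drv}"
                        seed = child_seed(config.seed, label)
                        report["seeds"][label] = seed
                        res = matrix_stats.mantel(
                            dmat,
                            components[name][comp_name],
                            n_perm=config.n_perm_mantel,
                            alternative=config.mantel_alternative,
                            seed=seed,
                        )
                        row[drv] = {"r": res.r, "p": res.p}
                        mantel_rows.append(
                            {
                                "grain": grain,
                                "census": name,
                                "component": comp_name,
                                "driver": drv,
                                "r": res.r,
                                "p": res.p,
                                "n_perm": res.n_perm,
                            }
                        )
                    mantel_report[name][comp_name] = row
            greport["mantel"] = mantel_report
            _stage_done(f"mantel/{glabel}", t1)

        if grain in varpart_grains:
            t1 = _stage(f"varpart/{glabel}")
            ids_all, coords_all = dbmem.cell_centroids(geometry, grain)
            coords = coords_all[active]
            basis = dbmem.select_mem(dbmem.build_dbmem(coords))
            mem_df = pd.DataFrame(
                basis.vectors,
                index=env_active.index,
                columns=[f"MEM{k + 1}" for k in range(basis.vectors.shape[1])],
            )
            env_poly = topography.polynomial_expand(env_active)
            greport["dbmem"] = {
                "truncation": basis.truncation,
                "n_retained": int(basis.vectors.shape[1]),
            }
            vreport = {}
            for name in censuses:
                vreport[name] = {}
                for comp_name in ("bc", "bal", "gra"):
                    label = f"varpart/{glabel}/{name}/{comp_name}"
                    seed = child_seed(config.seed, label)
                    report["seeds"][label] = seed
                    Y = vp.pcoa_response(
                        vp.sqrt_transform(components[name][comp_name])
                    )
                    # each set may use at most half the model df, so the
                    # combined E+S model stays estimable at coarse grains
                    cap = max(1, (Y.n - 2) // 2)
                    sel_env = vp.forward_select(
                        Y, env_poly, config.n_perm_forward, config.alpha, seed,
                        max_select=cap,
                    )
                    sel_mem = vp.forward_select(
                        Y, mem_df, config.n_perm_forward, config.alpha, seed + 1,
                        max_select=cap,
                    )
                    fr = vp.varpart(
                        Y,
                        env_poly[sel_env.selected] if sel_env.selected else None,
                        mem_df[sel_mem.selected] if sel_mem.selected else None,
                    )
                    vreport[name][comp_name] = {
                        "a": fr.a,
                        "b": fr.b,
                        "c": fr.c,
                        "d": fr.d,
                        "a_plus_b": fr.a + fr.b,
                        "m_env": fr.m_env,
                        "m_space": fr.m_space,
                        "selected_env": sel_env.selected,
                        "selected_mem": sel_mem.selected,
                    }
                    varpart_rows.append(
                        {
                            "grain": grain,
                            "census": name,
                            "component": comp_name,
                            **{k: vreport[name][comp_name][k] for k in "abcd"},
                            "m_env": fr.m_env,
                            "m_space": fr.m_space,
                        }
                    )
            greport["varpart"] = vreport
            _stage_done(f"varpart/{glabel}", t1)

        report["grains"][glabel] = greport
        _stage_done(f"grain/{glabel}", t0)

    if len(config.grains) >= 3:
        t0 = _stage("grain_trend")
        trend = {}
        for name in censuses:
            trend[name] = {}
            for comp_name in ("bc", "bal", "gra"):
                means = [
                    report["grains"][f"{g:g}"][name]["beta_mean"][comp_name]
                    for g in config.grains
                ]
                try:
                    res = matrix_stats.grain_trend(config.grains, means)
                    trend[name][comp_name] = {
                        "rho": res.rho,
                        "p": res.p,
                        "exact": res.exact,
                    }
                except KarstBetaError as exc:
                    trend[name][comp_name] = {"error": str(exc)}
        report["grain_trend"] = trend
        _stage_done("grain_trend", t0)

    pd.DataFrame(simplex_rows).to_csv(outdir / "beta_summary.csv", index=False)
    if mantel_rows:
        pd.DataFrame(mantel_rows).to_csv(outdir / "mantel.csv", index=False)
    if varpart_rows:
        pd.DataFrame(varpart_rows).to_csv(outdir / "varpart.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _peek_geometry(config: PipelineConfig) -> PlotGeometry:
    dem = ElevationGrid.from_csv(config.dem_path)
    return dem.geometry()


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    # the report describes the analysis, not where it lives: dropping the
    # output path keeps identical-seed runs byte-identical
    d.pop("outdir", None)
    return d


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
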