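"""Synthetic plot generator: determinism, degenerate configs, statistical
structure of the community and the birth-death census transition."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from karstbeta import (
    SyntheticConfig,
    advance_census,
    aggregate,
    decompose,
    env_distance,
    generate_community,
    generate_dem,
    mantel,
)
from karstbeta.errors import ConfigurationError
from karstbeta.topography import cell_elevation


class TestConfig:
    def test_niche_weight_bounds(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(seed=0, niche_weight=1.5)

    def test_non_divisible_extent(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(seed=0, x_extent=205.0)


class TestGenerateDem:
    def test_seed_determinism(self, small_config):
        a = generate_dem(small_config)
        b = generate_dem(small_config)
        assert (a.values == b.values).all()

    def test_flat_degenerate(self):
        cfg = SyntheticConfig(seed=1, x_extent=100, y_extent=100, n_peaks=0, relief=0.0)
        dem = generate_dem(cfg)
        assert (dem.values == dem.values.flat[0]).all()

    def test_default_realised_range(self):
        """Regression fixture: the default-config DEM spans its configured relief."""
        dem = generate_dem(SyntheticConfig(seed=1))
        assert dem.values.shape == (51, 31)
        assert dem.values.min() == pytest.approx(180.0)
        assert dem.values.max() == pytest.approx(370.0)
        # multiple peaks and at least one interior depression survive rescaling
        interior = dem.values[1:-1, 1:-1]
        lowest = np.unravel_index(np.argmin(interior), interior.shape)
        assert 0 <= lowest[0] < interior.shape[0]


class TestGenerateCommunity:
    def test_canonical_sort_determinism(self, small_config, small_dem):
        a = generate_community(small_dem, small_config)
        b = generate_community(small_dem, small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_total_stems_near_target(self, small_config, small_census):
        assert abs(len(small_census) - small_config.n_stems_target) <= 0.1 * small_config.n_stems_target

    def test_poisson_dispersion_without_structure(self):
        """w=0 and no neutral heterogeneity: counts are plain Poisson, so the
        across-cell variance/mean ratio of a species' counts is ~1."""
        cfg = SyntheticConfig(
            seed=5, x_extent=1000, y_extent=100, n_species=5,
            n_stems_target=20000, niche_weight=0.0, neutral_range=0.0,
            species_abundance_sd=0.0,
        )
        dem = generate_dem(cfg)
        census = generate_community(dem, cfg)
        ab = aggregate(census, cfg.geometry(), 10)  # 1000 cells
        counts = ab.counts.to_numpy()
        ratios = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        assert np.all(np.abs(ratios - 1.0) < 0.2)

    def test_pure_niche_species_track_elevation(self):
        """w=1: a species whose optimum sits at the elevation maximum has
        counts positively rank-correlated with cell elevation."""
        cfg = SyntheticConfig(
            seed=9, x_extent=300, y_extent=200, n_species=30,
            n_stems_target=20000, niche_weight=1.0,
        )
        dem = generate_dem(cfg)
        census = generate_community(dem, cfg)
        ab = aggregate(census, cfg.geometry(), 10)
        ele = cell_elevation(dem, cfg.geometry(), 10).ravel(order="C")
        # species optima are seeded identically to the generator's stream
        rng = cfg.rng(1)
        rng.normal(0.0, cfg.species_abundance_sd, size=cfg.n_species)
        opt_ele = rng.uniform(ele.min(), ele.max(), size=cfg.n_species)
        high_sp = ab.counts.columns[int(np.argmax(opt_ele))]
        rho = spearmanr(ab.counts[high_sp].to_numpy(), ele).statistic
        assert rho > 0

    def test_single_species_limit(self):
        cfg = SyntheticConfig(
            seed=3, x_extent=100, y_extent=100, n_species=2, n_stems_target=2000
        )
        dem = generate_dem(cfg)
        census = generate_community(dem, cfg)
        one = census[census["species"] == census["species"].iloc[0]]
        comp = decompose(aggregate(one, cfg.geometry(), 50).counts)
        defined = ~np.isnan(comp.bal)
        assert np.allclose(comp.bal[defined], 0.0)


class TestAdvanceCensus:
    def test_identity_without_turnover(self, small_config, small_dem, small_census):
        cfg = replace(small_config, mortality_base=0.0, recruitment_base=0.0)
        c2 = advance_census(small_census, small_dem, cfg)
        pd.testing.assert_frame_equal(
            c2.drop(columns="census"), small_census.drop(columns="census")
        )

    def test_total_mortality_empties_plot(self, small_config, small_dem, small_census):
        cfg = replace(small_config, mortality_base=1.0, recruitment_base=0.0)
        assert len(advance_census(small_census, small_dem, cfg)) == 0

    def test_death_fraction_within_binomial_bound(self, small_config, small_dem, small_census):
        cfg = replace(
            small_config, mortality_base=0.15, recruitment_base=0.0,
            turnover_elevation_bias=0.0,
        )
        c2 = advance_census(small_census, small_dem, cfg)
        n = len(small_census)
        dead = n - len(c2)
        sd = np.sqrt(n * 0.15 * 0.85)
        assert abs(dead - 0.15 * n) <= 3 * sd

    def test_stem_conservation(self, small_config, small_dem, small_census):
        c2 = advance_census(small_census, small_dem, small_config)
        assert not c2["tag"].duplicated().any()
        survivors = c2[c2["tag"].isin(set(small_census["tag"]))]
        merged = survivors.merge(small_census, on="tag", suffixes=("_2", "_1"))
        assert (merged["gx_2"] == merged["gx_1"]).all()
        assert (merged["species_2"] == merged["species_1"]).all()
        new = c2[~c2["tag"].isin(set(small_census["tag"]))]
        assert new["tag"].str.startswith("c2-").all()


class TestNicheSignalRecovery:
    def test_mantel_detects_niche_structure(self):
        """Pure niche assembly (w=1) leaves a Mantel-detectable environment
        signal in beta diversity in >= 95% of replicates; pure short-range
        noise (w=0) does not produce systematically positive r."""
        n_rep = 20
        significant = 0
        null_rs = []
        for k in range(n_rep):
            for w, collect in ((1.0, True), (0.0, False)):
                cfg = SyntheticConfig(
                    seed=1000 + k, x_extent=200, y_extent=100, n_species=30,
                    n_stems_target=5000, niche_weight=w, neutral_range=10.0,
                )
                dem = generate_dem(cfg)
                census = generate_community(dem, cfg)
                ab = aggregate(census, cfg.geometry(), 20)
                comp = decompose(ab)
                ele = cell_elevation(dem, cfg.geometry(), 20).ravel(order="C")
                denv = env_distance(pd.Series(ele, index=ab.counts.index, name="ELE"))
                res = mantel(denv, comp.matrix("bc"), n_perm=199, seed=k)
                if collect:
                    significant += res.p <= 0.05
                else:
                    null_rs.append(res.r)
        assert significant >= int(0.95 * n_rep)
        assert abs(np.mean(null_rs)) < 0.15
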