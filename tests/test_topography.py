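"""Topographic variables: analytic planes, hand-traceable D8 flow, the
20-column polynomial contract and standardized environmental distances."""

import numpy as np
import pandas as pd
import pytest

from karstbeta import ElevationGrid, PlotGeometry, env_distance, polynomial_expand, topo_variables, twi_ach
from karstbeta.errors import ComputationError
from karstbeta.topography import cell_elevation, convexity, d8_flow


def plane_dem(nx=11, ny=7, res=10.0, fx=0.0, fy=0.0, offset=0.0):
    X, Y = np.meshgrid(np.arange(nx) * res, np.arange(ny) * res, indexing="ij")
    return ElevationGrid(offset + fx * X + fy * Y, res)


@pytest.fixture()
def flat_geometry():
    return PlotGeometry(100.0, 60.0, 10.0)


class TestTopoVariables:
    def test_flat_dem(self, flat_geometry):
        env = topo_variables(plane_dem(offset=5.0), flat_geometry, 10)
        assert np.allclose(env["SLO"], 0.0)
        assert np.allclose(env["CON"], 0.0)
        assert env["flat"].all()
        assert np.allclose(env["SIN"], 0.0) and np.allclose(env["COS"], 0.0)

    @pytest.mark.parametrize("grain", [10, 20])
    def test_unit_east_plane(self, flat_geometry, grain):
        """z = x rises 1 m per metre east: slope 45 deg, aspect due east."""
        env = topo_variables(plane_dem(fx=1.0), flat_geometry, grain)
        assert np.allclose(env["SLO"], 45.0, atol=1e-9)
        assert np.allclose(env["SIN"], 1.0, atol=1e-12)
        assert np.allclose(env["COS"], 0.0, atol=1e-12)

    def test_north_plane_aspect(self, flat_geometry):
        env = topo_variables(plane_dem(fy=0.5), flat_geometry, 10)
        assert np.allclose(env["SIN"], 0.0, atol=1e-12)
        assert np.allclose(env["COS"], 1.0, atol=1e-12)

    def test_raised_cell_convexity(self):
        """One raised interior cell: its CON is +1, cardinal neighbours -1/8."""
        ele = np.zeros((7, 7))
        ele[3, 3] = 1.0
        centres = np.zeros((7, 7))  # flat plain centres for border cells
        con = convexity(ele, centres)
        assert con[3, 3] == pytest.approx(1.0)
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            assert con[3 + dx, 3 + dy] == pytest.approx(-1 / 8)

    def test_ele_aggregates_consistently(self, flat_geometry):
        """Grain-20 ELE equals the mean of its four grain-10 cell ELEs.

        With corner-mean ELE this identity is exact for (piecewise) planar
        surfaces; on rough terrain the corner-based coarse ELE deliberately
        re-reads the node grid instead of averaging fine-cell values.
        """
        dem = plane_dem(fx=0.8, fy=-0.3, offset=200.0)
        geom = flat_geometry
        e10 = cell_elevation(dem, geom, 10)
        e20 = cell_elevation(dem, geom, 20)
        coarse_from_fine = (
            e10[0::2, 0::2] + e10[1::2, 0::2] + e10[0::2, 1::2] + e10[1::2, 1::2]
        ) / 4.0
        np.testing.assert_allclose(e20, coarse_from_fine, atol=1e-9)

    def test_rotation_permutes_aspect(self, small_dem, small_config):
        """Transposing the DEM swaps east and north: SIN and COS exchange,
        SLO and CON are unchanged up to the same site permutation."""
        geom = small_config.geometry()
        env = topo_variables(small_dem, geom, 10)
        demT = ElevationGrid(small_dem.values.T, small_dem.resolution)
        geomT = PlotGeometry(geom.y_extent, geom.x_extent, geom.base_resolution)
        envT = topo_variables(demT, geomT, 10)
        # site (ix, iy) of the original maps to (iy, ix) of the transpose
        perm = envT.loc[[(iy, ix) for ix, iy in env.index]]
        np.testing.assert_allclose(env["SLO"].to_numpy(), perm["SLO"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(env["CON"].to_numpy(), perm["CON"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(env["SIN"].to_numpy(), perm["COS"].to_numpy(), atol=1e-9)
        np.testing.assert_allclose(env["COS"].to_numpy(), perm["SIN"].to_numpy(), atol=1e-9)


class TestD8:
    def test_inclined_plane_drains_west(self):
        """On z = x every cell drains due west; accumulation grows eastward
        to the column length on the downslope (west) edge."""
        ele = np.arange(5)[:, None] * np.ones((1, 5)) * 10.0
        receiver, acc = d8_flow(ele, 10.0)
        assert (receiver[1:, :] == (np.arange(4)[:, None] * 5 + np.arange(5))).all()
        assert (acc[0, :] == 5).all()  # west edge collects its whole row
        assert (acc[-1, :] == 1).all()

    def test_bowl_minimum_collects_everything(self):
        x, y = np.meshgrid(np.arange(5) - 2, np.arange(5) - 2, indexing="ij")
        ele = (x**2 + y**2).astype(float)
        _, acc = d8_flow(ele, 10.0)
        assert acc[2, 2] == acc.max() == 25

    def test_channel_cell_has_zero_ach(self, flat_geometry):
        cols = twi_ach(plane_dem(fx=1.0), flat_geometry, 10, channel_threshold=5)
        ach = cols["ACH"].to_numpy().reshape(10, 6)
        # on z=x the west column accumulates 10 cells and is the channel
        assert np.allclose(ach[0, :], 0.0)
        assert (ach[-1, :] > 0).all()

    def test_no_channel_raises(self, flat_geometry):
        with pytest.raises(ComputationError, match="channel_threshold"):
            twi_ach(plane_dem(fx=1.0), flat_geometry, 10, channel_threshold=1000)


class TestPolynomialExpand:
    @pytest.fixture()
    def env(self, rng):
        n = 12
        df = pd.DataFrame(
            {
                "ELE": rng.uniform(180, 370, n),
                "SLO": rng.uniform(0, 60, n),
                "CON": rng.normal(0, 2, n),
                "TWI": rng.uniform(2, 9, n),
                "ACH": rng.uniform(0, 50, n),
                "RBR": rng.uniform(0, 1, n),
                "SIN": rng.uniform(-1, 1, n),
                "COS": rng.uniform(-1, 1, n),
            }
        )
        return df

    def test_twenty_columns_in_documented_order(self, env):
        X = polynomial_expand(env)
        assert X.shape[1] == 20
        assert list(X.columns[:6]) == ["ELE", "ELE2", "ELE3", "SLO", "SLO2", "SLO3"]
        assert list(X.columns[-2:]) == ["SIN", "COS"]

    def test_centred_powers(self):
        env = pd.DataFrame(
            {
                "ELE": [-1.0, 0.0, 1.0],
                **{v: [0.0, 0.0, 0.0] for v in ("SLO", "CON", "TWI", "ACH", "RBR", "SIN", "COS")},
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            X = polynomial_expand(env)
        np.testing.assert_allclose(X["ELE3"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(X["SLO2"], 0.0)

    def test_column_means_zero_for_linear_terms(self, env):
        X = polynomial_expand(env)
        for v in ("ELE", "SLO", "CON", "TWI", "ACH", "RBR"):
            assert X[v].mean() == pytest.approx(0.0, abs=1e-9)


class TestEnvDistance:
    def test_identical_sites(self):
        env = pd.DataFrame({"ELE": [5.0, 5.0, 7.0]})
        d = env_distance(env)
        assert d.square()[0, 1] == 0.0

    def test_single_variable_hand_computed(self):
        d = env_distance(pd.DataFrame({"ELE": [0.0, 1.0]}))
        assert d.condensed[0] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_two_variables_hand_computed(self):
        d = env_distance(pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]}))
        assert d.condensed[0] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_column_dropped(self):
        env = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            d = env_distance(env)
        assert "b" not in d.metric

    def test_triangle_inequality(self, rng):
        env = pd.DataFrame(rng.normal(size=(15, 4)))
        sq = env_distance(env).square()
        for _ in range(200):
            i, j, k = rng.choice(15, 3, replace=False)
            assert sq[i, j] <= sq[i, k] + sq[k, j] + 1e-9
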