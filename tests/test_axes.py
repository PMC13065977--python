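"""Parameter axes: grid simulation, polynomial contour fits, stability
interpolation, and the mechanistic closed loop."""

from dataclasses import replace

import numpy as np
import pytest

from gastrumap.axes import (
    ParameterGrid,
    closed_loop_predict,
    contour_angle_stats,
    fit_axes,
    infer_sox2_stability,
    simulate_grid,
)
from gastrumap.embedding import TrainConfig, train_embedding
from gastrumap.fates import simulated_phenotype
from gastrumap.pde import ModelParams, simulate
from gastrumap.records import PhenotypeVector

FAST = ModelParams(T=24.0, grid_n=61, dt_snapshot=1.0)


@pytest.fixture(scope="module")
def small_grid_net():
    """3x3 simulated grid projected through a net trained on the grid's own
    2-D principal components."""
    from sklearn.decomposition import PCA

    densities = [750.0, 950.0, 1150.0]
    stabilities = [0.7, 1.0, 1.3]
    phen = {}
    for d in densities:
        res = simulate(replace(FAST, d=d))
        for cs in stabilities:
            p = replace(FAST, d=d, C_s=cs)
            phen[(d, cs)] = simulated_phenotype(res, p).vector
    X = np.stack([phen[(d, cs)].values for d in densities for cs in stabilities])
    coords = PCA(n_components=2, random_state=0).fit_transform(X) * 10
    net = train_embedding(
        np.repeat(X, 4, axis=0), np.repeat(coords, 4, axis=0),
        TrainConfig(seed=0, max_epochs=600, patience=100),
    )
    grid = simulate_grid(densities, stabilities, FAST, net)
    return grid, net


def _fake_linear_grid():
    """Projections on a perfect affine lattice (no simulation)."""
    densities = np.array([1.0, 2.0, 3.0])
    stabilities = np.array([10.0, 20.0, 30.0])
    phen, proj = {}, {}
    rng = np.random.default_rng(0)
    for i, d in enumerate(densities):
        for j, cs in enumerate(stabilities):
            key = (float(d), float(cs))
            phen[key] = PhenotypeVector(rng.random(150))
            proj[key] = np.array([float(i), float(j)])
    return ParameterGrid(densities=densities, stabilities=stabilities,
                         phenotypes=phen, projections=proj)


class TestFitAxes:
    def test_linear_grid_residual_zero(self):
        axes = fit_axes(_fake_linear_grid(), degree=1)
        assert axes.mean_contour_residual() == pytest.approx(0.0, abs=1e-9)

    def test_nodes_recover_parameters_exactly(self):
        grid = _fake_linear_grid()
        axes = fit_axes(grid, degree=1)
        for (d, cs), p in grid.projections.items():
            dd, ss = axes.interpolate_params(p)
            assert dd == pytest.approx(d, abs=1e-6)
            assert ss == pytest.approx(cs, abs=1e-6)

    def test_stability_midpoint_interpolates(self):
        axes = fit_axes(_fake_linear_grid(), degree=1)
        # halfway between the cs=10 and cs=20 contours
        mid = np.array([1.0, 0.5])
        assert infer_sox2_stability(axes, mid) == pytest.approx(15.0, abs=0.5)

    def test_node_stability_identity(self):
        grid = _fake_linear_grid()
        axes = fit_axes(grid, degree=1)
        assert infer_sox2_stability(axes, grid.projections[(2.0, 20.0)]) == pytest.approx(20.0)

    def test_far_point_warns(self):
        axes = fit_axes(_fake_linear_grid(), degree=1)
        with pytest.warns(UserWarning, match="extrapolat"):
            infer_sox2_stability(axes, np.array([100.0, 100.0]))

    def test_orthogonal_lattice_angles(self):
        axes = fit_axes(_fake_linear_grid(), degree=1)
        assert contour_angle_stats(axes) > 80.0  # near-perpendicular lattice


class TestSimulateGrid:
    def test_single_cell_equals_direct_composition(self, small_grid_net):
        _, net = small_grid_net
        grid = simulate_grid([950.0], [1.0], FAST, net)
        direct = simulated_phenotype(simulate(replace(FAST, d=950.0, C_s=1.0))).vector
        np.testing.assert_allclose(
            grid.phenotypes[(950.0, 1.0)].values, direct.values, atol=1e-12
        )

    def test_sox2_monotone_along_stability_rows(self, small_grid_net):
        grid, _ = small_grid_net
        for d in grid.densities:
            profs = [grid.phenotypes[(float(d), float(cs))].marker_profile("sox2")
                     for cs in grid.stabilities]
            for lo, hi in zip(profs[:-1], profs[1:]):
                assert np.all(hi >= lo - 1e-12)

    def test_bra_auc_decreasing_in_density(self, small_grid_net):
        grid, _ = small_grid_net
        cs = float(grid.stabilities[1])
        aucs = [grid.phenotypes[(float(d), cs)].marker_profile("bra").sum()
                for d in grid.densities]
        assert aucs[0] > aucs[1] > aucs[2]


class TestClosedLoop:
    def test_grid_node_round_trip(self, small_grid_net):
        grid, net = small_grid_net
        axes = fit_axes(grid)
        node = (950.0, 1.0)
        out = closed_loop_predict(axes, grid.projections[node], 950.0, FAST, net)
        assert out["inferred_C_s"] == pytest.approx(1.0, rel=0.05)
        np.testing.assert_allclose(
            out["phenotype"].values, grid.phenotypes[node].values, atol=0.05
        )
        coord_scale = np.ptp([p for p in grid.projections.values()])
        assert out["distance_to_centroid"] < 0.1 * coord_scale

    def test_out_of_range_density_warns(self, small_grid_net):
        grid, net = small_grid_net
        axes = fit_axes(grid)
        with pytest.warns(UserWarning, match="extrapolat"):
            out = closed_loop_predict(axes, grid.projections[(950.0, 1.0)], 2000.0,
                                      FAST, net)
        assert "phenotype" in out

    def test_nonpositive_density_rejected(self, small_grid_net):
        grid, net = small_grid_net
        axes = fit_axes(grid)
        with pytest.raises(ValueError):
            closed_loop_predict(axes, np.zeros(2), -5.0, FAST, net)
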