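"""Fate decoding: integral oracles, SOX2 rule, canonical spatial ordering,
and density effects on mesoderm."""

from dataclasses import replace

import numpy as np
import pytest

from gastrumap.fates import decode_bra, decode_gata3, decode_sox2, simulated_phenotype
from gastrumap.pde import ModelParams, SimulationResult, r_loc


def _manual_result(times, b=None, u=None, v=None, params=None, n=21):
    """Assemble a SimulationResult with hand-specified field histories."""
    p = params or ModelParams(grid_n=n)
    ax = np.linspace(-p.r_rad, p.r_rad, n)
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y)
    mask = r <= p.r_rad
    times = np.asarray(times, float)
    zeros = np.zeros((times.size, n, n))
    return SimulationResult(
        times=times,
        b=b if b is not None else zeros.copy(),
        u=u if u is not None else zeros.copy(),
        v=v if v is not None else zeros.copy(),
        mask=mask,
        r=r,
        params=p,
    )


class TestGata3:
    def test_constant_bmp_pixel_at_rloc_and_far_outside(self):
        # shallow sigmoid: the pixel nearest r_loc sees denominator ~ 2
        p = ModelParams(grid_n=81, T=48.0, k_1=0.02)
        times = np.linspace(0, p.T, 25)
        b = np.ones((times.size, 81, 81))
        res = _manual_result(times, b=b, params=p, n=81)
        gmap = decode_gata3(res, p)
        rl = r_loc(p)
        idx = np.unravel_index(np.argmin(np.abs(res.r - rl) + ~res.mask * 1e9), res.r.shape)
        assert gmap[idx] == pytest.approx(p.T / 2, rel=0.05)
        # steep sigmoid with a small r_loc: pixels far outside see ~ T
        p2 = ModelParams(grid_n=81, T=48.0, k_1=0.5, d=100.0)
        res2 = _manual_result(times, b=b, params=p2, n=81)
        gmap2 = decode_gata3(res2, p2)
        far = res2.mask & (res2.r > r_loc(p2) + 8 / p2.k_1)
        assert far.any()
        assert np.max(gmap2[far]) == pytest.approx(p2.T, rel=0.02)

    def test_piecewise_constant_history_matches_trapezoid(self):
        p = ModelParams(grid_n=21, k_1=1e-6)  # denominator ~2 everywhere
        times = np.array([0.0, 1.0, 2.0, 4.0])
        levels = np.array([1.0, 0.5, 0.5, 0.25])
        b = levels[:, None, None] * np.ones((4, 21, 21))
        res = _manual_result(times, b=b, params=p)
        expected = np.trapezoid(levels, times) / 2.0
        gmap = decode_gata3(res, p)
        assert gmap[res.mask].max() == pytest.approx(expected, rel=1e-3)


class TestBra:
    def test_constant_nodal_gives_zero(self):
        p = ModelParams(grid_n=21)
        times = np.linspace(0, 10, 11)
        u = np.full((11, 21, 21), 5.0)  # gate wide open
        v = np.full((11, 21, 21), 3.0)
        res = _manual_result(times, u=u, v=v, params=p)
        bmap = decode_bra(res, p)
        np.testing.assert_allclose(bmap, 0.0, atol=1e-12)

    def test_closed_gate_suppresses(self):
        p = ModelParams(grid_n=21, k_2=50.0, Wnt_thresh=1.0)
        times = np.linspace(0, 10, 11)
        v = np.linspace(0, 4, 11)[:, None, None] * np.ones((11, 21, 21))
        res = _manual_result(times, v=v, params=p)  # u = 0 everywhere
        bmap = decode_bra(res, p)
        assert np.abs(bmap).max() < 1e-8

    def test_open_gate_telescopes_to_final_nodal(self):
        p = ModelParams(grid_n=21, k_2=50.0, Wnt_thresh=0.1)
        times = np.linspace(0, 10, 41)
        vT = 2.5
        v = np.linspace(0, vT, 41)[:, None, None] * np.ones((41, 21, 21))
        u = np.full((41, 21, 21), 5.0)
        res = _manual_result(times, u=u, v=v, params=p)
        bmap = decode_bra(res, p)
        assert bmap[res.mask].max() == pytest.approx(vT, rel=1e-6)

    def test_single_snapshot_rejected(self):
        res = _manual_result([0.0])
        with pytest.raises(ValueError):
            decode_bra(res)


class TestSox2:
    def test_zero_inputs_basal_level(self):
        p = ModelParams(C_s=1.5, c_1=1.0)
        out = decode_sox2(np.zeros((5, 5)), np.zeros((5, 5)), p)
        np.testing.assert_allclose(out, 1.5)

    def test_zero_stability_silences(self):
        p = ModelParams(C_s=0.0)
        out = decode_sox2(np.random.default_rng(0).random((5, 5)),
                          np.random.default_rng(1).random((5, 5)), p)
        np.testing.assert_allclose(out, 0.0)

    def test_hand_value(self):
        p = ModelParams(C_s=2.0, c_1=1.0, c_2=1.0, c_3=1.0)
        out = decode_sox2(np.full((2, 2), 0.3), np.full((2, 2), 0.4), p,
                          normalized_inputs=False)
        np.testing.assert_allclose(out, 0.6)

    def test_clamped_at_zero(self):
        p = ModelParams(C_s=1.0, c_1=0.1, c_2=5.0, c_3=5.0)
        out = decode_sox2(np.ones((3, 3)), np.ones((3, 3)), p, normalized_inputs=False)
        assert np.all(out == 0.0)

    def test_monotone_in_suppressors(self):
        p = ModelParams()
        low = decode_sox2(np.full((4, 4), 0.2), np.full((4, 4), 0.2), p,
                          normalized_inputs=False)
        high = decode_sox2(np.full((4, 4), 0.6), np.full((4, 4), 0.6), p,
                           normalized_inputs=False)
        assert np.all(high <= low)


class TestSimulatedPhenotype:
    def test_canonical_ordering_at_reference_density(self, sims_by_density):
        fp = simulated_phenotype(sims_by_density[950])
        gata3 = fp.vector.marker_profile("gata3")
        bra = fp.vector.marker_profile("bra")
        sox2 = fp.vector.marker_profile("sox2")
        assert np.argmax(gata3) < 10
        assert np.argmax(sox2) >= 40
        assert np.argmax(gata3) < np.argmax(bra) < np.argmax(sox2)
        assert len(fp.vector) == 150

    def test_bra_auc_decreases_with_density(self, sims_by_density):
        aucs = [simulated_phenotype(sims_by_density[d]).vector.marker_profile("bra").sum()
                for d in (750, 950, 1150)]
        assert aucs[0] > aucs[1] > aucs[2]

    def test_deterministic_given_result(self, sims_by_density):
        a = simulated_phenotype(sims_by_density[950]).vector.values
        b = simulated_phenotype(sims_by_density[950]).vector.values
        np.testing.assert_array_equal(a, b)

    def test_sox2_bins_increase_with_stability(self, sims_by_density):
        res = sims_by_density[950]
        lo = simulated_phenotype(res, replace(res.params, C_s=0.8)).vector.marker_profile("sox2")
        hi = simulated_phenotype(res, replace(res.params, C_s=1.2)).vector.marker_profile("sox2")
        assert np.all(hi >= lo)
        assert hi.sum() > lo.sum()
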