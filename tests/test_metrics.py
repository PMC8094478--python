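import numpy as np
import pytest
from hypothesis import given, strategies as st

import contextcv as cv
from contextcv.metrics import NeighborhoodSpec, BinScheme

from conftest import random_masked_grid, random_masked_stack
from oracles import naive_focal_sd, naive_lcv, naive_ncv, naive_pcv


def assert_surfaces_match(surface, oracle_values, oracle_undefined):
    np.testing.assert_array_equal(surface.undefined, oracle_undefined)
    np.testing.assert_allclose(
        surface.values, oracle_values, rtol=1e-12, atol=1e-12, equal_nan=True
    )


class TestFocalSd:
    def test_constant_grid_is_zero(self):
        g = cv.ContextGrid(spec=cv.GridSpec(5, 5), toxicity=np.full((5, 5), 3.7))
        for hw in (0, 1, 2):
            sd = cv.focal_sd(g, hw)
            np.testing.assert_allclose(sd, 0.0, atol=1e-12)

    def test_center_of_1_to_9(self, grid_1to9):
        sd = cv.focal_sd(grid_1to9, 1)
        assert sd[1, 1] == pytest.approx(2.5820, abs=1e-4)  # pop SD of 1..9

    def test_truncated_corner_window(self, grid_1to9):
        # corner window members {1, 2, 4, 5}
        sd = cv.focal_sd(grid_1to9, 1)
        assert sd[0, 0] == pytest.approx(1.5811, abs=1e-4)

    def test_single_member_window_is_zero(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        g = cv.ContextGrid(
            spec=cv.GridSpec(3, 3), toxicity=np.full((3, 3), 2.0), mask=mask
        )
        assert cv.focal_sd(g, 1)[1, 1] == 0.0

    def test_negative_half_width_rejected(self, grid_1to9):
        with pytest.raises(ValueError):
            cv.focal_sd(grid_1to9, -1)


class TestSpotValues:
    def test_pcv_center(self, grid_1to9):
        surf = cv.pcv_surface(grid_1to9)
        assert surf.values[1, 1] == pytest.approx(0.5164, abs=1e-4)

    def test_pcv_constant_grid_zero(self):
        g = cv.ContextGrid(spec=cv.GridSpec(4, 4), toxicity=np.full((4, 4), 9.0))
        assert np.allclose(cv.pcv_surface(g).values, 0.0, atol=1e-12)

    def test_pcv_zero_pixel_undefined(self):
        tox = np.array([[0.0, 2.0], [4.0, 8.0]])
        surf = cv.pcv_surface(cv.ContextGrid(spec=cv.GridSpec(2, 2), toxicity=tox))
        assert surf.undefined[0, 0]
        assert np.isnan(surf.values[0, 0])
        assert not surf.undefined[1, 1]

    def test_ncv_isolated_spike(self, spike_grid):
        # pop SD of neighbourhood means {1, 1/9, 1/25, 1/49, 1/81, 1/361},
        # independent of the spike's magnitude
        surf = cv.ncv_surface(spike_grid)
        assert surf.values[10, 10] == pytest.approx(0.3605, abs=1e-4)

    def test_ncv_spike_independent_of_magnitude(self, spike_grid):
        s1 = cv.ncv_surface(spike_grid)
        g7 = cv.ContextGrid(
            spec=spike_grid.spec, toxicity=spike_grid.toxicity * 7.0
        )
        s7 = cv.ncv_surface(g7)
        np.testing.assert_allclose(s7.values, s1.values, rtol=1e-12, equal_nan=True)

    def test_ncv_constant_grid_zero(self):
        g = cv.ContextGrid(spec=cv.GridSpec(21, 21), toxicity=np.full((21, 21), 2.0))
        assert np.allclose(cv.ncv_surface(g).values, 0.0, atol=1e-12)

    def test_lcv_1_2_3(self):
        spec = cv.GridSpec(2, 2)
        stack = cv.YearStack(
            [
                cv.ContextGrid(spec=spec, toxicity=np.full((2, 2), v), year=y)
                for y, v in [(2001, 1.0), (2002, 2.0), (2003, 3.0)]
            ]
        )
        surf = cv.lcv_surface(stack)
        # sqrt(2/3) / 2
        np.testing.assert_allclose(surf.values, 0.40825, atol=1e-5)

    def test_lcv_constant_series_zero_and_zero_series_undefined(self):
        spec = cv.GridSpec(1, 2)
        tox = np.array([[2.0, 0.0]])
        stack = cv.YearStack(
            [cv.ContextGrid(spec=spec, toxicity=tox, year=y) for y in (2001, 2002, 2003)]
        )
        surf = cv.lcv_surface(stack)
        assert surf.values[0, 0] == 0.0
        assert surf.undefined[0, 1]

    def test_lcv_even_year_count_uses_central_mean(self):
        spec = cv.GridSpec(1, 1)
        stack = cv.YearStack(
            [
                cv.ContextGrid(spec=spec, toxicity=np.array([[v]]), year=y)
                for y, v in [(2001, 1.0), (2002, 2.0), (2003, 4.0), (2004, 10.0)]
            ]
        )
        surf = cv.lcv_surface(stack)
        expected = np.std([1, 2, 4, 10]) / 3.0  # median = (2 + 4) / 2
        assert surf.values[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_lcv_requires_two_years(self):
        spec = cv.GridSpec(1, 1)
        stack = cv.YearStack(
            [cv.ContextGrid(spec=spec, toxicity=np.array([[1.0]]), year=2001)]
        )
        with pytest.raises(ValueError, match=">= 2"):
            cv.lcv_surface(stack)


class TestOracleEquivalence:
    """The fast focal-statistics path must agree with the brute-force loop."""

    @pytest.mark.parametrize("seed", range(10))
    def test_pcv_matches_loop(self, seed):
        g = random_masked_grid(np.random.default_rng(seed))
        surf = cv.pcv_surface(g)
        assert_surfaces_match(surf, *naive_pcv(g))

    @pytest.mark.parametrize("seed", range(10))
    def test_ncv_matches_loop(self, seed):
        g = random_masked_grid(np.random.default_rng(100 + seed), max_side=15)
        surf = cv.ncv_surface(g)
        assert_surfaces_match(surf, *naive_ncv(g))

    @pytest.mark.parametrize("seed", range(10))
    def test_lcv_matches_loop(self, seed):
        stack = random_masked_stack(np.random.default_rng(200 + seed), max_side=12)
        surf = cv.lcv_surface(stack)
        assert_surfaces_match(surf, *naive_lcv(stack))

    @pytest.mark.parametrize("half_width", [0, 1, 3])
    def test_focal_sd_matches_loop(self, half_width):
        g = random_masked_grid(np.random.default_rng(5), max_side=15)
        np.testing.assert_allclose(
            cv.focal_sd(g, half_width),
            naive_focal_sd(g, half_width),
            rtol=1e-12, atol=1e-12, equal_nan=True,
        )


class TestInvariances:
    @pytest.mark.parametrize("c", [0.001, 3.0, 1e6])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(17)
        g = random_masked_grid(rng, max_side=12)
        scaled = cv.ContextGrid(spec=g.spec, toxicity=c * g.toxicity, mask=g.mask)
        for fn in (cv.pcv_surface, cv.ncv_surface):
            a, b = fn(g), fn(scaled)
            np.testing.assert_allclose(
                a.values, b.values, rtol=1e-9, equal_nan=True
            )
            np.testing.assert_array_equal(a.undefined, b.undefined)
        stack = random_masked_stack(rng, max_side=10)
        scaled_stack = cv.YearStack(
            [
                cv.ContextGrid(spec=s.spec, toxicity=c * s.toxicity, mask=s.mask,
                               year=s.year)
                for s in stack
            ]
        )
        a, b = cv.lcv_surface(stack), cv.lcv_surface(scaled_stack)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-9, equal_nan=True)

    def test_translation_sensitivity(self, grid_1to9):
        """Adding a constant changes the metrics: the SD stays, the denominator moves."""
        shifted = cv.ContextGrid(
            spec=grid_1to9.spec, toxicity=grid_1to9.toxicity + 10.0
        )
        pcv0 = cv.pcv_surface(grid_1to9).values[1, 1]
        pcv1 = cv.pcv_surface(shifted).values[1, 1]
        assert pcv1 == pytest.approx(pcv0 * 5 / 15, rel=1e-9)
        assert pcv1 != pytest.approx(pcv0)

    def test_sample_sd_option(self, grid_1to9):
        surf = cv.pcv_surface(grid_1to9, ddof=1)
        expected = np.std(np.arange(1, 10), ddof=1) / 5.0
        assert surf.values[1, 1] == pytest.approx(expected, rel=1e-12)


class TestBinning:
    @pytest.mark.parametrize(
        "value, expected_bin",
        [(0.0, 1), (0.024, 1), (0.025, 2), (0.03, 2), (0.05, 3), (0.074, 3),
         (0.075, 4), (0.4, 4), (0.5, 5), (4.99, 5), (5.0, 6), (1e9, 6)],
    )
    def test_default_edges(self, value, expected_bin):
        assert BinScheme().assign(np.array([value]))[0] == expected_bin

    def test_bin_metric_leaves_undefined_unbinned(self):
        tox = np.array([[0.0, 2.0], [4.0, 8.0]])
        surf = cv.pcv_surface(cv.ContextGrid(spec=cv.GridSpec(2, 2), toxicity=tox))
        binned = cv.bin_metric(surf)
        assert binned.bin[0, 0] == 0
        assert (binned.bin[~surf.undefined] >= 1).all()

    def test_non_monotone_scheme_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(edges=(0.05, 0.025))

    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_assigned_bin_interval_contains_value(self, value):
        scheme = BinScheme()
        b = int(scheme.assign(np.array([value]))[0])
        lo, hi = scheme.intervals()[b - 1]
        assert lo <= value < hi


class TestNeighborhoodSpec:
    def test_default_sizes(self):
        assert NeighborhoodSpec().sizes == (1, 9, 25, 49, 81, 361)

    def test_requires_singleton_and_monotone(self):
        with pytest.raises(ValueError):
            NeighborhoodSpec((1, 2))
        with pytest.raises(ValueError):
            NeighborhoodSpec((0, 2, 1))


@pytest.fixture(scope="module")
def single_release():
    cfg = cv.ScenarioConfig(
        n_rows=64, n_cols=64, n_sites=1, years=(2008,),
        cutoff_radius=20 * 0.805, p_site_near_center=0.0,
        acute_rate=0.0, seed=3,
    )
    stack, sites = cv.simulate_surface(cfg)
    return stack[0], sites.iloc[0]


class TestRingArtifact:
    """A hard cutoff radius shows up as an elevated-PCV annulus."""

    def test_cutoff_annulus_has_higher_pcv_than_interior(self, single_release):
        grid, site = single_release
        surf = cv.pcv_surface(grid)
        X, Y = cv.pixel_centers(grid.spec)
        d_pix = np.hypot(X - site["x"], Y - site["y"]) / grid.spec.pixel_size
        R = 20.0
        ring = (d_pix >= R - 1) & (d_pix <= R + 1) & surf.defined_mask
        interior = (d_pix >= R / 2 - 1) & (d_pix <= R / 2 + 1) & surf.defined_mask
        assert ring.sum() > 0 and interior.sum() > 0
        assert surf.values[ring].mean() > surf.values[interior].mean()

    def test_near_release_pcv_exceeds_grid_median(self, single_release):
        grid, site = single_release
        surf = cv.pcv_surface(grid)
        X, Y = cv.pixel_centers(grid.spec)
        d_pix = np.hypot(X - site["x"], Y - site["y"]) / grid.spec.pixel_size
        near = (d_pix <= 2) & surf.defined_mask
        assert near.sum() > 0
        grid_median = np.median(surf.defined_values())
        assert surf.values[near].mean() > grid_median
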