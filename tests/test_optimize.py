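import warnings

import numpy as np
import pytest

from colonyopt import (
    BranchPattern,
    ConditionMapping,
    GridSpec,
    PRESETS,
    build_mapping,
    optimal_pattern,
    screen_WD,
)
from colonyopt.optimize import OptimizationResult, _argmax_pattern

TINY_GRID = GridSpec(Lx=10.0, Ly=10.0, h=1.0, dt=0.02, R=90.0)
W3 = np.array([1.0, 2.0, 4.0])
D3 = np.array([0.05, 0.2, 0.5])


@pytest.fixture(scope="module")
def tiny_screen():
    return screen_WD(PRESETS["fig2"], W3, D3, t_end=6.0, grid=TINY_GRID)


class TestScreenWD:
    def test_deterministic_bit_identical(self, tiny_screen):
        again = screen_WD(PRESETS["fig2"], W3, D3, t_end=6.0, grid=TINY_GRID)
        assert np.array_equal(tiny_screen.biomass, again.biomass)

    def test_beyond_diagonal_cells_evaluate_as_uniform(self, tiny_screen):
        # (4, 0.5) and (2, 0.5) both violate WD <= 1 -> same uniform value
        B = tiny_screen.biomass
        assert B[2, 2] == B[1, 2]

    def test_validation(self):
        with pytest.raises(ValueError):
            screen_WD(PRESETS["fig2"], np.array([]), D3)
        with pytest.raises(ValueError):
            screen_WD(PRESETS["fig2"], np.array([-1.0]), D3)

    def test_csv_roundtrip(self, tiny_screen, tmp_path):
        p = tmp_path / "heat.csv"
        tiny_screen.to_csv(str(p))
        import pandas as pd
        df = pd.read_csv(p, index_col=0)
        np.testing.assert_allclose(df.to_numpy(), tiny_screen.biomass)

    def test_max_biomass_non_decreasing_in_N0(self):
        maxima = []
        for N0 in (4.0, 8.0, 16.0):
            res = screen_WD(PRESETS["fig2"].replace(N0=N0), W3, D3,
                            t_end=6.0, grid=TINY_GRID)
            maxima.append(res.biomass.max())
        assert np.all(np.diff(maxima) >= 0)


class TestOptimalPattern:
    def _result(self, B, W=W3, D=D3):
        return OptimizationResult(W_grid=W, D_grid=D, biomass=np.asarray(B, float),
                                  optimum=BranchPattern(1, 0.05),
                                  params=PRESETS["fig2"], t_end=24.0)

    def test_single_cell_grid(self):
        res = self._result([[5.0]], W=np.array([2.0]), D=np.array([0.1]))
        opt = optimal_pattern(res)
        assert (opt.W, opt.D) == (2.0, 0.1)

    def test_exact_tie_breaks_toward_smaller_W_then_smaller_D(self):
        B = np.zeros((3, 3))
        B[1, 1] = B[2, 0] = 7.0  # (W=2, D=0.2) vs (W=4, D=0.05)
        opt = optimal_pattern(self._result(B), rel_tol=0.0)
        assert (opt.W, opt.D) == (2.0, 0.2)
        B2 = np.zeros((3, 3))
        B2[1, 2] = B2[1, 0] = 7.0  # same W, tie on D: (2, 0.5) is uniform-capped
        opt2 = optimal_pattern(self._result(B2), rel_tol=0.0)
        assert (opt2.W, opt2.D) == (2.0, 0.05)

    def test_matches_bruteforce_argmax(self, tiny_screen):
        opt = optimal_pattern(tiny_screen, rel_tol=0.0)
        best = -np.inf
        best_cell = None
        for i, W in enumerate(tiny_screen.W_grid):
            for j, D in enumerate(tiny_screen.D_grid):
                if tiny_screen.biomass[i, j] > best:
                    best = tiny_screen.biomass[i, j]
                    best_cell = (min(W, 1.0 / D), D)
        assert (opt.W, opt.D) == pytest.approx(best_cell)
        assert tiny_screen.biomass.max() == best

    def test_plateau_touching_diagonal_reports_uniform(self):
        B = np.full((3, 3), 10.0)
        B[0, 0] = 1.0  # informative span; everything else tied incl. WD >= 1
        opt = optimal_pattern(self._result(B))
        assert opt.is_uniform

    def test_flat_matrix_does_not_claim_diagonal(self):
        B = np.full((3, 3), 10.0)
        opt = optimal_pattern(self._result(B))
        assert not opt.is_uniform and opt.W == 1.0

    def test_empty_result_rejected(self):
        res = self._result(np.zeros((0, 0)), W=np.array([]), D=np.array([]))
        with pytest.raises(ValueError):
            optimal_pattern(res)


class TestConditionMapping:
    def test_tabulated_rows_exact_and_interpolated_between(self):
        m = ConditionMapping([5.0, 10.0], [1.0, 3.0], [0.2, 0.1])
        assert m.lookup(5.0).W == 1.0 and m.lookup(10.0).D == 0.1
        mid = m.lookup(7.5)
        assert mid.W == pytest.approx(2.0) and mid.D == pytest.approx(0.15)

    def test_extrapolation_clamps_to_end_rows(self):
        m = ConditionMapping([5.0, 10.0], [1.0, 3.0], [0.2, 0.1])
        assert m.lookup(0.0).W == 1.0
        assert m.lookup(50.0).W == 3.0

    def test_interpolated_pattern_respects_constraint(self):
        # W and D interpolating across the diagonal could overshoot WD=1
        m = ConditionMapping([0.0, 1.0], [2.0, 10.0], [0.5, 0.1])
        pat = m.lookup(0.5)
        assert pat.W * pat.D <= 1.0 + 1e-9

    def test_csv_roundtrip(self, tmp_path):
        m = ConditionMapping([5.0, 10.0], [1.0, 3.0], [0.2, 0.1])
        p = tmp_path / "map.csv"
        m.to_csv(str(p))
        back = ConditionMapping.from_csv(str(p))
        np.testing.assert_allclose(back.W_opt, m.W_opt)

    def test_build_mapping_sorts_with_warning(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            m = build_mapping(PRESETS["fig2"], [8.0, 4.0], W_grid=W3, D_grid=D3,
                              t_end=4.0, grid=TINY_GRID)
        assert any("sorted" in str(w.message) for w in rec)
        assert m.N0_values[0] < m.N0_values[1]

    def test_build_mapping_needs_two_levels(self):
        with pytest.raises(ValueError):
            build_mapping(PRESETS["fig2"], [8.0], W_grid=W3, D_grid=D3)

    def test_optimal_width_non_decreasing_in_N0(self, fig2_mapping):
        """The optimal branch width widens with nutrient availability."""
        assert np.all(np.diff(fig2_mapping.W_opt) >= -1e-9)
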