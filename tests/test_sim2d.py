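import numpy as np
import pytest
from scipy.spatial.distance import cdist

from colonyopt import (
    BranchPattern,
    GridSpec,
    PRESETS,
    SeedDisk,
    SeedingConfig,
    Tip,
    local_tip_density,
    simulate_2d,
    uniform_field,
)
from colonyopt.sim2d import Colony2DState, init_colony, stamp_mask_from_trajectories

FIG4 = PRESETS["fig4"]


def fresh_state(grid, N0=8.0, seeds=()):
    fld = uniform_field(N0, grid)
    return Colony2DState(
        grid=grid, nutrient=fld,
        colony_owner=np.full((grid.ny, grid.nx), -1, dtype=np.int32),
        branch_owner=np.full((grid.ny, grid.nx), -1, dtype=np.int32),
        density=np.zeros((grid.ny, grid.nx)),
        tips=[], trajectories={}, seeds=SeedingConfig(list(seeds)),
        consumed={}, initial_biomass={})


def run_homogeneous(D, W=2.0, t_end=16.0, N0=8.0, seed_r=5.0, C0=0.5):
    grid = GridSpec(Lx=90, Ly=90, h=1.0, dt=0.02)
    fld = uniform_field(N0, grid)
    seeding = SeedingConfig([SeedDisk(center=(45.0, 45.0), radius=seed_r, C0=C0)])
    return simulate_2d(FIG4, BranchPattern(W=W, D=D), fld, seeding, t_end=t_end)


class TestInitColony:
    def test_tip_count_follows_perimeter_density(self):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        st = fresh_state(grid)
        tips = init_colony(st, SeedDisk((20, 20), 5.0, 0.5), BranchPattern(2, 0.10), 0)
        assert len(tips) == max(2, round(2 * np.pi * 5.0 * 0.10))  # = 3
        st2 = fresh_state(grid)
        tips2 = init_colony(st2, SeedDisk((20, 20), 5.0, 0.5), BranchPattern(2, 0.001), 0)
        assert len(tips2) == 2  # degenerate-density floor

    def test_headings_are_exact_outward_radials(self):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        st = fresh_state(grid)
        tips = init_colony(st, SeedDisk((20, 20), 5.0, 0.5), BranchPattern(2, 0.2), 0)
        for t in tips:
            r = t.position - np.array([20.0, 20.0])
            r = r / np.linalg.norm(r)
            assert float(r @ t.heading) == pytest.approx(1.0, abs=1e-12)

    def test_seed_biomass_matches_stamped_area(self):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        st = fresh_state(grid)
        init_colony(st, SeedDisk((20, 20), 5.0, 1.6), BranchPattern(2, 0.1), 0)
        area = float(st.mask.sum()) * grid.h ** 2
        assert st.biomass(0) == pytest.approx(1.6 * area)


class TestLocalTipDensity:
    def _two_tips(self, apart):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        st = fresh_state(grid)
        a = Tip(np.array([10.0, 20.0]), np.array([1.0, 0.0]), 0, 0, BranchPattern(2, 0.1))
        b = Tip(np.array([10.0 + apart, 20.0]), np.array([1.0, 0.0]), 0, 1, BranchPattern(2, 0.1))
        st.tips = [a, b]
        st.trajectories = {0: [(0, 10.0, 20.0, 2.0)], 1: [(0, 10.0 + apart, 20.0, 2.0)]}
        return st, a, b

    def test_pair_at_10mm_reads_one_tenth(self):
        st, a, b = self._two_tips(10.0)
        assert local_tip_density(a, st) == pytest.approx(0.1)
        assert local_tip_density(b, st) == pytest.approx(0.1)

    def test_lone_tip_has_zero_density(self):
        st, a, b = self._two_tips(10.0)
        b.active = False
        assert local_tip_density(a, st) == 0.0

    def test_matches_bruteforce_nearest_neighbor(self):
        grid = GridSpec(Lx=100, Ly=100, h=1.0, dt=0.02)
        st = fresh_state(grid)
        rng = np.random.default_rng(5)
        pts = rng.uniform(10, 90, (50, 2))
        st.tips = [Tip(p, np.array([1.0, 0.0]), 0, k, BranchPattern(2, 0.1))
                   for k, p in enumerate(pts)]
        dmat = cdist(pts, pts)
        np.fill_diagonal(dmat, np.inf)
        for k, tip in enumerate(st.tips):
            assert local_tip_density(tip, st) == pytest.approx(1.0 / dmat[k].min())

    def test_trajectory_mode(self):
        st, a, b = self._two_tips(8.0)
        assert local_tip_density(a, st, mode="trajectories") == pytest.approx(1.0 / 8.0)
        with pytest.raises(ValueError):
            local_tip_density(a, st, mode="nope")


class TestSimulate2D:
    def test_empty_plate_leaves_only_seed_disks(self):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        fld = uniform_field(0.0, grid)
        seeding = SeedingConfig([SeedDisk((20, 20), 5.0, 0.5)])
        st = simulate_2d(FIG4, BranchPattern(W=2, D=0.1), fld, seeding, t_end=4.0)
        ii, jj = np.nonzero(st.mask)
        rr = np.hypot((jj + 0.5) - 20, (ii + 0.5) - 20)
        assert rr.max() <= 5.0 + 2.0  # seed disk + initial tip stamps only
        assert st.total_biomass() == pytest.approx(st.initial_biomass[0], rel=1e-12)

    def test_yield_identity_holds_globally(self):
        st = run_homogeneous(0.1, t_end=8.0)
        gained = st.total_biomass() - sum(st.initial_biomass.values())
        consumed = sum(st.consumed.values())
        assert gained == pytest.approx(
            (FIG4.alpha_C / FIG4.beta_N) * consumed, rel=1e-6)

    def test_deterministic(self):
        a = run_homogeneous(0.1, t_end=4.0)
        b = run_homogeneous(0.1, t_end=4.0)
        assert np.array_equal(a.mask, b.mask)
        assert a.total_biomass() == b.total_biomass()

    def test_mask_reproducible_from_trajectories(self):
        st = run_homogeneous(0.1, t_end=8.0)
        np.testing.assert_array_equal(stamp_mask_from_trajectories(st), st.mask)

    def test_rotational_symmetry_of_mass_center(self):
        st = run_homogeneous(0.1, t_end=12.0)
        ii, jj = np.nonzero(st.mask)
        cx, cy = (jj + 0.5).mean(), (ii + 0.5).mean()
        assert np.hypot(cx - 45.0, cy - 45.0) < 2.0 * st.grid.h

    def test_branch_count_increases_with_density(self):
        counts = [len(run_homogeneous(D, t_end=10.0).trajectories)
                  for D in (0.05, 0.1, 0.2)]
        assert counts[0] < counts[1] < counts[2]

    def test_tip_density_settles_into_bifurcation_band(self):
        st = run_homogeneous(0.1, t_end=16.0)
        dens = [local_tip_density(t, st) for t in st.active_tips()]
        assert len(dens) >= 5
        assert (2.0 / 3.0) * 0.1 <= np.mean(dens) <= 2.0 * 0.1

    def test_neighboring_colonies_avoid_each_other(self):
        grid = GridSpec(Lx=90, Ly=90, h=1.0, dt=0.02)
        fld = uniform_field(14.5, grid)
        seeding = SeedingConfig([SeedDisk((30, 45), 5.0, 1.6), SeedDisk((60, 45), 5.0, 1.6)])
        st = simulate_2d(PRESETS["fig6"], BranchPattern(W=2, D=0.1), fld, seeding, t_end=10.0)
        b2c = {t.branch_id: t.colony_id for t in st.tips}
        for b, verts in st.trajectories.items():
            for (_, x, y, _W) in verts:
                i = min(int(y / grid.h), grid.ny - 1)
                j = min(int(x / grid.h), grid.nx - 1)
                owner = st.colony_owner[i, j]
                assert owner < 0 or owner == b2c[b]

    def test_seed_outside_domain_rejected(self):
        grid = GridSpec(Lx=40, Ly=40, h=1.0, dt=0.02)
        fld = uniform_field(8.0, grid)
        with pytest.raises(ValueError, match="outside"):
            simulate_2d(FIG4, BranchPattern(2, 0.1), fld,
                        SeedingConfig([SeedDisk((50, 20), 5.0, 0.5)]), t_end=1.0)
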