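import numpy as np
import pytest

from colonyopt import BranchPattern, GridSpec, PRESETS, biomass_at, simulate_1d

FIG2 = PRESETS["fig2"]
SMALL = GridSpec(Lx=20.0, Ly=20.0, h=1.0, dt=0.02, R=90.0)


def uniform_front_oracle(params, nx: int, h: float, dt: float, C0: float, t_end: float):
    """Independent branchless-front implementation: pure 1D arrays.

    Mirrors the documented algorithm (FTCS diffusion with the same
    sub-stepping rule, clamped consumption, yield-locked growth, expansion
    law dA/dt = gamma*Omega, biomass-conserving front split) without using
    any of the 2D lattice machinery.  Returns per-unit-height biomass and
    front position trajectories.
    """
    N = np.full(nx, params.N0, dtype=float)
    dens = np.zeros(nx)
    dens[0] = C0
    cols, L = 1, h
    B = C0 * h * h
    yr = params.alpha_C / params.beta_N
    limit = 0.95 * h * h / (4.0 * params.D_N)
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps
    ts, Bs, Ls = [0.0], [B], [L]
    for k in range(1, n_steps + 1):
        nsub = max(1, int(np.ceil(dt / limit)))
        sub = dt / nsub if dt > limit else dt
        for _ in range(nsub if dt > limit else 1):
            p = np.pad(N, 1, mode="edge")
            N = N + params.D_N * sub * (p[:-2] + p[2:] - 2.0 * N) / (h * h)
        monod = N[:cols] / (params.K_N + N[:cols])
        fG = monod * dens[:cols] ** 2 / (dens[:cols] + params.C_m)
        removed = np.minimum(params.beta_N * fG * dt, N[:cols])
        N[:cols] -= removed
        dens[:cols] += yr * removed
        dB = yr * float(removed.sum()) * h * h
        B += dB
        L = min(L + params.gamma * dB / h, nx * h)
        new_cols = int(np.clip(np.floor(L / h + 0.5), 1, nx))
        while cols < new_cols:
            donor = dens[cols - 1]
            dens[cols] = donor / 2.0
            dens[cols - 1] = donor / 2.0
            cols += 1
        ts.append(k * dt)
        Bs.append(B)
        Ls.append(L)
    return np.array(ts), np.array(Bs), np.array(Ls)


class TestBranchPattern:
    def test_constraint_wd_at_most_one(self):
        BranchPattern(W=2.0, D=0.5)  # boundary case is allowed
        with pytest.raises(ValueError, match="W\\*D"):
            BranchPattern(W=3.0, D=0.5)
        with pytest.raises(ValueError):
            BranchPattern(W=0.0, D=0.1)
        assert BranchPattern(W=2.0, D=0.5).is_uniform
        assert not BranchPattern(W=1.0, D=0.1).is_uniform


class TestSimulate1D:
    def test_empty_plate_never_grows_or_moves(self):
        run = simulate_1d(FIG2.replace(N0=0.0), BranchPattern(W=2, D=0.1),
                          grid=SMALL, t_end=5.0, record_every=25)
        assert run.final().L == run.states[0].L
        assert run.final().B == pytest.approx(run.states[0].B, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL, C0=0.0)
        with pytest.raises(ValueError):
            simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL, t_end=-1.0)
        with pytest.raises(ValueError):
            simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL, allocation="magic")

    def test_yield_identity_closes(self):
        run = simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL,
                          t_end=24.0, record_every=100)
        for s in run.states[1:]:
            gained = s.B - run.states[0].B
            assert gained == pytest.approx(
                (FIG2.alpha_C / FIG2.beta_N) * s.nutrient_consumed, rel=1e-6)

    def test_length_and_biomass_non_decreasing(self):
        run = simulate_1d(FIG2, BranchPattern(W=1, D=0.1), grid=SMALL,
                          t_end=12.0, record_every=20)
        assert np.all(np.diff(run.lengths) >= 0)
        assert np.all(np.diff(run.biomass) >= 0)

    def test_uniform_front_oracle_equivalence(self):
        """A WD = 1 pattern must reduce exactly to the branchless 1D front."""
        pat = BranchPattern(W=4.0, D=0.25)
        run = simulate_1d(FIG2, pat, grid=SMALL, t_end=12.0)
        ny = run.grid.ny
        ts, Bs, Ls = uniform_front_oracle(FIG2, SMALL.nx, SMALL.h, SMALL.dt,
                                          C0=0.5, t_end=12.0)
        np.testing.assert_allclose(run.times, ts, rtol=1e-12)
        np.testing.assert_allclose(run.biomass / ny, Bs, rtol=1e-8)
        np.testing.assert_allclose(run.lengths, Ls, rtol=1e-8)

    def test_thin_branches_beat_uniform_when_nutrient_poor(self, fig2_screens):
        """At N0 = 8 g/l, gamma = 7.5 a thin branch pattern accumulates
        strictly more biomass than the non-branching colony."""
        res = fig2_screens["poor"]
        i = int(np.argmin(np.abs(res.W_grid - 2.0)))
        j = int(np.argmin(np.abs(res.D_grid - 0.2)))
        thin = res.biomass[i, j]
        uniform = res.biomass[-1, -1]  # W=10, D=0.5 cell evaluates as WD=1
        assert res.W_grid[-1] * res.D_grid[-1] > 1.0
        assert thin > uniform * 1.02

    def test_uniform_allocation_mode_keeps_density_flat(self):
        run = simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL,
                          t_end=4.0, allocation="uniform", record_every=50)
        dens = run.density[run.mask]
        np.testing.assert_allclose(dens, dens[0], rtol=1e-9)


class TestBiomassAt:
    def test_endpoints_and_interpolation(self):
        run = simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL,
                          t_end=6.0, record_every=10)
        assert biomass_at(run, 0.0) == run.states[0].B
        assert biomass_at(run, 6.0) == run.final().B
        t_mid = 3.14
        lo = max(s.B for s in run.states if s.t <= t_mid)
        hi = min(s.B for s in run.states if s.t >= t_mid)
        assert lo <= biomass_at(run, t_mid) <= hi

    def test_initial_biomass_is_inoculum(self):
        run = simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL,
                          C0=0.7, t_end=1.0, record_every=10)
        assert biomass_at(run, 0.0) == pytest.approx(0.7 * run.states[0].area)

    def test_out_of_range_rejected(self):
        run = simulate_1d(FIG2, BranchPattern(W=2, D=0.1), grid=SMALL,
                          t_end=2.0, record_every=10)
        with pytest.raises(ValueError, match="outside"):
            biomass_at(run, 3.0)
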