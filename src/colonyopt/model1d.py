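"""Parallel-branch (1D-extension) colony growth engine.

A colony growing from a strip inoculum forms parallel branches of width
``W`` at density ``D`` (branches per mm transverse to extension).  By
periodicity it suffices to simulate one spatial period: a strip of height
``1/D`` with one branch of width ``W`` centred in it, extending in ``+x``
from a one-cell-deep full-width inoculum strip.  Per outer time step the
engine

1. diffuses the nutrient (no-flux boundaries, sub-stepped for stability);
2. consumes nutrient inside the colony mask at rate ``beta_N * f_G(N, C)``,
   clamped so no cell goes negative;
3. converts the nutrient actually removed into biomass through the yield
   ratio ``alpha_C / beta_N`` (so the nutrient/biomass budget closes to
   round-off by construction);
4. elongates the branch so that the colony's area expansion is
   proportional to its total growth, ``dA/dt = gamma * Omega``: with a
   branch cross-section of width ``W`` per period this is
   ``dL/dt = gamma * Omega_period / W`` (equivalently
   ``dL/dt = gamma * (Omega/A) * L``, an exponential front when the whole
   colony is fed and a stalling one when only the boundary is);
5. colonizes newly claimed cells by a biomass-conserving front split: each
   new cell takes half the cell density of the colony cell behind it
   (``allocation="local"``, the default), so the colony edge is low-density
   and densities accumulate locally where nutrient lasts.  With
   ``allocation="uniform"`` biomass is instead re-allocated uniformly over
   the whole colony each step (``C = B / A``).

``WD = 1`` is the non-branching (uniform front) limit; the branch then fills
the whole strip and the run reduces exactly to a 1D front.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .growth import GrowthFunctionSpec, ModelParams, f_G
from .pde import GridSpec, NutrientField, step_diffusion

__all__ = ["BranchPattern", "Colony1DState", "Colony1DRun", "simulate_1d", "biomass_at"]

_WD_TOL = 1e-9


@dataclass(frozen=True)
class BranchPattern:
    """Branch width ``W`` (mm) and branch density ``D`` (1/mm).

    ``W * D <= 1`` because the branches cannot overfill the cross-section;
    equality is the uniform, non-branching colony.
    """

    W: float
    D: float

    def __post_init__(self) -> None:
        if self.W <= 0 or self.D <= 0:
            raise ValueError("W and D must be positive")
        if self.W * self.D > 1.0 + _WD_TOL:
            raise ValueError(f"pattern violates W*D <= 1 (got {self.W * self.D:.4g})")

    @property
    def is_uniform(self) -> bool:
        return self.W * self.D >= 1.0 - _WD_TOL


@dataclass
class Colony1DState:
    """Snapshot of the one-period colony at time ``t``."""

    t: float                 # h
    L: float                 # branch length, mm
    B: float                 # total biomass in the period, c.u. * mm^2
    C: float                 # mean colony cell density, c.u.
    area: float              # rasterized colony area, mm^2
    nutrient_consumed: float  # cumulative, g/l * mm^2


@dataclass
class Colony1DRun:
    """Full trajectory of a one-period run plus the final field and lattices."""

    params: ModelParams
    pattern: BranchPattern
    grid: GridSpec
    states: list[Colony1DState] = dc_field(default_factory=list)
    field: NutrientField | None = None
    mask: np.ndarray | None = None
    density: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def biomass(self) -> np.ndarray:
        return np.array([s.B for s in self.states])

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.L for s in self.states])

    def final(self) -> Colony1DState:
        return self.states[-1]


def _branch_rows(ny: int, W: float, h: float) -> slice:
    """Rows of the branch, centred in the period strip; at least one row."""
    w_cells = int(np.clip(round(W / h), 1, ny))
    lo = (ny - w_cells) // 2
    return slice(lo, lo + w_cells)


def _front_cols(L: float, h: float, nx: int) -> int:
    """Occupied branch columns: cells whose center lies left of the front."""
    return int(np.clip(np.floor(L / h + 0.5), 1, nx))


def simulate_1d(params: ModelParams, pattern: BranchPattern, grid: GridSpec | None = None,
                C0: float = 0.5, t_end: float = 24.0,
                spec: GrowthFunctionSpec | None = None,
                allocation: str = "local",
                record_every: int = 1) -> Colony1DRun:
    """Simulate one spatial period of the parallel-branch colony.

    Parameters
    ----------
    params, pattern
        Environment and colony geometry (``pattern.W * pattern.D <= 1``).
    grid
        Supplies ``Lx`` (extension length), ``h`` and the outer ``dt``; the
        strip height is ``1/D`` regardless of ``grid.Ly``.
    C0
        Initial cell density (c.u.) of the one-grid-cell-deep full-width
        inoculum strip at x = 0 (every pattern starts from the same
        inoculum).
    allocation
        ``"local"`` (default): density accumulates per cell and front cells
        are seeded by halving the donor cell's density.  ``"uniform"``:
        biomass is re-allocated uniformly over the colony every step.
    record_every
        Store a state every this many outer steps (the last step is always
        stored).
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if allocation not in ("local", "uniform"):
        raise ValueError(f"unknown allocation mode {allocation!r}")
    grid = grid or GridSpec()
    h = grid.h
    nx = grid.nx
    ny = max(1, int(round(1.0 / (pattern.D * h))))
    period_grid = GridSpec(Lx=nx * h, Ly=ny * h, h=h, dt=grid.dt, R=grid.R)
    rows = _branch_rows(ny, pattern.W, h)
    W_r = (rows.stop - rows.start) * h  # realized branch width after rasterization

    fld = NutrientField(period_grid, params.N0)
    yield_ratio = params.alpha_C / params.beta_N
    cell_area = h * h

    # colony lattice: full-width inoculum strip (one cell deep) + branch
    mask = np.zeros((ny, nx), dtype=bool)
    mask[:, 0] = True
    L = h
    cols = 1
    dens = np.zeros((ny, nx))
    dens[:, 0] = C0
    B = C0 * ny * cell_area
    area = float(mask.sum()) * cell_area
    consumed = 0.0

    run = Colony1DRun(params=params, pattern=pattern, grid=period_grid)
    run.states.append(Colony1DState(0.0, L, B, B / area, area, 0.0))

    n_steps = int(np.ceil(t_end / grid.dt))
    dt = t_end / n_steps
    for k in range(1, n_steps + 1):
        step_diffusion(fld, params.D_N, dt)
        sub = fld.values[mask]
        demand = params.beta_N * f_G(sub, dens[mask], params, spec) * dt
        removed = np.minimum(demand, sub)
        fld.values[mask] = sub - removed
        removed_mass = float(removed.sum()) * cell_area
        consumed += removed_mass
        dens[mask] += yield_ratio * removed
        dB = yield_ratio * removed_mass
        B += dB
        dL = params.gamma * dB / W_r
        L = min(L + dL, period_grid.Lx)
        new_cols = _front_cols(L, h, nx)
        if new_cols > cols:
            for c in range(cols, new_cols):
                donor = dens[rows, c - 1] if c > 1 else dens[rows, 0]
                dens[rows, c] = donor / 2.0
                dens[rows, c - 1] = donor / 2.0
                mask[rows, c] = True
            cols = new_cols
            area = float(mask.sum()) * cell_area
        if allocation == "uniform":
            dens[mask] = B / area
        if k % record_every == 0 or k == n_steps:
            run.states.append(Colony1DState(k * dt, L, B, B / area, area, consumed))

    run.field = fld
    run.mask = mask
    run.density = dens
    return run


def biomass_at(run: Colony1DRun, t: float) -> float:
    """Biomass (c.u. * mm^2) at time ``t``, linearly interpolated."""
    times = run.times
    if not (times[0] <= t <= times[-1]):
        raise ValueError(f"t={t} outside simulated range [{times[0]}, {times[-1]}]")
    return float(np.interp(t, times, run.biomass))
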