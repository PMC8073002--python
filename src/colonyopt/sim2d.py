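"""Tip-tracking 2D branching growth engine.

Colonies start from inoculum disks.  Branches are represented by their
moving tips: the colony mask is the union of disks of radius ``W/2``
stamped along the tip trajectories.  Cell density is a lattice field that
accumulates locally (low-density colony edges, dense fed interior).  Per
step the engine

1. diffuses the shared nutrient field and lets every colonized cell consume
   nutrient (clamped at zero), converting the removed nutrient into biomass
   through the yield ratio ``alpha_C / beta_N``;
2. gives each branch an elongation increment from the expansion law
   ``dA/dt = gamma * Omega`` applied per branch: ``dL_b = gamma *
   Omega_b * dt / W_b``, where ``Omega_b`` is the growth in the cells the
   branch owns (trunk ownership is inherited across bifurcations), so thin
   branches elongate faster for the same growth — the engine of
   anti-gradient expansion on nutrient-gradient plates;
3. moves each active tip by ``dL`` along a blend of its previous heading
   and the local nutrient gradient, then stamps a ``W/2`` disk at the new
   position; newly claimed cells are seeded at half the donor cell's
   density, debited from the branch so total biomass is conserved;
4. bifurcates a tip into two (headings rotated by the split half-angle,
   parent trunk cells divided between the children by side) when its local
   branch density ``1/d`` — ``d`` the distance to the nearest other active
   tip — falls below ``2/3 * D``;
5. deactivates tips that leave the domain, starve (local nutrient below
   ``0.05 * K_N``) or run into another colony's mask (branches of
   neighbouring colonies avoid each other);
6. optionally refreshes each tip's (W, D) from a condition-to-pattern
   mapping evaluated at the nutrient concentration at the tip, so the
   branch geometry tracks the local environment as the colony expands.

``budget="colony"`` replaces the per-branch elongation by a single
colony-wide increment ``dL = gamma * Omega_colony * dt / sum(W_tips)``
shared by all tips of the colony.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial.distance import cdist

from .growth import GrowthFunctionSpec, ModelParams, f_G
from .model1d import BranchPattern
from .optimize import ConditionMapping
from .pde import GridSpec, NutrientField, gradient_at, step_diffusion

__all__ = [
    "SeedDisk",
    "SeedingConfig",
    "Tip",
    "Colony2DState",
    "init_colony",
    "local_tip_density",
    "step",
    "simulate_2d",
    "stamp_mask_from_trajectories",
]


@dataclass(frozen=True)
class SeedDisk:
    """One inoculum: center (mm), radius (mm), initial cell density (c.u.)."""

    center: tuple[float, float]
    radius: float = 5.0
    C0: float = 1.6

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.C0 <= 0:
            raise ValueError("seed radius and C0 must be positive")


@dataclass
class SeedingConfig:
    seeds: list[SeedDisk]

    def validate(self, grid: GridSpec) -> None:
        for s in self.seeds:
            x, y = s.center
            if not (0 <= x <= grid.Lx and 0 <= y <= grid.Ly):
                raise ValueError(f"seed at {s.center} outside domain")


@dataclass
class Tip:
    """An active branch tip."""

    position: np.ndarray        # (x, y) mm
    heading: np.ndarray         # unit 2-vector
    colony_id: int
    branch_id: int
    pattern: BranchPattern
    active: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        h = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(h)
        if n == 0:
            raise ValueError("tip heading must be non-zero")
        self.heading = h / n


@dataclass
class Colony2DState:
    """Shared nutrient field, ownership/density lattices, tips, trajectories."""

    grid: GridSpec
    nutrient: NutrientField
    colony_owner: np.ndarray            # int lattice, -1 = uncolonized
    branch_owner: np.ndarray            # int lattice, -1 = uncolonized
    density: np.ndarray                 # c.u. per cell
    tips: list[Tip]
    # branch_id -> list of (t, x, y, W) vertices; seeds stored separately
    trajectories: dict[int, list[tuple[float, float, float, float]]]
    seeds: SeedingConfig
    consumed: dict[int, float]          # per colony, g/l * mm^2
    initial_biomass: dict[int, float]   # per colony, c.u. * mm^2
    t: float = 0.0
    next_branch_id: int = 0
    #: (t, total biomass, active tip count) summary rows, appended per step
    history: list[tuple[float, float, int]] = dc_field(default_factory=list)
    #: steps on which a tip displacement had to be capped at h
    capped_steps: int = 0

    @property
    def mask(self) -> np.ndarray:
        return self.colony_owner >= 0

    def colony_mask(self, colony_id: int) -> np.ndarray:
        return self.colony_owner == colony_id

    def active_tips(self) -> list[Tip]:
        return [tp for tp in self.tips if tp.active]

    def biomass(self, colony_id: int | None = None) -> float:
        """Biomass (c.u. * mm^2) of one colony, or of all colonies."""
        if colony_id is None:
            m = self.colony_owner >= 0
        else:
            m = self.colony_owner == colony_id
        return float(self.density[m].sum()) * self.grid.h ** 2

    def total_biomass(self) -> float:
        return self.biomass()

    def tip_positions(self, colony_id: int | None = None) -> np.ndarray:
        pts = [tp.position for tp in self.active_tips()
               if colony_id is None or tp.colony_id == colony_id]
        return np.array(pts) if pts else np.empty((0, 2))


def _disk_cells(grid: GridSpec, center, radius: float):
    """Lattice indices of cells whose center lies within the disk."""
    cx, cy = center
    h = grid.h
    j0 = max(0, int((cx - radius) / h - 1))
    j1 = min(grid.nx - 1, int((cx + radius) / h + 1))
    i0 = max(0, int((cy - radius) / h - 1))
    i1 = min(grid.ny - 1, int((cy + radius) / h + 1))
    if j1 < j0 or i1 < i0:
        return np.empty(0, int), np.empty(0, int)
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    x = (jj + 0.5) * h
    y = (ii + 0.5) * h
    inside = (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2
    return ii[inside].ravel(), jj[inside].ravel()


def _cell_of(grid: GridSpec, x: float, y: float) -> tuple[int, int]:
    return (min(int(y / grid.h), grid.ny - 1), min(int(x / grid.h), grid.nx - 1))


def _stamp(state: Colony2DState, center, radius: float, colony_id: int,
           branch_id: int, seed_density: float | None = None) -> int:
    """Claim unowned cells of the disk for (colony, branch).

    ``seed_density`` > 0 seeds the claimed cells and debits the same amount
    of biomass from the branch's existing cells (conservative transfer).
    Returns the number of newly claimed cells.
    """
    ii, jj = _disk_cells(state.grid, center, radius)
    if ii.size == 0:
        return 0
    free = state.colony_owner[ii, jj] < 0
    ii, jj = ii[free], jj[free]
    if ii.size == 0:
        return 0
    state.colony_owner[ii, jj] = colony_id
    state.branch_owner[ii, jj] = branch_id
    if seed_density is not None and seed_density > 0:
        donors = (state.branch_owner == branch_id)
        donors[ii, jj] = False
        avail = float(state.density[donors].sum())
        needed = seed_density * ii.size
        if avail > 0:
            scale = max(0.0, 1.0 - min(needed, avail) / avail)
            seeded = min(needed, avail) / ii.size
            state.density[donors] *= scale
            state.density[ii, jj] = seeded
    return int(ii.size)


def init_colony(state: Colony2DState, seed: SeedDisk, pattern: BranchPattern,
                colony_id: int) -> list[Tip]:
    """Seed one colony: stamp the inoculum disk and place the initial tips.

    ``n = max(2, round(2 pi r0 D))`` tips sit evenly spaced on the seed
    perimeter with exact outward radial headings, so the initial tip spacing
    realizes the target branch density on the seed circumference.  The
    seed-disk cells are partitioned among the initial branches by angular
    sector, giving every branch a starter trunk.
    """
    n = max(2, int(round(2.0 * np.pi * seed.radius * pattern.D)))
    cx, cy = seed.center
    tips = []
    for k in range(n):
        ang = 2.0 * np.pi * k / n
        u = np.array([np.cos(ang), np.sin(ang)])
        branch = state.next_branch_id
        state.next_branch_id += 1
        pos = np.array([cx, cy]) + seed.radius * u
        pos = np.clip(pos, [0.0, 0.0], [state.grid.Lx, state.grid.Ly])
        tip = Tip(position=pos, heading=u, colony_id=colony_id,
                  branch_id=branch, pattern=pattern)
        state.trajectories[branch] = [(state.t, pos[0], pos[1], pattern.W)]
        tips.append(tip)

    ii, jj = _disk_cells(state.grid, seed.center, seed.radius)
    if ii.size:
        x = (jj + 0.5) * state.grid.h - cx
        y = (ii + 0.5) * state.grid.h - cy
        ang = np.mod(np.arctan2(y, x), 2.0 * np.pi)
        sector = np.mod(np.round(ang / (2.0 * np.pi / n)).astype(int), n)
        free = state.colony_owner[ii, jj] < 0
        state.colony_owner[ii[free], jj[free]] = colony_id
        state.branch_owner[ii[free], jj[free]] = np.array(
            [tips[s].branch_id for s in sector[free]])
        state.density[ii[free], jj[free]] = seed.C0
    for tip in tips:
        k = _stamp(state, tip.position, pattern.W / 2.0, colony_id, tip.branch_id)
        if k:
            sel = (state.branch_owner == tip.branch_id) & (state.density == 0)
            state.density[sel] = seed.C0
    state.initial_biomass[colony_id] = state.biomass(colony_id)
    state.consumed.setdefault(colony_id, 0.0)
    state.tips.extend(tips)
    return tips


def local_tip_density(tip: Tip, state: Colony2DState,
                      mode: str = "tips") -> float:
    """Local branch density ``1/d`` at a tip, 1/mm.

    ``d`` is the distance to the nearest other active tip (any colony);
    ``mode="trajectories"`` uses the nearest vertex of any other branch's
    trajectory instead.  A lone tip has density 0 by convention.
    """
    if mode == "tips":
        others = np.array([t.position for t in state.active_tips() if t is not tip])
    elif mode == "trajectories":
        pts = [np.array(v, dtype=float)[:, 1:3]
               for b, v in state.trajectories.items() if b != tip.branch_id]
        others = np.vstack(pts) if pts else np.empty((0, 2))
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    if others.size == 0:
        return 0.0
    d = float(np.min(np.linalg.norm(others - tip.position, axis=1)))
    if d == 0.0:
        return np.inf
    return 1.0 / d


def _blend_heading(heading: np.ndarray, grad: np.ndarray, lam: float,
                   dL: float, eps_grad: float) -> np.ndarray:
    """Relax the heading toward the nutrient gradient.

    ``lam`` is an alignment rate per unit arc length (1/mm): over a path of
    length ``1/lam`` the heading forgets its history and follows the local
    gradient.  Blending per arc length (not per step) keeps the branch
    persistence length independent of the time step.
    """
    g = np.linalg.norm(grad)
    if g < eps_grad:
        return heading
    w = 1.0 - np.exp(-lam * dL)
    d = (1.0 - w) * heading + w * grad / g
    n = np.linalg.norm(d)
    return heading if n == 0 else d / n


def _rotate(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def step(state: Colony2DState, params: ModelParams,
         control: ConditionMapping | BranchPattern, dt: float,
         spec: GrowthFunctionSpec | None = None,
         budget: str = "branch",
         lam: float = 0.2,
         theta_b: float = np.pi / 6,
         eps_grad: float = 1e-9,
         eps_stop_frac: float = 0.05,
         probe_ahead: float = 8.0,
         density_mode: str = "tips",
         rng: np.random.Generator | None = None,
         jitter: float = 0.0) -> Colony2DState:
    """Advance the 2D simulation by one outer step of length ``dt`` (h)."""
    grid = state.grid
    h = grid.h
    cell_area = h * h
    yield_ratio = params.alpha_C / params.beta_N

    # 1. diffusion (sub-stepped) and consumption inside the colonized cells
    step_diffusion(state.nutrient, params.D_N, dt)
    owner = state.colony_owner
    colonized = owner >= 0
    gained = np.zeros_like(state.nutrient.values)
    if colonized.any():
        sub = state.nutrient.values[colonized]
        demand = params.beta_N * f_G(sub, state.density[colonized], params, spec) * dt
        removed = np.minimum(demand, sub)
        state.nutrient.values[colonized] = sub - removed
        state.density[colonized] += yield_ratio * removed
        gained[colonized] = yield_ratio * removed * cell_area  # c.u.*mm^2 per cell
        for cid in np.unique(owner[colonized]):
            m = owner == cid
            state.consumed[cid] = state.consumed.get(cid, 0.0) \
                + float(gained[m].sum()) / yield_ratio

    # 2. per-tip elongation increments
    active = state.active_tips()
    dLs = _extension_budgets(state, active, gained, params, budget)

    # 3. move, stamp, deactivate
    for tip, dL in zip(active, dLs):
        if dL <= 0:
            continue
        if dL > h:
            dL = h
            state.capped_steps += 1
        grad = gradient_at(state.nutrient, tuple(tip.position))
        direction = _blend_heading(tip.heading, grad, lam, dL, eps_grad)
        if jitter > 0.0 and rng is not None:
            direction = _rotate(direction, rng.normal(0.0, jitter))
        new_pos = tip.position + dL * direction
        x, y = new_pos
        if not (0.0 <= x <= grid.Lx and 0.0 <= y <= grid.Ly):
            tip.active = False
            continue
        i, j = _cell_of(grid, x, y)
        if owner[i, j] >= 0 and owner[i, j] != tip.colony_id:
            tip.active = False
            continue
        if state.nutrient.value_at(x, y) < eps_stop_frac * params.K_N:
            tip.active = False
            continue
        di, dj = _cell_of(grid, *tip.position)
        donor_density = state.density[di, dj]
        tip.position = new_pos
        tip.heading = direction
        _stamp(state, new_pos, tip.pattern.W / 2.0, tip.colony_id, tip.branch_id,
               seed_density=donor_density / 2.0)
        state.trajectories[tip.branch_id].append(
            (state.t + dt, float(x), float(y), tip.pattern.W))

    # 4. mapping refresh from the local nutrient environment: sampled a
    # short distance ahead of the tip, outside the branch's own depletion
    # skin — the concentration the branch is about to grow into
    if isinstance(control, ConditionMapping):
        for tip in state.active_tips():
            probe = tip.position + probe_ahead * tip.heading
            px = float(np.clip(probe[0], 0.0, grid.Lx))
            py = float(np.clip(probe[1], 0.0, grid.Ly))
            tip.pattern = control.lookup(state.nutrient.value_at(px, py))

    # 5. bifurcation where the local density has dropped below 2/3 D
    _bifurcate(state, theta_b, density_mode)

    state.t += dt
    state.history.append((state.t, state.total_biomass(), len(state.active_tips())))
    return state


def _extension_budgets(state: Colony2DState, tips: list[Tip],
                       gained: np.ndarray, params: ModelParams,
                       budget: str) -> np.ndarray:
    """Elongation increment dL (mm) for each active tip, this step.

    ``budget="branch"``: expansion law per branch, ``dL_b = gamma *
    Omega_b dt / W_b`` over the cells each branch owns.  ``"colony"``: one
    shared increment per colony, total cross-section = sum of tip widths.
    """
    if not tips:
        return np.empty(0)
    owner = state.colony_owner
    if budget == "colony":
        dLs = np.empty(len(tips))
        for cid in {t.colony_id for t in tips}:
            mine = [k for k, t in enumerate(tips) if t.colony_id == cid]
            G = float(gained[owner == cid].sum())
            cross = sum(tips[k].pattern.W for k in mine)
            for k in mine:
                dLs[k] = params.gamma * G / cross if cross > 0 else 0.0
        return dLs
    if budget != "branch":
        raise ValueError(f"unknown extension budget {budget!r}")
    branch_ids = np.array([t.branch_id for t in tips])
    bo = state.branch_owner
    valid = bo >= 0
    if valid.any():
        sums = np.bincount(bo[valid], weights=gained[valid],
                           minlength=int(branch_ids.max()) + 1)
    else:
        sums = np.zeros(int(branch_ids.max()) + 1)
    return np.array([params.gamma * sums[t.branch_id] / t.pattern.W
                     if t.branch_id < sums.size else 0.0
                     for t in tips])


def _bifurcate(state: Colony2DState, theta_b: float, density_mode: str) -> None:
    active = state.active_tips()
    if not active:
        return
    positions = np.array([t.position for t in active])
    if density_mode == "tips" and len(active) >= 2:
        dmat = cdist(positions, positions)
        np.fill_diagonal(dmat, np.inf)
        nearest = dmat.min(axis=1)
    else:
        nearest = np.array([
            1.0 / rho if (rho := local_tip_density(t, state, density_mode)) > 0 else np.inf
            for t in active])
    for tip, d in zip(active, nearest):
        density = 0.0 if not np.isfinite(d) else (np.inf if d == 0 else 1.0 / d)
        if density < (2.0 / 3.0) * tip.pattern.D:
            tip.active = False
            perp = np.array([-tip.heading[1], tip.heading[0]])
            child_branches = []
            for sign in (+1.0, -1.0):
                child_heading = _rotate(tip.heading, sign * theta_b)
                child_pos = tip.position + sign * (state.grid.h / 2.0) * perp
                child_pos = np.clip(child_pos, [0.0, 0.0],
                                    [state.grid.Lx, state.grid.Ly])
                branch = state.next_branch_id
                state.next_branch_id += 1
                child = Tip(position=child_pos, heading=child_heading,
                            colony_id=tip.colony_id, branch_id=branch,
                            pattern=tip.pattern)
                state.trajectories[branch] = [
                    (state.t, float(child_pos[0]), float(child_pos[1]), tip.pattern.W)]
                state.tips.append(child)
                child_branches.append((sign, branch, child_pos))
            # children inherit the parent trunk, split by side of the
            # parent's heading line, so elongation budgets stay continuous
            ii, jj = np.nonzero(state.branch_owner == tip.branch_id)
            if ii.size:
                relx = (jj + 0.5) * state.grid.h - tip.position[0]
                rely = (ii + 0.5) * state.grid.h - tip.position[1]
                side = relx * perp[0] + rely * perp[1]
                for sign, branch, _ in child_branches:
                    sel = side * sign >= 0
                    state.branch_owner[ii[sel], jj[sel]] = branch
            for sign, branch, child_pos in child_branches:
                _stamp(state, child_pos, tip.pattern.W / 2.0, tip.colony_id, branch)


def simulate_2d(params: ModelParams,
                control: ConditionMapping | BranchPattern,
                field: NutrientField,
                seeding: SeedingConfig,
                t_end: float,
                dt: float | None = None,
                spec: GrowthFunctionSpec | None = None,
                budget: str = "branch",
                lam: float = 0.2,
                theta_b: float = np.pi / 6,
                probe_ahead: float = 8.0,
                density_mode: str = "tips",
                seed: int | None = None,
                jitter: float = 0.0) -> Colony2DState:
    """Run the 2D branching simulation to ``t_end`` (or until no tip is active).

    ``control`` is either a fixed :class:`BranchPattern` applied everywhere
    or a :class:`ConditionMapping` consulted at each tip's local nutrient
    concentration.  Deterministic unless ``jitter > 0`` (heading noise with
    the given RNG ``seed``).
    """
    grid = field.grid
    seeding.validate(grid)
    dt = dt if dt is not None else grid.dt
    state = Colony2DState(grid=grid, nutrient=field,
                          colony_owner=np.full((grid.ny, grid.nx), -1, dtype=np.int32),
                          branch_owner=np.full((grid.ny, grid.nx), -1, dtype=np.int32),
                          density=np.zeros((grid.ny, grid.nx)),
                          tips=[], trajectories={}, seeds=seeding,
                          consumed={}, initial_biomass={})
    for cid, sd in enumerate(seeding.seeds):
        if isinstance(control, ConditionMapping):
            pat = control.lookup(field.value_at(*sd.center))
        else:
            pat = control
        init_colony(state, sd, pat, cid)
    rng = np.random.default_rng(seed) if seed is not None else None
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        if not state.active_tips():
            break
        step(state, params, control, dt, spec=spec, budget=budget, lam=lam,
             theta_b=theta_b, probe_ahead=probe_ahead, density_mode=density_mode,
             rng=rng, jitter=jitter)
    return state


def stamp_mask_from_trajectories(state: Colony2DState) -> np.ndarray:
    """Re-derive the colony footprint purely from seeds + stored trajectories.

    Stamping is a pure function of the trajectory vertices and their
    per-vertex widths, so this must reproduce ``state.mask`` exactly.
    """
    grid = state.grid
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    for sd in state.seeds.seeds:
        ii, jj = _disk_cells(grid, sd.center, sd.radius)
        mask[ii, jj] = True
    for verts in state.trajectories.values():
        for (_, x, y, W) in verts:
            ii, jj = _disk_cells(grid, (x, y), W / 2.0)
            mask[ii, jj] = True
    return mask
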