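"""Synthetic scenario generation: nutrient fields, seedings, test masks.

The gradient plate emulates the two-layer wedge construction used on real
swarming plates: a wedge of nutrient-bearing agar overlaid with a plain
layer yields, after depth averaging, a linear end-to-end profile, which can
optionally be smoothed further by lateral diffusion.
"""

from __future__ import annotations

import warnings

import numpy as np

from .pde import GridSpec, NutrientField, step_diffusion
from .sim2d import SeedDisk, SeedingConfig

__all__ = [
    "uniform_field",
    "gradient_field",
    "seeds_from_raster",
    "synthetic_star_mask",
]

#: center-to-center pitch of a 1,536-well microplate, mm
WELL_PITCH_1536 = 2.25


def uniform_field(N0: float, grid: GridSpec) -> NutrientField:
    """Spatially uniform nutrient field at concentration ``N0`` (g/l)."""
    if N0 < 0:
        raise ValueError("N0 must be non-negative")
    return NutrientField(grid, N0)


def gradient_field(N_left: float, N_right: float, grid: GridSpec,
                   equilibration_time: float = 0.0,
                   D_N: float = 6.0) -> NutrientField:
    """Depth-averaged two-layer wedge plate: linear ramp along x.

    ``equilibration_time`` (h) optionally applies lateral diffusion with
    diffusivity ``D_N`` on top of the ramp (which strictly reduces the
    end-to-end contrast).  The default returns the plain linear ramp.
    """
    if N_left < 0 or N_right < 0:
        raise ValueError("end concentrations must be non-negative")
    x, _ = grid.cell_centers()
    vals = N_left + (N_right - N_left) * x / grid.Lx
    fld = NutrientField(grid, vals)
    if equilibration_time > 0:
        step_diffusion(fld, D_N, equilibration_time)
    return fld


def seeds_from_raster(bitmap, grid: GridSpec,
                      spot_spacing: float = WELL_PITCH_1536,
                      r0: float = 5.0, C0: float = 1.6,
                      origin: tuple[float, float] | None = None) -> SeedingConfig:
    """One inoculum disk per set pixel of a bitmap, laid out on a dot grid.

    Pixel (row, col) maps to ``origin + (col + 0.5, rows - row - 0.5) *
    spot_spacing`` so the bitmap reads the usual way (row 0 on top).  By
    default the dot grid is centred in the domain.  Seeds falling outside
    the domain are dropped with a warning.
    """
    if isinstance(bitmap, (str, bytes)) or hasattr(bitmap, "__fspath__"):
        import imageio.v3 as iio
        bitmap = np.asarray(iio.imread(bitmap))
    bm = np.asarray(bitmap)
    if bm.ndim == 3:  # RGB(A) raster: any lit channel counts
        bm = bm[..., :3].max(axis=-1)
    bm = bm.astype(bool)
    if bm.size == 0:
        raise ValueError("empty bitmap")
    rows, cols = bm.shape
    if origin is None:
        origin = ((grid.Lx - cols * spot_spacing) / 2.0,
                  (grid.Ly - rows * spot_spacing) / 2.0)
    seeds, dropped = [], 0
    for r, c in np.argwhere(bm):
        x = origin[0] + (c + 0.5) * spot_spacing
        y = origin[1] + (rows - r - 0.5) * spot_spacing
        if 0 <= x <= grid.Lx and 0 <= y <= grid.Ly:
            seeds.append(SeedDisk(center=(float(x), float(y)), radius=r0, C0=C0))
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} seeds outside the domain", stacklevel=2)
    if not seeds:
        warnings.warn("bitmap produced no seeds", stacklevel=2)
    return SeedingConfig(seeds=seeds)


def synthetic_star_mask(n_arms: int, arm_width: float, radius: float,
                        grid: GridSpec, rotation: float = 0.0,
                        core_radius: float | None = None):
    """Synthetic branched colony: radial bars of known constant width.

    Fixture generator for the width quantifier: rasterizes ``n_arms``
    straight arms of width ``arm_width`` and length ``radius`` radiating
    from the domain center (plus a small core disk), and returns
    ``(mask, ground_truth)`` where the ground truth records the arm width
    and the center.
    """
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    # overlapping arms would make the per-arm width ill-defined
    min_r = max(arm_width, grid.h)
    if n_arms > 1 and n_arms * arm_width >= 2.0 * np.pi * min_r:
        raise ValueError("arms overlap at the sampled radii; reduce n_arms or arm_width")
    cx, cy = grid.Lx / 2.0, grid.Ly / 2.0
    x, y = grid.cell_centers()
    dx, dy = x - cx, y - cy
    rr = np.hypot(dx, dy)
    mask = np.zeros((grid.ny, grid.nx), dtype=bool)
    for k in range(n_arms):
        ang = rotation + 2.0 * np.pi * k / n_arms
        u = np.array([np.cos(ang), np.sin(ang)])
        along = dx * u[0] + dy * u[1]
        across = -dx * u[1] + dy * u[0]
        mask |= (along >= 0) & (along <= radius) & (np.abs(across) <= arm_width / 2.0)
    core = core_radius if core_radius is not None else arm_width
    mask |= rr <= core
    truth = {"arm_width": arm_width, "n_arms": n_arms, "radius": radius,
             "center": (cx, cy), "core_radius": core}
    return mask, truth
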