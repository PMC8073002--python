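"""Finite-difference nutrient field on a rectangular grid.

Explicit (FTCS) 5-point diffusion with zero-flux (reflecting) boundaries,
automatic sub-stepping to respect the stability bound ``dt <= h^2/(4 D_N)``,
and bilinearly interpolated central-difference gradients for tip steering.

Coordinates are continuous millimetres with the origin at the lower-left
corner of the domain; lattice cell ``(i, j)`` (row = y, column = x) owns the
half-open square centred at ``((j + 0.5) h, (i + 0.5) h)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["GridSpec", "NutrientField", "step_diffusion", "gradient_at"]

#: safety factor applied to the explicit stability bound when sub-stepping
_STABILITY_SAFETY = 0.95


@dataclass(frozen=True)
class GridSpec:
    """Rectangular domain and stepping parameters.

    ``Lx, Ly`` are the domain extent (mm), ``h`` the grid spacing (mm),
    ``dt`` the outer time step (h).  ``R`` is the transverse size of the
    parallel-branch model domain (mm); it only matters when scaling
    per-period biomass to a whole plate.
    """

    Lx: float = 90.0
    Ly: float = 90.0
    h: float = 0.5
    dt: float = 0.02
    R: float = 90.0

    def __post_init__(self) -> None:
        if self.h <= 0 or self.dt <= 0:
            raise ValueError("h and dt must be positive")
        if self.Lx < self.h or self.Ly < self.h:
            raise ValueError("domain must span at least one grid cell")

    @property
    def nx(self) -> int:
        return max(1, int(round(self.Lx / self.h)))

    @property
    def ny(self) -> int:
        return max(1, int(round(self.Ly / self.h)))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of cell centers, each shaped (ny, nx)."""
        x = (np.arange(self.nx) + 0.5) * self.h
        y = (np.arange(self.ny) + 0.5) * self.h
        return np.meshgrid(x, y)

    def stable_dt(self, D_N: float) -> float:
        return self.h * self.h / (4.0 * D_N)


class NutrientField:
    """2D lattice of nutrient concentrations (g/l) on a :class:`GridSpec`."""

    def __init__(self, grid: GridSpec, values: np.ndarray | float):
        self.grid = grid
        if np.isscalar(values):
            arr = np.full((grid.ny, grid.nx), float(values))
        else:
            arr = np.asarray(values, dtype=float).copy()
            if arr.shape != (grid.ny, grid.nx):
                raise ValueError(f"values shape {arr.shape} != grid shape {(grid.ny, grid.nx)}")
        if np.any(arr < 0):
            raise ValueError("nutrient concentrations must be non-negative")
        self.values = arr
        #: number of negative values clamped so far (must stay 0 in reference runs)
        self.clamp_count = 0

    def copy(self) -> "NutrientField":
        out = NutrientField(self.grid, self.values)
        out.clamp_count = self.clamp_count
        return out

    def total_mass(self) -> float:
        """Integral of the field over the domain, g/l * mm^2."""
        return float(self.values.sum()) * self.grid.h ** 2

    def clamp_negative(self) -> None:
        neg = self.values < 0
        n = int(neg.sum())
        if n:
            self.clamp_count += n
            self.values[neg] = 0.0

    def value_at(self, x: float, y: float) -> float:
        """Bilinearly interpolated concentration at a continuous point."""
        return float(_bilinear(self.values, self.grid, x, y))

    def to_text(self, path: str) -> None:
        """Write the field as delimited text plus a sidecar JSON header."""
        np.savetxt(path, self.values, delimiter=",")
        self._write_sidecar(str(path) + ".json", scale=None)

    def to_png(self, path: str) -> None:
        """Write a 16-bit grayscale raster; linear scaling in a sidecar JSON."""
        import imageio.v3 as iio
        vmax = float(self.values.max())
        scale = 65535.0 / vmax if vmax > 0 else 1.0
        img = np.round(self.values[::-1] * scale).astype(np.uint16)  # row 0 on top
        iio.imwrite(path, img)
        self._write_sidecar(str(path) + ".json", scale=scale)

    def _write_sidecar(self, path: str, scale: float | None) -> None:
        meta = {"Lx": self.grid.Lx, "Ly": self.grid.Ly, "h": self.grid.h,
                "unit": "g/l", "origin": "lower-left", "layout": "rows are y, columns are x"}
        if scale is not None:
            meta["counts_per_g_per_l"] = scale
        with open(path, "w") as fh:
            json.dump(meta, fh)


def _laplacian(v: np.ndarray, h: float) -> np.ndarray:
    # reflecting (zero-flux) boundaries via edge padding
    p = np.pad(v, 1, mode="edge")
    return (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * v) / (h * h)


def step_diffusion(field: NutrientField, D_N: float, dt: float,
                   substep: bool = True) -> NutrientField:
    """Advance pure diffusion by ``dt`` (in place) and return the field.

    Sub-divides ``dt`` whenever it exceeds the explicit stability bound;
    with ``substep=False`` an unstable ``dt`` raises instead.
    """
    limit = _STABILITY_SAFETY * field.grid.stable_dt(D_N)
    if dt <= limit:
        n, sub = 1, dt
    elif substep:
        n = int(np.ceil(dt / limit))
        sub = dt / n
    else:
        raise ValueError(
            f"dt={dt} exceeds explicit stability bound {limit:.3g}; enable sub-stepping")
    v = field.values
    h = field.grid.h
    for _ in range(n):
        v += D_N * sub * _laplacian(v, h)
    return field


def _bilinear(arr: np.ndarray, grid: GridSpec, x: float, y: float):
    """Bilinear interpolation of a cell-centered lattice at (x, y)."""
    if not (0.0 <= x <= grid.Lx and 0.0 <= y <= grid.Ly):
        raise ValueError(f"point ({x}, {y}) outside domain")
    fx = np.clip(x / grid.h - 0.5, 0.0, grid.nx - 1.0)
    fy = np.clip(y / grid.h - 0.5, 0.0, grid.ny - 1.0)
    j0 = min(int(fx), grid.nx - 2) if grid.nx > 1 else 0
    i0 = min(int(fy), grid.ny - 2) if grid.ny > 1 else 0
    tx = fx - j0
    ty = fy - i0
    j1 = min(j0 + 1, grid.nx - 1)
    i1 = min(i0 + 1, grid.ny - 1)
    return ((1 - tx) * (1 - ty) * arr[i0, j0] + tx * (1 - ty) * arr[i0, j1]
            + (1 - tx) * ty * arr[i1, j0] + tx * ty * arr[i1, j1])


def gradient_at(field: NutrientField, point: tuple[float, float]) -> np.ndarray:
    """Nutrient gradient (g/l/mm) at a continuous point.

    Central differences on the lattice (one-sided at boundaries), bilinearly
    interpolated to the query point.  Exact on linear fields at interior
    points.
    """
    x, y = point
    grid = field.grid
    gx_lattice, gy_lattice = _gradient_lattice(field)
    gx = _bilinear(gx_lattice, grid, x, y)
    gy = _bilinear(gy_lattice, grid, x, y)
    return np.array([gx, gy], dtype=float)


def _gradient_lattice(field: NutrientField) -> tuple[np.ndarray, np.ndarray]:
    v = field.values
    h = field.grid.h
    if v.shape[1] > 1:
        gx = np.gradient(v, h, axis=1)
    else:
        gx = np.zeros_like(v)
    if v.shape[0] > 1:
        gy = np.gradient(v, h, axis=0)
    else:
        gy = np.zeros_like(v)
    return gx, gy
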