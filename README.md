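# colonyopt

Coarse-grained optimization modelling of branching bacterial colony
growth, motivated by *Pseudomonas aeruginosa* swarming colonies.

Instead of deriving branches from a patterning instability, the model asks
a fitness question: among all colony geometries with branch width `W` and
branch density `D` (constrained by `W·D ≤ 1`; equality is the uniform,
non-branching colony), which maximizes total biomass at 24 h under given
growth conditions? The dynamics couple a nutrient reaction–diffusion field

    ∂N/∂t = D_N ∇²N − β_N f_G(N, C)      (inside the colony)
    ∂C/∂t = α_C f_G(N, C)                (inside the colony)

with a colony that expands its area in proportion to its total growth,
`dA/dt = γ Ω`, `Ω = ∫ α_C f_G dA`. The kernel
`f_G = N/(K_N+N) · C²/(C+C_m)` is Monod in nutrient and cooperatively
gated in cell density. A single dimensionless number,
`γ (α_C/β_N) N₀`, separates the regimes: below ~1 growth concentrates at
colony boundaries and thin branches win; above it, coverage wins and the
non-branching colony is optimal.

The package provides:

* `model1d` — the parallel-branch screening engine (one spatial period,
  exact nutrient/biomass budget);
* `optimize` — exhaustive (W, D) screens, biomass heatmaps, and the
  condition→pattern mapping `N₀ → (W*, D*)`;
* `sim2d` — a tip-tracking 2D branching simulator (gradient-following
  tips, density-triggered bifurcation at `1/d < 2/3·D`, `W/2` mask
  stamping, multi-colony seeding and avoidance) that consumes the mapping
  to predict morphologies under uniform, gradient and multi-seed
  conditions;
* `surrogate` — a scikit-learn-style neural-network emulator of the
  biomass objective (512/512/256/128, leaky ReLU 0.2, He init, Adam with
  gradient clipping, min–max scaling, 3-member ensemble) for large
  parameter screens;
* `fields` / `quantify` — scenario generators (uniform and wedge-gradient
  plates, dot-raster seedings, ground-truth star masks) and morphometrics
  (radial branch-width measurement, anti-gradient asymmetry index,
  expansion-speed fitting).

Named parameter presets (`fig2`, `fig4`, `fig5`, `fig6`, `ev3`, `ev4`)
cover the printed homogeneous, 2D-pattern, gradient-plate and multi-seed
conditions; see `docs/methods.md` for the model, its assumptions and every
numerical choice.

## Worked example

```python
import numpy as np
from colonyopt import (PRESETS, screen_WD, build_mapping, gradient_field,
                       simulate_2d, SeedingConfig, SeedDisk, GridSpec,
                       asymmetry_index)

W = np.geomspace(0.5, 10, 8)
D = np.geomspace(0.02, 0.5, 8)

# 1. nutrient-poor screen: branching is optimal
poor = screen_WD(PRESETS["fig2"], W, D)
print(poor.optimum)            # BranchPattern(W=0.5, D=0.5)   (W·D = 0.25)

# 2. nutrient-rich screen: the non-branching colony is optimal
rich = screen_WD(PRESETS["fig2"].replace(N0=30.0), W, D)
print(rich.optimum)            # BranchPattern(W=7.95, D=0.126) (W·D = 1.0)

# 3. gradient plate: map nutrient to optimal pattern, then predict 2D growth
p5 = PRESETS["fig5"]
mapping = build_mapping(p5, [0.5, 5, 10, 15, 20], W_grid=W, D_grid=D)
grid = GridSpec(Lx=90, Ly=90, h=1.0, dt=0.02)
plate = gradient_field(0.0, 20.0, grid, D_N=p5.D_N)
seeds = SeedingConfig([SeedDisk(center=(45, 45), radius=5.0, C0=1.6)])
state = simulate_2d(p5, mapping, plate, seeds, t_end=16.0)
print(asymmetry_index(state.mask, grid, (45, 45), axis=(1, 0)))
# 1.5217  -> the colony reached ~1.5x farther toward the LOW-nutrient side
```

The first two prints are the regime flip: under scarce nutrient the argmax
sits strictly inside the `W·D < 1` branching region, under abundant
nutrient it sits on the non-branching diagonal. The last number is the
anti-gradient asymmetry index — extent toward the low-nutrient end divided
by extent toward the high-nutrient end — whose value above 1 reproduces the
counterintuitive faster expansion into scarcity (thin sparse branches
elongate faster than wide fronts at comparable growth).

A thin CLI wraps the same functions:

```bash
colonyopt screen --params fig2 --n-w 8 --n-d 8 --out heatmap.csv
colonyopt simulate-2d --params fig5 --field gradient:0:20 --t-end 16 --out run
colonyopt measure --mask run_mask.csv --h 1.0
```

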