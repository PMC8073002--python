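# Methods

## The model

`colonyopt` treats branching pattern formation in surface-growing bacterial
colonies (the motivating organism is *Pseudomonas aeruginosa* on soft-agar
swarming plates) as an optimization problem rather than an emergent
instability: the branch geometry is *imposed* by two parameters — branch
width `W` (mm) and branch density `D` (branches per mm transverse to
extension) — and the model asks which (W, D) maximizes total biomass at a
fixed time under given growth conditions. Branches cannot overfill the
cross-section, so `W·D ≤ 1`; equality is the uniform, non-branching colony.

Three coupled processes drive the dynamics on a rectangular domain:

1. **Nutrient** `N(x, t)` (g/l) diffuses with diffusivity `D_N` (mm²/h) and
   is consumed inside the colony at rate `β_N f_G(N, C)` (g/l/h), where
   `β_N` has units g/l/h per c.u. Boundaries are zero-flux (a closed
   plate).
2. **Cell density** `C(x, t)` (c.u., an opaque areal density unit) grows
   inside the colony at `α_C f_G(N, C)` (c.u./h). Growth and consumption
   share the kernel `f_G`, so biomass gained and nutrient removed are
   locked by the yield ratio `α_C/β_N` — a budget identity the solvers
   maintain to round-off by construction (both are computed from the same
   clamped per-cell consumption).
3. **Expansion.** The colony's *area* expands proportionally to its total
   growth rate `Ω = ∫ α_C f_G dA`:

       dA/dt = γ · Ω

   with expansion efficiency `γ` (experimentally tuned by agar density, the
   surface-wetness proxy). For a parallel branch of width `W` this is
   `dL/dt = γ Ω_period / W`; for a 2D branch, `dL_b/dt = γ Ω_b / W_b` over
   the cells that branch owns. Equivalently `dL/dt = γ (Ω/A) L`: the front
   is exponential while the whole colony is fed and stalls to a
   diffusion-limited crawl when only the boundary is. We considered the
   alternative reading `dL/dt = γ Ω/A` (no area proportionality) and
   rejected it on first principles: it bounds *total* expansion by
   `∫A dL = γ ΔB`, which for realistic parameter magnitudes pins every
   colony at a few millimetres regardless of conditions and erases the
   regime structure the model exists to produce.

### The growth kernel

    f_G(N, C) = N/(K_N + N) · C²/(C + C_m)

Monod in nutrient (half-saturation `K_N`, g/l) and cooperatively gated in
density: the per-capita rate `α_C · C/(C + C_m)` saturates at `α_C` for
dense populations and falls off linearly below the saturation density
`C_m`. The density gating is the Allee-type cooperativity characteristic of
swarming (surfactant production and collective movement require local
density), and it matters structurally: freshly colonized edges are dilute,
so a front that advances faster than its cells can regrow is self-limiting.
That self-limitation is what makes an *interior* optimal branch width exist
and rise with nutrient; with an amplitude-saturated kernel
(`f_G ≤ C_m`, available as `GrowthFunctionSpec("monod_saturating")`) the
thinnest representable branch is always optimal in the poor regime and no
width gradient can form across a nutrient ramp. The kernel is a strategy
object; solvers only assume it vanishes when either argument does and is
monotone in both.

### Density bookkeeping

Cell density accumulates *locally* (`allocation="local"`, the default):
each lattice cell keeps its own `C`, and when the front claims a new cell
the donor cell behind it is split in half — a biomass-conserving Fisher-like
front with dilute edges and dense fed interiors. The alternative reading of
"biomass is uniformly allocated within the entire colony"
(`allocation="uniform"`, `C = B/A` everywhere) is retained as an option but
cannot reproduce the regime flip: redistributing density erases the
front/interior distinction that separates boundary-fed from area-fed
growth.

### The phase boundary

The combination `γ·(α_C/β_N)·N₀` is dimensionless (mm of front advance
bought per mm of front supplied) and controls the regime:

* `γ (α_C/β_N) N₀ < 1` — the uniform front cannot sustain itself on the
  nutrient it sweeps; growth concentrates at fronts and edges, and thin
  branches (large fed perimeter per area, small `W` divisor in the
  expansion law) win. Nutrient-poor default conditions
  (`N₀ = 8, γ = 7.5`): 0.30.
* `γ (α_C/β_N) N₀ ≳ 1` — the whole covered area stays productive long
  enough for the front to outrun depletion; coverage wins and the
  non-branching colony is optimal. `N₀ = 30`: 1.13; `γ = 25`: 1.00.

## Screening and the condition→pattern mapping

`screen_WD` runs one period of the parallel-branch engine per (W, D) cell:
a strip of height `1/D` with one branch of width `W` centred in it,
extending from a one-cell-deep *full-width* inoculum strip at density
`C0 = 0.5` c.u. (every pattern starts from the same inoculum; a
branch-only stub would hand non-branching colonies a spurious initial
biomass advantage of order `1/(WD)`). Whole-plate biomass is per-period
biomass times the number of periods on a plate of transverse size
`R = 90` mm. Cells with `W·D > 1` are evaluated as the uniform colony.

Default screening domain: runway `Lx = 20` mm, `h = 1` mm, `dt = 0.02` h,
scored at `t = 24` h. The runway is chosen so that well-fed colonies
complete it within the scoring horizon, as colonies on real plates reach
the dish boundary; on a much longer runway the abundant-nutrient regimes
never finish and near-diagonal geometries pick up a ~1% edge-access
artifact.

**Argmax regularization.** Biomass values within 0.5% of the maximum are
treated as tied (the heatmap's rasterization noise is of that order, and in
abundant regimes the objective genuinely plateaus at total-consumption).
If the uniform colony attains the plateau it is reported (a flat maximum
touching the diagonal means branching buys nothing); a near-flat matrix
(span < 2% — e.g. a starved environment) never claims the diagonal.
Remaining ties break toward smaller W, then smaller D. `rel_tol=0` recovers
the exact argmax.

`build_mapping` screens several `N₀` levels and tabulates `(W*, D*)`;
queries interpolate linearly and clamp at the ends, with interpolated
patterns projected back under `W·D ≤ 1`.

## The 2D tip engine

Branches are tips with positions, unit headings and per-tip (W, D); the
colony mask is the union of `W/2`-radius disks stamped along tip
trajectories (stamping is a pure function of the stored trajectories — a
round-trip test reconstructs the mask exactly). Per step: diffusion and
clamped consumption on the shared field; per-branch elongation
`dL_b = γ Ω_b dt / W_b` (trunk cell ownership is inherited across
bifurcations, split by side of the parent heading, so budgets stay
continuous); tip movement along a blend of the previous heading and the
local nutrient gradient; disk stamping with biomass-conserving edge
seeding; bifurcation into two tips (headings rotated ±30°, a declared
knob) when the local branch density `1/d` — `d` the distance to the nearest
other active tip — falls below `2/3·D`; deactivation at the domain
boundary, on starvation (`N < 0.05 K_N`), or on contact with another
colony's mask, which is what makes neighbouring colonies avoid each other.

Numerical choices that required a decision:

* **Heading persistence per arc length.** The gradient-blend weight is
  `1 − exp(−λ·dL)` per step with `λ = 0.2`/mm (persistence length 5 mm).
  Blending per *step* would make branch stiffness depend on `dt`; with
  1,000 steps per run any fixed per-step weight collapses headings onto
  the gradient within minutes of simulated time, sibling branches never
  diverge after a bifurcation, and the tip-density band is violated.
* **Mapping probe.** When a condition→pattern mapping controls the tips,
  each tip reads the *current* nutrient field a catchment-scale distance
  ahead of itself (`probe_ahead = 8` mm along the heading, clamped to the
  domain) — the concentration it is about to grow into. Sampling at the tip
  itself always reads the branch's own freshly depleted halo, which blinds
  the control loop (no width asymmetry can form on a gradient plate).
  `probe_ahead = 0` recovers the naive reading.
* **Children at a bifurcation** are offset ±`h/2` perpendicular to the
  parent heading (coincident children would make nearest-neighbour
  distances zero).
* Tip displacements are capped at one lattice cell per step (counted in
  `capped_steps`; zero in all reference runs).

Anti-gradient expansion on a two-layer wedge plate (linear 0→20 g/l ramp)
emerges from the mapping: low-nutrient-side tips get thin sparse branches
which, at comparable per-branch growth, elongate faster
(`dL ∝ 1/W`), while rich-side tips get wide near-uniform fronts. The
asymmetry index (extent toward the low end over extent toward the high
end) is ≈ 1.5 for the gradient-plate preset and ≈ 0.4 for a high-γ
control, which expands fastest where nutrient is plentiful.

## Surrogate

A numpy implementation of the screening emulator: 9 inputs
(`D_N, β_N, α_C, K_N, C_m, γ, N₀, W, D`) → biomass, four hidden layers
512/512/256/128, leaky-ReLU slope 0.2, He initialization, Adam (lr 1e-3)
with global-norm gradient clipping, per-column min–max scaling of inputs
and target, three members averaged into the ensemble prediction. Unstated
training details are package defaults: MSE loss, batch 64 (tests use 128),
500 epochs with early stopping on a 10% validation split. Training tables
come from `build_training_set` (uniform sampling over ranges bracketing
the named presets by ±50%, one direct simulation per row); the test-scale
benchmark uses 40 parameter sets × a 5×5 (W, D) grid (1,000 rows), which
reaches held-out rank correlation ≈ 0.99 against the simulator in about
half a minute of training. The surrogate is an optional accelerator: every
consumer (`build_mapping`, `classify_anti_gradient`, `screen_parameters`)
also runs against the direct simulator.

## What the synthetic scenarios do and do not emulate

`fields.gradient_field` collapses the two-layer wedge plate to its
depth-averaged linear profile (optionally diffusion-smoothed);
`seeds_from_raster` lays inoculum disks on a 2.25-mm dot pitch (the
1,536-well template); `synthetic_star_mask` provides ground-truth branched
masks for the quantifier. None of these model agar mechanics, surface
wetness fields, rhamnolipid transport or branch initiation from
instability — `γ` is the sole wetness proxy, and branch geometry is always
imposed, never emergent. Passing tests therefore certify the optimization
logic and the solvers, not a mechanistic account of swarming; on real plate
images the quantifier additionally inherits whatever illumination and
segmentation artifacts produced the input mask.

## Problem sizes used by the tests and the acceptance script

Screens are 8×8 over `W ∈ [0.5, 10]` mm, `D ∈ [0.02, 0.5]`/mm at
`h = 1` mm on the 20-mm runway (the package default grid is 20×20 over
`D ∈ [0.01, 0.5]`); 2D runs use the full 90×90 mm plate at `h = 1` mm,
`dt = 0.02` h, 16 h horizon; the surrogate benchmark is the 1,000-row
table above; the morphometric check uses a 6-arm star of 3-mm arms at
`h = 0.25` mm. These sizes were chosen as the smallest at which the
regime structure, the density band and the surrogate accuracy are stable;
finer grids sharpen the same answers.

## Known limitations

* `W` below the lattice pitch rasterizes to one cell, so distinct sub-pitch
  widths tie in screens (reported optima can sit at the grid floor).
* The near-degenerate constant-`WD` ridge of the branching regime means the
  reported `(W*, D*)` cell is tolerance-regularized; the attained biomass
  is insensitive to the choice along the ridge.
* Expansion speed inherits lattice anisotropy of order `h` per branch;
  mass-centre drift in symmetric runs stays below two cells.
* The density-split front is first-order in `h`; the yield identity is
  exact regardless.
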