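"""Model parameters and the local growth/consumption kinetics.

The kinetics shared by every engine in this package are a Monod factor in
the nutrient ``N`` and a cooperatively gated factor in the areal cell
density ``C``:

    f_G(N, C) = N / (K_N + N) * C**2 / (C + C_m)

``f_G`` carries cell-density units (c.u.).  The per-capita growth rate
``alpha_C * f_G / C`` saturates at ``alpha_C`` for dense populations with
half-saturation at ``C = C_m`` — sparse cells grow disproportionately
slowly, the Allee-type cooperativity characteristic of swarming (surfactant
production and collective movement need local density).  This gating is
what makes dilute, fast-advancing colony edges self-limiting, so an optimal
branch width exists and increases with nutrient.  Cell growth is
``alpha_C * f_G`` (c.u./h) and nutrient consumption is ``beta_N * f_G``
(g/l/h), so the yield ratio ``alpha_C / beta_N`` links biomass gained to
nutrient removed exactly.

The exact algebraic form of the growth kernel is a configurable strategy
(:class:`GrowthFunctionSpec`), because only its qualitative shape (zero at
zero, monotone in both arguments) is pinned down by the model; solvers
depend on the interface, not the formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields as dc_fields
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "GrowthFunctionSpec",
    "PRESETS",
    "f_G",
    "growth_rate",
    "consumption_rate",
    "load_params",
]


@dataclass(frozen=True)
class ModelParams:
    """The seven environmental/physiological constants of the growth model.

    Attributes
    ----------
    D_N : float
        Nutrient diffusivity, mm^2/h.
    beta_N : float
        Nutrient consumption rate, g/l/h per c.u.
    alpha_C : float
        Cell growth rate, 1/h.
    K_N : float
        Half-saturation nutrient concentration, g/l.
    C_m : float
        Cell-density saturation constant, c.u.
    gamma : float
        Colony expansion efficiency, mm/h per c.u.  Experimentally a proxy
        for surface wetness (agar density).
    N0 : float
        Initial nutrient concentration, g/l.
    """

    D_N: float
    beta_N: float
    alpha_C: float
    K_N: float
    C_m: float
    gamma: float
    N0: float

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "N0":
                # the initial nutrient concentration is a state, not a rate:
                # an empty plate (N0 = 0) is a legitimate degenerate input
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"ModelParams.N0 must be non-negative, got {v!r}")
            elif not np.isfinite(v) or v <= 0:
                raise ValueError(f"ModelParams.{f.name} must be strictly positive, got {v!r}")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def as_tuple(self):
        return (self.D_N, self.beta_N, self.alpha_C, self.K_N, self.C_m, self.gamma, self.N0)


#: Named parameter presets.  "fig2" is the homogeneous screening condition
#: (nutrient-poor default N0 = 8 g/l, gamma = 7.5); "fig4" the 2D
#: branching-pattern condition; "fig5" the gradient-plate condition
#: (gamma = 7.513); "fig6" the multi-seed condition (gamma = 4,
#: N0 = 14.5 g/l); "ev3" and "ev4" the fixed-pattern and diverse-pattern
#: gallery conditions.
PRESETS: dict[str, ModelParams] = {
    "fig2": ModelParams(D_N=6.0, beta_N=160.0, alpha_C=0.8, K_N=0.8, C_m=0.05, gamma=7.5, N0=8.0),
    "fig4": ModelParams(D_N=6.951, beta_N=216.9, alpha_C=1.486, K_N=1.156, C_m=0.0548, gamma=7.5, N0=8.0),
    "fig5": ModelParams(D_N=5.749, beta_N=195.5, alpha_C=1.105, K_N=0.6635, C_m=0.07890, gamma=7.513, N0=8.0),
    "fig6": ModelParams(D_N=5.749, beta_N=195.5, alpha_C=1.105, K_N=0.6635, C_m=0.07890, gamma=4.0, N0=14.5),
    "ev3": ModelParams(D_N=9.0, beta_N=160.0, alpha_C=1.2, K_N=0.8, C_m=0.05, gamma=7.5, N0=8.0),
    "ev4": ModelParams(D_N=9.326, beta_N=152.9, alpha_C=1.878, K_N=0.8466, C_m=0.06050, gamma=7.385, N0=8.0),
}


def _monod_cooperative(N, C, K_N: float, C_m: float):
    N = np.asarray(N, dtype=float)
    C = np.asarray(C, dtype=float)
    return (N / (K_N + N)) * (C * C / (C + C_m))


def _monod_saturating(N, C, K_N: float, C_m: float):
    N = np.asarray(N, dtype=float)
    C = np.asarray(C, dtype=float)
    return (N / (K_N + N)) * (C * C_m / (C + C_m))


@dataclass(frozen=True)
class GrowthFunctionSpec:
    """Strategy object selecting the algebraic form of the growth kernel.

    ``form="monod_cooperative"`` is the default described in the module
    docstring.  ``form="monod_saturating"`` caps the kernel at ``C_m``
    (per-capita rate decreasing in C); ``form="monod_linear"`` drops the
    C-dependence beyond proportionality.  Custom forms can be registered in
    :attr:`FORMS`.
    """

    form: str = "monod_cooperative"

    FORMS = {
        "monod_cooperative": _monod_cooperative,
        "monod_saturating": _monod_saturating,
        "monod_linear": lambda N, C, K_N, C_m: (np.asarray(N, float) / (K_N + np.asarray(N, float))) * np.asarray(C, float),
    }

    def __call__(self, N, C, K_N: float, C_m: float):
        try:
            fn = self.FORMS[self.form]
        except KeyError:
            raise ValueError(f"unknown growth-function form {self.form!r}") from None
        return fn(N, C, K_N, C_m)


_DEFAULT_SPEC = GrowthFunctionSpec()


def _check_domain(N, C) -> None:
    if np.any(np.asarray(N) < 0):
        raise ValueError("nutrient concentration N must be non-negative")
    if np.any(np.asarray(C) < 0):
        raise ValueError("cell density C must be non-negative")


def f_G(N, C, params: ModelParams, spec: GrowthFunctionSpec | None = None):
    """Growth kernel, c.u.  Zero when either ``N`` or ``C`` is zero."""
    _check_domain(N, C)
    spec = spec or _DEFAULT_SPEC
    return spec(N, C, params.K_N, params.C_m)


def growth_rate(N, C, params: ModelParams, spec: GrowthFunctionSpec | None = None):
    """Cell growth rate ``alpha_C * f_G``, c.u./h."""
    return params.alpha_C * f_G(N, C, params, spec)


def consumption_rate(N, C, params: ModelParams, spec: GrowthFunctionSpec | None = None):
    """Nutrient consumption rate ``beta_N * f_G``, g/l/h.

    Callers apply this only inside the colony mask.
    """
    return params.beta_N * f_G(N, C, params, spec)


def load_params(source: str) -> ModelParams:
    """Load parameters from a preset name or a YAML/JSON config file.

    A config file may set ``preset: <name>`` and override any subset of the
    seven fields.
    """
    if source in PRESETS:
        return PRESETS[source]
    with open(source) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = PRESETS[cfg.pop("preset")] if "preset" in cfg else None
    names = {f.name for f in dc_fields(ModelParams)}
    unknown = set(cfg) - names
    if unknown:
        raise ValueError(f"unknown parameter keys in {source}: {sorted(unknown)}")
    if base is not None:
        return base.replace(**cfg)
    return ModelParams(**cfg)
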