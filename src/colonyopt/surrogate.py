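"""Neural-network emulator of the biomass objective and parameter screening.

The emulator maps the 9-vector (D_N, beta_N, alpha_C, K_N, C_m, gamma, N0,
W, D) to the 24-h whole-plate biomass of the parallel-branch model.  The
network is a fully connected 512-512-256-128 stack with leaky-rectifier
activations (negative slope 0.2), He initialization, Adam with gradient
clipping, and per-input min-max scaling; three members trained from
different initializations are averaged into an ensemble prediction.  It is
implemented directly on numpy and exposed as scikit-learn estimators
(``fit`` / ``predict`` / ``get_params``), so it composes with sklearn model
selection.

The surrogate is an optional accelerator: every consumer also accepts the
direct simulator backend, because trained weights are disposable — the
recipe is what matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .fields import gradient_field
from .growth import ModelParams, PRESETS
from .model1d import BranchPattern
from .optimize import ConditionMapping, OptimizationResult, _argmax_pattern, screen_WD
from .pde import GridSpec
from .quantify import asymmetry_index
from .sim2d import SeedDisk, SeedingConfig, simulate_2d

__all__ = [
    "INPUT_COLUMNS",
    "MLPBiomassSurrogate",
    "SurrogateEnsemble",
    "build_training_set",
    "train_ensemble",
    "predict",
    "ScreenRecord",
    "screen_parameters",
    "default_parameter_ranges",
]

INPUT_COLUMNS = ("D_N", "beta_N", "alpha_C", "K_N", "C_m", "gamma", "N0", "W", "D")


class _MinMaxColumns:
    """Per-column min-max scaling to [0, 1] with exact round-trip."""

    def fit(self, X: np.ndarray) -> "_MinMaxColumns":
        self.lo_ = X.min(axis=0)
        span = X.max(axis=0) - self.lo_
        if np.any(span == 0):
            cols = np.nonzero(span == 0)[0].tolist()
            raise ValueError(f"constant input column(s) {cols}: min-max scaling undefined")
        self.span_ = span
        return self

    def transform(self, X):
        return (X - self.lo_) / self.span_

    def inverse(self, Z):
        return Z * self.span_ + self.lo_


class _MLP:
    """Minimal fully connected net: leaky ReLU, He init, Adam, MSE loss."""

    def __init__(self, sizes, slope: float, rng: np.random.Generator):
        self.slope = slope
        self.W = [rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
                  for n_in, n_out in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(n_out) for n_out in sizes[1:]]

    def forward(self, X):
        acts = [X]
        a = X
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = z if k == len(self.W) - 1 else np.where(z > 0, z, self.slope * z)
            acts.append(a)
        return acts

    def backward(self, acts, err):
        """Gradients of mean squared error; ``err = (pred - y) * 2 / n``."""
        gW, gb = [None] * len(self.W), [None] * len(self.b)
        delta = err
        for k in range(len(self.W) - 1, -1, -1):
            gW[k] = acts[k].T @ delta
            gb[k] = delta.sum(axis=0)
            if k > 0:
                da = delta @ self.W[k].T
                a = acts[k]
                delta = da * np.where(a > 0, 1.0, self.slope)
        return gW, gb


def _adam_update(params, grads, m, v, step, lr, clip, beta1=0.9, beta2=0.999, eps=1e-8):
    norm = np.sqrt(sum(float((g * g).sum()) for g in grads))
    if clip and norm > clip:
        grads = [g * (clip / norm) for g in grads]
    for p, g, mk, vk in zip(params, grads, m, v):
        mk *= beta1
        mk += (1 - beta1) * g
        vk *= beta2
        vk += (1 - beta2) * g * g
        mhat = mk / (1 - beta1 ** step)
        vhat = vk / (1 - beta2 ** step)
        p -= lr * mhat / (np.sqrt(vhat) + eps)


class MLPBiomassSurrogate(BaseEstimator, RegressorMixin):
    """Single-network biomass emulator (one member of the ensemble).

    Parameters mirror the training recipe: ``hidden_layers=(512, 512, 256,
    128)``, ``negative_slope=0.2``, ``learning_rate=1e-3`` with Adam and
    global-norm gradient clipping, min-max scaled inputs (targets are also
    min-max scaled internally and inverse-transformed on predict).
    """

    def __init__(self, hidden_layers=(512, 512, 256, 128), negative_slope=0.2,
                 learning_rate=1e-3, epochs=500, batch_size=64, clip_norm=1.0,
                 validation_fraction=0.1, patience=50, random_state=0):
        self.hidden_layers = hidden_layers
        self.negative_slope = negative_slope
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.clip_norm = clip_norm
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        rng = np.random.default_rng(self.random_state)
        self.x_scaler_ = _MinMaxColumns().fit(X)
        self.y_scaler_ = _MinMaxColumns().fit(y[:, None])
        Xs = self.x_scaler_.transform(X)
        ys = self.y_scaler_.transform(y[:, None])

        n = Xs.shape[0]
        n_val = int(round(self.validation_fraction * n))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = Xs[tr_idx], ys[tr_idx]
        Xval, yval = Xs[val_idx], ys[val_idx]

        sizes = [X.shape[1], *self.hidden_layers, 1]
        net = _MLP(sizes, self.negative_slope, rng)
        params = net.W + net.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]

        self.loss_curve_ = []
        self.validation_curve_ = []
        best_val, best_snapshot, since_best = np.inf, None, 0
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xtr))
            ep_loss = 0.0
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                acts = net.forward(Xtr[idx])
                resid = acts[-1] - ytr[idx]
                ep_loss += float((resid ** 2).sum())
                gW, gb = net.backward(acts, 2.0 * resid / len(idx))
                step += 1
                _adam_update(params, gW + gb, m, v, step, self.learning_rate, self.clip_norm)
            self.loss_curve_.append(ep_loss / len(Xtr))
            if len(Xval):
                val = float(((net.forward(Xval)[-1] - yval) ** 2).mean())
                self.validation_curve_.append(val)
                if val < best_val - 1e-12:
                    best_val, since_best = val, 0
                    best_snapshot = ([w.copy() for w in net.W], [b.copy() for b in net.b])
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if best_snapshot is not None:
            net.W, net.b = best_snapshot
        self.net_ = net
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected 2D input with {self.n_features_in_} columns")
        zs = self.net_.forward(self.x_scaler_.transform(X))[-1]
        return self.y_scaler_.inverse(zs).ravel()


class SurrogateEnsemble(BaseEstimator, RegressorMixin):
    """Mean of ``n_members`` independently initialized surrogates."""

    def __init__(self, n_members=3, random_state=0, **member_kwargs):
        self.n_members = n_members
        self.random_state = random_state
        self.member_kwargs = member_kwargs

    def fit(self, X, y):
        self.members_ = []
        for k in range(self.n_members):
            member = MLPBiomassSurrogate(random_state=self.random_state + 1000 * k,
                                         **self.member_kwargs)
            member.fit(X, y)
            self.members_.append(member)
        self.n_features_in_ = self.members_[0].n_features_in_
        return self

    def predict(self, X):
        check_is_fitted(self, "members_")
        return np.mean([m.predict(X) for m in self.members_], axis=0)

    def save(self, path: str) -> None:
        """Serialize weights + scaling metadata to one JSON container."""
        payload = {"n_members": len(self.members_), "members": []}
        for m in self.members_:
            payload["members"].append({
                "hidden_layers": list(m.hidden_layers),
                "negative_slope": m.negative_slope,
                "W": [w.tolist() for w in m.net_.W],
                "b": [b.tolist() for b in m.net_.b],
                "x_lo": m.x_scaler_.lo_.tolist(), "x_span": m.x_scaler_.span_.tolist(),
                "y_lo": m.y_scaler_.lo_.tolist(), "y_span": m.y_scaler_.span_.tolist(),
            })
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "SurrogateEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        ens = cls(n_members=payload["n_members"])
        ens.members_ = []
        for rec in payload["members"]:
            m = MLPBiomassSurrogate(hidden_layers=tuple(rec["hidden_layers"]),
                                    negative_slope=rec["negative_slope"])
            net = _MLP([1, 1], rec["negative_slope"], np.random.default_rng(0))
            net.W = [np.array(w) for w in rec["W"]]
            net.b = [np.array(b) for b in rec["b"]]
            m.net_ = net
            m.x_scaler_ = _MinMaxColumns()
            m.x_scaler_.lo_ = np.array(rec["x_lo"])
            m.x_scaler_.span_ = np.array(rec["x_span"])
            m.y_scaler_ = _MinMaxColumns()
            m.y_scaler_.lo_ = np.array(rec["y_lo"])
            m.y_scaler_.span_ = np.array(rec["y_span"])
            m.n_features_in_ = net.W[0].shape[0]
            ens.members_.append(m)
        ens.n_features_in_ = ens.members_[0].n_features_in_
        return ens


def default_parameter_ranges(base: ModelParams | None = None,
                             spread: float = 0.5) -> dict[str, tuple[float, float]]:
    """Sampling ranges bracketing the named presets by ±``spread``."""
    presets = [base] if base is not None else list(PRESETS.values())
    ranges = {}
    for name in INPUT_COLUMNS[:7]:
        vals = [getattr(p, name) for p in presets]
        ranges[name] = (min(vals) * (1 - spread), max(vals) * (1 + spread))
    return ranges


def build_training_set(n_sets: int, W_grid, D_grid,
                       ranges: dict[str, tuple[float, float]] | None = None,
                       seed: int = 0, grid: GridSpec | None = None,
                       t_end: float = 24.0, C0: float = 0.5) -> pd.DataFrame:
    """Simulate ``n_sets`` random environments over a (W, D) grid.

    Returns a DataFrame with the nine input columns plus ``biomass``
    (whole-plate c.u. mm^2 at ``t_end``), one row per (parameter set, W, D)
    combination.  Deterministic for a fixed ``seed``.
    """
    ranges = ranges or default_parameter_ranges()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_sets):
        kw = {name: rng.uniform(*ranges[name]) for name in INPUT_COLUMNS[:7]}
        p = ModelParams(**kw)
        res = screen_WD(p, W_grid=W_grid, D_grid=D_grid, t_end=t_end, grid=grid, C0=C0)
        for i, W in enumerate(res.W_grid):
            for j, D in enumerate(res.D_grid):
                rows.append({**kw, "W": W, "D": D, "biomass": res.biomass[i, j]})
    return pd.DataFrame(rows, columns=[*INPUT_COLUMNS, "biomass"])


def train_ensemble(table: pd.DataFrame, seed: int = 0,
                   **member_kwargs) -> SurrogateEnsemble:
    """Train the 3-member ensemble on a training table from
    :func:`build_training_set`."""
    if len(table) < 100:
        raise ValueError("need at least 100 rows for meaningful training")
    X = table[list(INPUT_COLUMNS)].to_numpy(dtype=float)
    y = table["biomass"].to_numpy(dtype=float)
    ens = SurrogateEnsemble(random_state=seed, **member_kwargs)
    return ens.fit(X, y)


def predict(ensemble: SurrogateEnsemble, vec) -> float:
    """Ensemble biomass prediction for one 9-vector."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size != len(INPUT_COLUMNS):
        raise ValueError(f"expected a {len(INPUT_COLUMNS)}-vector, got {vec.size} values")
    return float(ensemble.predict(vec[None, :])[0])


def surrogate_screen(ensemble: SurrogateEnsemble, params: ModelParams,
                     W_grid, D_grid, t_end: float = 24.0) -> OptimizationResult:
    """Surrogate-evaluated (W, D) screen with the same result type as the
    direct one."""
    W_grid = np.asarray(W_grid, float)
    D_grid = np.asarray(D_grid, float)
    base = [getattr(params, n) for n in INPUT_COLUMNS[:7]]
    X = np.array([[*base, W, D] for W in W_grid for D in D_grid])
    B = ensemble.predict(X).reshape(W_grid.size, D_grid.size)
    return OptimizationResult(W_grid=W_grid, D_grid=D_grid, biomass=B,
                              optimum=_argmax_pattern(W_grid, D_grid, B),
                              params=params, t_end=t_end)


@dataclass
class ScreenRecord:
    """One screened parameter set and its gradient-plate classification."""

    params: ModelParams
    mapping: ConditionMapping
    asymmetry: float
    anti_gradient: bool


def screen_parameters(n_sets: int,
                      ranges: dict[str, tuple[float, float]] | None = None,
                      gradient: tuple[float, float] = (0.0, 20.0),
                      seed: int = 0,
                      backend: SurrogateEnsemble | None = None,
                      N0_levels=None,
                      W_grid=None, D_grid=None,
                      grid: GridSpec | None = None,
                      sim_grid: GridSpec | None = None,
                      t_end_1d: float = 24.0,
                      t_end_2d: float = 16.0,
                      seed_radius: float = 5.0,
                      C0_2d: float = 1.6) -> list[ScreenRecord]:
    """Anti-gradient screening workflow over random parameter sets.

    For each sampled environment: build the condition-to-pattern mapping
    (direct simulation, or surrogate-evaluated screens when ``backend`` is
    given), simulate the 2D gradient plate, and classify the colony as
    anti-gradient when the asymmetry index exceeds 1.
    """
    ranges = ranges or default_parameter_ranges()
    rng = np.random.default_rng(seed)
    if N0_levels is None:
        N0_levels = np.linspace(max(gradient[0], 0.5), gradient[1], 5)
    if W_grid is None:
        W_grid = np.geomspace(0.5, 10.0, 8)
    if D_grid is None:
        D_grid = np.geomspace(0.02, 0.5, 8)
    records = []
    for _ in range(n_sets):
        kw = {name: rng.uniform(*ranges[name]) for name in INPUT_COLUMNS[:7]}
        p = ModelParams(**kw)
        rec = classify_anti_gradient(p, gradient=gradient, backend=backend,
                                     N0_levels=N0_levels, W_grid=W_grid, D_grid=D_grid,
                                     grid=grid, sim_grid=sim_grid, t_end_1d=t_end_1d,
                                     t_end_2d=t_end_2d, seed_radius=seed_radius,
                                     C0_2d=C0_2d)
        records.append(rec)
    return records


def classify_anti_gradient(params: ModelParams,
                           gradient: tuple[float, float] = (0.0, 20.0),
                           backend: SurrogateEnsemble | None = None,
                           N0_levels=None,
                           W_grid=None, D_grid=None,
                           grid: GridSpec | None = None,
                           sim_grid: GridSpec | None = None,
                           t_end_1d: float = 24.0,
                           t_end_2d: float = 16.0,
                           seed_radius: float = 5.0,
                           C0_2d: float = 1.6,
                           budget: str = "local") -> ScreenRecord:
    """Map, simulate the gradient plate, and classify one parameter set."""
    if N0_levels is None:
        N0_levels = np.linspace(max(gradient[0], 0.5), gradient[1], 5)
    if W_grid is None:
        W_grid = np.geomspace(0.5, 10.0, 8)
    if D_grid is None:
        D_grid = np.geomspace(0.02, 0.5, 8)
    from .optimize import build_mapping  # local import to avoid cycle confusion
    if backend is not None:
        mapping = build_mapping(
            params, N0_levels,
            screen_fn=lambda p: surrogate_screen(backend, p, W_grid, D_grid, t_end_1d))
    else:
        mapping = build_mapping(params, N0_levels, W_grid=W_grid, D_grid=D_grid,
                                t_end=t_end_1d, grid=grid)
    sim_grid = sim_grid or GridSpec(Lx=90.0, Ly=90.0, h=1.0, dt=0.02)
    fld = gradient_field(gradient[0], gradient[1], sim_grid, D_N=params.D_N)
    center = (sim_grid.Lx / 2.0, sim_grid.Ly / 2.0)
    seeding = SeedingConfig([SeedDisk(center=center, radius=seed_radius, C0=C0_2d)])
    state = simulate_2d(params, mapping, fld, seeding, t_end=t_end_2d, budget=budget)
    idx = asymmetry_index(state.mask, sim_grid, center, axis=(1.0, 0.0))
    return ScreenRecord(params=params, mapping=mapping, asymmetry=idx,
                        anti_gradient=bool(idx > 1.0))
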