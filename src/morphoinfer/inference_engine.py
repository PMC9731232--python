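"""Variational filtering in generalized coordinates for the cell ensemble.

Each cell carries internal (slot-belief) and active (position +
secretion) states in generalized coordinates of motion: a small stack of
temporal derivative orders (value, velocity, ...).  Sensory states are
not free variables; they are regenerated from the active states through
the shared signalling field, plus smooth additive noise.

The dynamics are gradient flows on the Laplace-form variational free
energy

    F = sum_cells [ 1/2 eps' Pi1 eps + 1/2 pi2 |i - mu|^2 ],

with eps the blockwise sensory prediction error.  Generalized flows are
the derivative-shift operator D minus the free-energy gradient taken on
the lowest order (higher-order contributions are suppressed):

    f_a = D a - grad_a F,    f_i = D i - grad_i F.

The gradient with respect to a cell's actions runs through its own
sensed secretion and position *and* through every cell's sensed field
(the chain rule through the diffusion kernel), which is what couples the
collective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .model_core import (
    MorphologyError,
    PrecisionConfig,
    TargetMorphology,
    SensoryTriple,
    signal_field,
    softmax,
)

DEFAULT_ORDERS = 3  # generalized embedding order n


class SimulationDivergenceError(RuntimeError):
    """Raised when an integrated state leaves the configured bound."""


@dataclass(frozen=True)
class GeneralizedState:
    """A state vector with its temporal derivatives up to a fixed order.

    ``orders[m]`` is the m-th derivative level; all levels share one
    dimension.
    """

    orders: np.ndarray  # (order_count, dim)

    @property
    def order_count(self) -> int:
        return self.orders.shape[0]

    @property
    def dim(self) -> int:
        return self.orders.shape[1]

    def __post_init__(self) -> None:
        if self.orders.ndim != 2 or self.orders.shape[0] < 1:
            raise MorphologyError("GeneralizedState needs a (orders, dim) array")


def _shift_orders(arr: np.ndarray, axis: int = 0) -> np.ndarray:
    """Move every derivative level down one order; highest level -> 0."""
    out = np.roll(arr, -1, axis=axis)
    index = [slice(None)] * arr.ndim
    index[axis] = -1
    out[tuple(index)] = 0.0
    return out


def generalized_shift(g: GeneralizedState) -> GeneralizedState:
    """Apply the derivative operator D: level m of the output is level
    m+1 of the input; the highest level becomes zero."""
    return GeneralizedState(orders=_shift_orders(g.orders, axis=0))


@dataclass
class CellEnsembleState:
    """All cells' internal, active and sensory states at one time.

    ``internal``: (n_cells, n_orders, n_slots) slot beliefs.
    ``active``:   (n_cells, n_orders, 2 + n_channels); the first two
    components of the lowest order are the position, the rest the
    secretion profile.  ``sc``/``sx``/``s_lambda`` are the sensed blocks
    (computed from active states + field, never integrated).
    """

    internal: np.ndarray
    active: np.ndarray
    sc: np.ndarray  # (n_cells, n_channels)
    sx: np.ndarray  # (n_cells, 2)
    s_lambda: np.ndarray  # (n_cells, n_channels)
    time_index: int = 0

    @property
    def n_cells(self) -> int:
        return self.internal.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """(n_cells, 2) lowest-order positions."""
        return self.active[:, 0, :2]

    @property
    def secretions(self) -> np.ndarray:
        """(n_cells, n_channels) lowest-order secretion profiles."""
        return self.active[:, 0, 2:]

    @property
    def beliefs(self) -> np.ndarray:
        """(n_cells, n_slots) lowest-order internal states."""
        return self.internal[:, 0, :]

    def sensory_triple(self, cell: int) -> SensoryTriple:
        return SensoryTriple(
            sc=self.sc[cell].copy(),
            sx=self.sx[cell].copy(),
            s_lambda=self.s_lambda[cell].copy(),
        )


@dataclass(frozen=True)
class NoiseParams:
    """Smooth sensory fluctuations: amplitude ``sd`` (signal units),
    temporal correlation length ``smoothness`` (macro-steps), ``seed``."""

    sd: float = 0.01
    smoothness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")
        if self.smoothness < 0:
            raise ValueError("noise smoothness must be nonnegative")


def generate_noise(
    params: NoiseParams,
    horizon: int,
    dim: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Seeded, temporally correlated Gaussian sequence of shape
    (horizon, dim).

    White noise is convolved with a Gaussian kernel of width
    ``params.smoothness`` (in samples) and rescaled so each marginal has
    standard deviation ``params.sd``; smoothness 0 gives white noise.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.sd == 0:
        return np.zeros((horizon, dim))
    white = rng.standard_normal((horizon, dim))
    if params.smoothness == 0:
        return params.sd * white
    smooth = gaussian_filter1d(white, sigma=params.smoothness, axis=0, mode="wrap")
    # the filter shrinks the variance by the squared kernel norm
    impulse = np.zeros(horizon)
    impulse[horizon // 2] = 1.0
    kernel = gaussian_filter1d(impulse, sigma=params.smoothness, mode="constant")
    norm = np.sqrt(np.sum(kernel**2))
    return params.sd * smooth / norm


def _gradients(
    ens: CellEnsembleState,
    morph: TargetMorphology,
    prec: PrecisionConfig,
    gains: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Free-energy gradients w.r.t. lowest-order internal states,
    positions and secretions: (gI, gX, gC)."""
    X = ens.positions
    C = ens.secretions
    I0 = ens.beliefs
    n = ens.n_cells
    if gains is None:
        gains = np.ones(n)
    eff = morph.params.tau * gains  # effective per-cell secretion gain

    sig = softmax(I0, axis=1)
    eps_c = ens.sc - sig @ morph.ec_star.T
    eps_x = ens.sx - sig @ morph.ex_star.T
    eps_l = ens.s_lambda - sig @ morph.lambda_star.T
    wc = prec.pi1_c[:, None] * eps_c
    wx = prec.pi1_x[:, None] * eps_x
    wl = prec.pi1_lambda[:, None] * eps_l

    # internal: dF/dI0 = -J_softmax' M' Pi eps + pi2 (I0 - mu)
    W = wc @ morph.ec_star + wx @ morph.ex_star + wl @ morph.lambda_star
    vjp = sig * (W - np.sum(sig * W, axis=1, keepdims=True))
    gI = -vjp + prec.pi2[:, None] * (I0 - prec.prior_mean)

    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    kernel = np.exp(-morph.params.k * d)

    # secretion: own sensed secretion + every cell's sensed field
    gC = wc + eff[:, None] * (kernel @ wl)

    # position: own sensed position + kernel geometry of the field
    tc = eff[:, None] * C  # effective secretions tau_j c_j
    A = wl @ tc.T  # A[m, j] = wl_m . (tau_j c_j)
    B = A + A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(d > 1e-12, -morph.params.k * kernel * B / d, 0.0)
    gX = wx + G.sum(axis=1)[:, None] * X - G @ X
    return gI, gX, gC


def free_energy(
    ens: CellEnsembleState, morph: TargetMorphology, prec: PrecisionConfig
) -> float:
    """Laplace free energy of the ensemble (nats, additive constants
    dropped), evaluated on the lowest generalized order."""
    sig = softmax(ens.beliefs, axis=1)
    eps_c = ens.sc - sig @ morph.ec_star.T
    eps_x = ens.sx - sig @ morph.ex_star.T
    eps_l = ens.s_lambda - sig @ morph.lambda_star.T
    dev = ens.beliefs - prec.prior_mean
    return float(
        0.5
        * (
            np.sum(prec.pi1_c[:, None] * eps_c**2)
            + np.sum(prec.pi1_x[:, None] * eps_x**2)
            + np.sum(prec.pi1_lambda[:, None] * eps_l**2)
            + np.sum(prec.pi2[:, None] * dev**2)
        )
    )


def flow(
    ens: CellEnsembleState,
    morph: TargetMorphology,
    prec: PrecisionConfig,
    gains: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized flows (d_internal, d_active) of all cells.

    Level 0 is the derivative shift minus the free-energy gradient;
    higher levels carry the shift alone.
    """
    gI, gX, gC = _gradients(ens, morph, prec, gains)
    d_internal = _shift_orders(ens.internal, axis=1)
    d_active = _shift_orders(ens.active, axis=1)
    d_internal[:, 0, :] -= gI
    d_active[:, 0, :2] -= gX
    d_active[:, 0, 2:] -= gC
    return d_internal, d_active


def sense(
    ens: CellEnsembleState,
    morph: TargetMorphology,
    gains: np.ndarray | None = None,
    noise_slice: np.ndarray | None = None,
) -> CellEnsembleState:
    """Regenerate sensory states from the active states and the field.

    ``noise_slice`` is a flat (n_cells * (2 * n_channels + 2),) vector
    laid out per cell as [sc block, sx block, s_lambda block].
    """
    n, ch = ens.n_cells, morph.n_channels
    lam = signal_field(ens.positions.T, ens.secretions.T, morph.params, gains).T
    sc = ens.secretions.copy()
    sx = ens.positions.copy()
    sl = lam
    if noise_slice is not None:
        w = np.asarray(noise_slice, dtype=float).reshape(n, 2 * ch + 2)
        sc = sc + w[:, :ch]
        sx = sx + w[:, ch : ch + 2]
        sl = sl + w[:, ch + 2 :]
    ens.sc, ens.sx, ens.s_lambda = sc, sx, sl
    return ens


def integrate_step(
    ens: CellEnsembleState,
    dt: float,
    noise_slice: np.ndarray | None,
    morph: TargetMorphology,
    prec: PrecisionConfig,
    gains: np.ndarray | None = None,
    divergence_bound: float = 1e6,
) -> CellEnsembleState:
    """One explicit Euler step of the coupled gradient flows, then
    sensory regeneration through the field."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    d_internal, d_active = flow(ens, morph, prec, gains)
    new = CellEnsembleState(
        internal=ens.internal + dt * d_internal,
        active=ens.active + dt * d_active,
        sc=ens.sc,
        sx=ens.sx,
        s_lambda=ens.s_lambda,
        time_index=ens.time_index + 1,
    )
    for name, arr in (("internal", new.internal), ("active", new.active)):
        norms = np.linalg.norm(arr.reshape(arr.shape[0], -1), axis=1)
        bad = np.where(~np.isfinite(norms) | (norms > divergence_bound))[0]
        if bad.size:
            raise SimulationDivergenceError(
                f"cell {bad[0]} {name} state diverged at step "
                f"{new.time_index} (norm {norms[bad[0]]:.3g}); "
                "try a smaller dt"
            )
    return sense(new, morph, gains, noise_slice)


@dataclass(frozen=True)
class RunConfig:
    """Numerical configuration of one simulation run.

    ``horizon`` macro-steps of unit duration, each integrated with
    ``substeps`` Euler sub-steps (dt = 1/substeps).
    """

    horizon: int = 32
    substeps: int = 32
    seed: int = 0
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_orders: int = DEFAULT_ORDERS
    init_position_sd: float = 0.5
    init_internal_sd: float = 0.1
    divergence_bound: float = 1e6


@dataclass
class Trajectory:
    """Recorded simulation: one snapshot per macro-step (plus the
    initial state), per-snapshot free energy, and run metadata."""

    morph: TargetMorphology
    snapshots: list[CellEnsembleState]
    free_energy: np.ndarray
    seed: int
    config: RunConfig
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def final(self) -> CellEnsembleState:
        return self.snapshots[-1]

    def to_long_frame(self):
        """Long-format table (step, cell, block, component, value) of the
        lowest-order states."""
        import pandas as pd

        rows = []
        for step, snap in enumerate(self.snapshots):
            for cell in range(snap.n_cells):
                blocks = {
                    "position": snap.positions[cell],
                    "secretion": snap.secretions[cell],
                    "belief": snap.beliefs[cell],
                }
                for block, vec in blocks.items():
                    for comp, val in enumerate(vec):
                        rows.append((step, cell, block, comp, float(val)))
        return pd.DataFrame(
            rows, columns=["step", "cell", "block", "component", "value"]
        )

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "horizon": self.config.horizon,
            "substeps": self.config.substeps,
            "n_cells": self.final.n_cells,
            "free_energy": [float(f) for f in self.free_energy],
            **self.metadata,
        }


def initial_ensemble(
    morph: TargetMorphology,
    run: RunConfig,
    rng: np.random.Generator,
    gains: np.ndarray | None = None,
) -> CellEnsembleState:
    """All cells undifferentiated near the morphology centroid: beliefs
    ~ N(0, init_internal_sd^2), positions ~ centroid +
    N(0, init_position_sd^2), secretions zero, higher orders zero."""
    n, s, ch = morph.n_slots, morph.n_slots, morph.n_channels
    centroid = morph.ex_star.mean(axis=1)
    internal = np.zeros((n, run.n_orders, s))
    internal[:, 0, :] = run.init_internal_sd * rng.standard_normal((n, s))
    active = np.zeros((n, run.n_orders, 2 + ch))
    active[:, 0, :2] = centroid + run.init_position_sd * rng.standard_normal((n, 2))
    ens = CellEnsembleState(
        internal=internal,
        active=active,
        sc=np.zeros((n, ch)),
        sx=np.zeros((n, 2)),
        s_lambda=np.zeros((n, ch)),
    )
    return sense(ens, morph, gains)


def simulate(
    morph: TargetMorphology,
    prec: PrecisionConfig,
    run: RunConfig,
    gains: np.ndarray | None = None,
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate the collective for ``run.horizon`` macro-steps.

    Deterministic for a fixed seed: initial jitter and the smooth
    sensory noise both derive from ``run.seed``.
    """
    if prec.n_cells != morph.n_slots:
        raise MorphologyError(
            "precision config is per-cell and must match the slot count "
            f"({prec.n_cells} vs {morph.n_slots})"
        )
    from ._kernel import run_kernel

    rng = np.random.default_rng(run.seed)
    ens = initial_ensemble(morph, run, rng, gains)
    n, ch, S = ens.n_cells, morph.n_channels, morph.n_slots
    sdim = 2 * ch + 2
    total = run.horizon * run.substeps + 1
    if run.noise.smoothness > 0 and run.noise.sd > 0:
        # the process is smooth on the scale of a macro-step, so sample
        # it coarsely (8 points per correlation length) and interpolate
        per = 8
        coarse_n = max(int(np.ceil(run.horizon / run.noise.smoothness)) * per, 2)
        coarse = generate_noise(
            NoiseParams(sd=run.noise.sd, smoothness=float(per)),
            coarse_n,
            n * sdim,
            rng=rng,
        )
        t_coarse = np.linspace(0.0, run.horizon, coarse_n)
        t_fine = np.linspace(0.0, run.horizon, total)
        noise = np.empty((total, n * sdim))
        for col in range(n * sdim):
            noise[:, col] = np.interp(t_fine, t_coarse, coarse[:, col])
        noise = noise.reshape(total, n, sdim)
    else:
        noise = generate_noise(
            NoiseParams(sd=run.noise.sd, smoothness=0.0),
            total,
            n * sdim,
            rng=rng,
        ).reshape(total, n, sdim)
    if gains is None:
        gains = np.ones(n)
    (trajI, trajX, trajC, trajSc, trajSx, trajSl, fes, status, bad) = run_kernel(
        ens.beliefs.copy(),
        ens.positions.copy(),
        ens.secretions.copy(),
        noise,
        morph.ec_star,
        morph.ex_star,
        morph.lambda_star,
        morph.params.tau,
        morph.params.k,
        np.asarray(gains, dtype=float),
        prec.pi1_c,
        prec.pi1_x,
        prec.pi1_lambda,
        prec.pi2,
        prec.prior_mean,
        run.substeps,
        run.horizon,
        run.divergence_bound,
    )
    if status != 0:
        raise SimulationDivergenceError(
            f"state diverged at sub-step {bad}; try a smaller dt "
            "(more sub-steps)"
        )
    snapshots = []
    for rec in range(run.horizon + 1):
        internal = np.zeros((n, run.n_orders, S))
        internal[:, 0, :] = trajI[rec]
        active = np.zeros((n, run.n_orders, 2 + ch))
        active[:, 0, :2] = trajX[rec]
        active[:, 0, 2:] = trajC[rec]
        snapshots.append(
            CellEnsembleState(
                internal=internal,
                active=active,
                sc=trajSc[rec].copy(),
                sx=trajSx[rec].copy(),
                s_lambda=trajSl[rec].copy(),
                time_index=rec * run.substeps,
            )
        )
    return Trajectory(
        morph=morph,
        snapshots=snapshots,
        free_energy=np.asarray(fes),
        seed=run.seed,
        config=run,
        metadata=dict(metadata or {}),
    )
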