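"""Generative model shared by every cell in the collective.

A target anatomy is *place coded*: it consists of ``n_slots`` slots along
the anterior-posterior axis, each with a type (head, pharynx, intestine,
tail), a planar position ``ex_star[:, j]`` and an expected secretion
profile ``ec_star[:, j]`` over ``n_channels`` signalling molecules.  The
extracellular concentration a cell sitting in slot ``j`` would sense,
``lambda_star[:, j]``, follows from secretion and isotropic diffusion of
every slot's profile:

    lambda_i = tau * sum_j ec_j * exp(-k * d_ij)

with ``d_ij`` the Euclidean distance between slots ``i`` and ``j`` (the
``j == i`` term is included, ``exp(0) = 1``).

Each cell holds a belief vector over slots; the softmax of that belief is
a categorical distribution, and the generative prediction is the convex
combination of slot columns weighted by it.  Prediction errors are the
blockwise difference between sensed and predicted signals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import softmax as _scipy_softmax

#: Canonical cell types along the planarian anterior-posterior axis.
CELL_TYPES = ("head", "pharynx", "intestine", "tail")


class MorphologyError(ValueError):
    """Raised for inconsistent morphology or signalling configurations."""


def softmax(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Normalised exponential of ``v`` along ``axis``.

    Numerically stable for large magnitudes; rejects non-finite input.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("softmax input must be finite")
    return _scipy_softmax(v, axis=axis)


@dataclass(frozen=True)
class SignalingParams:
    """Secretion gain ``tau`` and diffusion decay rate ``k`` (both > 0)."""

    tau: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau > 0 and self.k > 0):
            raise MorphologyError(
                f"tau and k must be positive, got tau={self.tau}, k={self.k}"
            )


def signal_field(
    positions: np.ndarray,
    secretions: np.ndarray,
    params: SignalingParams,
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """Sensed extracellular concentration at every cell position.

    Parameters
    ----------
    positions : (2, N) array of planar cell positions.
    secretions : (n_channels, N) array; column ``j`` is cell ``j``'s
        secretion profile.
    params : diffusion parameters (``tau``, ``k``).
    gains : optional (N,) per-cell multiplicative secretion gains (used
        by rescue interventions); default all ones.

    Returns
    -------
    (n_channels, N) array ``lam`` with
    ``lam[:, i] = tau * sum_j gains[j] * secretions[:, j] * exp(-k d_ij)``.
    """
    positions = np.asarray(positions, dtype=float)
    secretions = np.asarray(secretions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] != 2:
        raise MorphologyError(f"positions must be (2, N), got {positions.shape}")
    if secretions.ndim != 2 or secretions.shape[1] != positions.shape[1]:
        raise MorphologyError(
            "secretions and positions disagree on the number of cells: "
            f"{secretions.shape} vs {positions.shape}"
        )
    n = positions.shape[1]
    if gains is None:
        gains = np.ones(n)
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (n,):
        raise MorphologyError(f"gains must have shape ({n},), got {gains.shape}")
    d = cdist(positions.T, positions.T)
    kernel = np.exp(-params.k * d)  # symmetric, unit diagonal
    return params.tau * (secretions * gains) @ kernel


@dataclass(frozen=True)
class TargetMorphology:
    """Place-encoded target: slot types, expectations ec*, ex* and lambda*."""

    slot_types: tuple[str, ...]
    ec_star: np.ndarray  # (n_channels, n_slots)
    ex_star: np.ndarray  # (2, n_slots)
    lambda_star: np.ndarray  # (n_channels, n_slots)
    params: SignalingParams = field(default_factory=SignalingParams)

    @property
    def n_slots(self) -> int:
        return len(self.slot_types)

    @property
    def n_channels(self) -> int:
        return self.ec_star.shape[0]

    @property
    def stacked_targets(self) -> np.ndarray:
        """All slot expectations stacked row-wise: [ec*; ex*; lambda*]."""
        return np.vstack([self.ec_star, self.ex_star, self.lambda_star])

    def type_membership(self) -> np.ndarray:
        """(n_types, n_slots) 0/1 matrix mapping slots to CELL_TYPES."""
        return np.array(
            [[1.0 if t == ct else 0.0 for t in self.slot_types] for ct in CELL_TYPES]
        )

    def __post_init__(self) -> None:
        if self.n_slots < 1 or self.n_channels < 1:
            raise MorphologyError("need at least one slot and one channel")
        unknown = set(self.slot_types) - set(CELL_TYPES)
        if unknown:
            raise MorphologyError(f"unknown slot types: {sorted(unknown)}")
        if self.ec_star.shape != (self.n_channels, self.n_slots):
            raise MorphologyError("ec_star shape mismatch")
        if self.ex_star.shape != (2, self.n_slots):
            raise MorphologyError("ex_star shape mismatch")
        if self.lambda_star.shape != self.ec_star.shape:
            raise MorphologyError("lambda_star shape mismatch")
        if np.any(self.ec_star < 0):
            raise MorphologyError("ec_star entries must be nonnegative")
        expected = signal_field(self.ex_star, self.ec_star, self.params)
        if not np.allclose(self.lambda_star, expected, rtol=1e-10, atol=1e-10):
            raise MorphologyError(
                "lambda_star is not self-consistent with signal_field(ex_star, ec_star)"
            )


@dataclass(frozen=True)
class SensoryTriple:
    """One cell's sensed blocks: secretion sc, position sx, field s_lambda.

    The same container is reused for prediction-error blocks (eps_c,
    eps_x, eps_lambda), which live in the same spaces.
    """

    sc: np.ndarray  # (n_channels,)
    sx: np.ndarray  # (2,)
    s_lambda: np.ndarray  # (n_channels,)

    def stack(self) -> np.ndarray:
        return np.concatenate([self.sc, self.sx, self.s_lambda])

    def __post_init__(self) -> None:
        if self.sx.shape != (2,):
            raise MorphologyError(f"sx must be length 2, got {self.sx.shape}")
        if self.sc.shape != self.s_lambda.shape or self.sc.ndim != 1:
            raise MorphologyError("sc and s_lambda must be equal-length vectors")


@dataclass(frozen=True)
class PrecisionConfig:
    """Per-cell precisions (inverse variances) of the generative model.

    ``pi1_c``, ``pi1_x``, ``pi1_lambda`` weight the sensory prediction
    errors of the secretion, position and field blocks; ``pi2`` weights
    the Gaussian prior of the internal (slot-belief) states around
    ``prior_mean``.  Defaults follow the model convention pi1 = 1 and
    log pi2 = -2.
    """

    pi1_c: np.ndarray  # (n_cells,)
    pi1_x: np.ndarray  # (n_cells,)
    pi1_lambda: np.ndarray  # (n_cells,)
    pi2: np.ndarray  # (n_cells,)
    prior_mean: np.ndarray  # (n_cells, n_slots)

    @classmethod
    def defaults(cls, n_cells: int, n_slots: int) -> "PrecisionConfig":
        ones = np.ones(n_cells)
        return cls(
            pi1_c=ones.copy(),
            pi1_x=ones.copy(),
            pi1_lambda=ones.copy(),
            pi2=np.full(n_cells, np.exp(-2.0)),
            prior_mean=np.zeros((n_cells, n_slots)),
        )

    @property
    def n_cells(self) -> int:
        return self.pi1_c.shape[0]

    def __post_init__(self) -> None:
        for name in ("pi1_c", "pi1_x", "pi1_lambda", "pi2"):
            arr = getattr(self, name)
            if arr.shape != (self.n_cells,):
                raise MorphologyError(f"{name} must have shape (n_cells,)")
            if np.any(arr <= 0):
                raise MorphologyError(f"{name} must be strictly positive")
        if self.prior_mean.ndim != 2 or self.prior_mean.shape[0] != self.n_cells:
            raise MorphologyError("prior_mean must have shape (n_cells, n_slots)")


def predict(internal: np.ndarray, morph: TargetMorphology) -> SensoryTriple:
    """Generative prediction g(i): slot columns mixed by softmax(internal)."""
    internal = np.asarray(internal, dtype=float)
    if internal.shape != (morph.n_slots,):
        raise MorphologyError(
            f"internal must have length {morph.n_slots}, got {internal.shape}"
        )
    sig = softmax(internal)
    return SensoryTriple(
        sc=morph.ec_star @ sig,
        sx=morph.ex_star @ sig,
        s_lambda=morph.lambda_star @ sig,
    )


def prediction_error(
    s: SensoryTriple, internal: np.ndarray, morph: TargetMorphology
) -> SensoryTriple:
    """Blockwise sensory prediction error eps = s - g(internal)."""
    g = predict(internal, morph)
    if s.sc.shape != g.sc.shape:
        raise MorphologyError(
            f"sensory channel count {s.sc.shape} does not match morphology "
            f"{g.sc.shape}"
        )
    return SensoryTriple(
        sc=s.sc - g.sc, sx=s.sx - g.sx, s_lambda=s.s_lambda - g.s_lambda
    )


def _one_hot_expression(
    slot_types: tuple[str, ...], amplitude: float = 1.0
) -> np.ndarray:
    """Default ec*: each type secretes its own channel with the given
    amplitude."""
    return np.array(
        [[amplitude if t == ct else 0.0 for t in slot_types] for ct in CELL_TYPES]
    )


def build_target(config: dict | str | Path) -> TargetMorphology:
    """Construct a self-consistent :class:`TargetMorphology`.

    ``config`` is a mapping (or path to a JSON file) with keys
    ``slot_types``, ``ex_star`` (2 x n_slots), optional ``ec_star``
    (n_channels x n_slots; defaults to the one-hot-by-type rule over the
    four canonical channels at ``expression_amplitude``), ``tau`` and
    ``k``.  ``lambda_star`` is always derived via :func:`signal_field`,
    never read.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    slot_types = tuple(config["slot_types"])
    ex_star = np.asarray(config["ex_star"], dtype=float)
    if "ec_star" in config and config["ec_star"] is not None:
        ec_star = np.asarray(config["ec_star"], dtype=float)
    else:
        ec_star = _one_hot_expression(
            slot_types, float(config.get("expression_amplitude", 1.0))
        )
    params = SignalingParams(
        tau=float(config.get("tau", 1.0)), k=float(config.get("k", 1.0))
    )
    if ex_star.ndim != 2 or ex_star.shape != (2, len(slot_types)):
        raise MorphologyError(
            f"ex_star must be (2, {len(slot_types)}), got {ex_star.shape}"
        )
    if ec_star.ndim != 2 or ec_star.shape[1] != len(slot_types):
        raise MorphologyError(
            f"ec_star must have {len(slot_types)} columns, got {ec_star.shape}"
        )
    lam = signal_field(ex_star, ec_star, params)
    return TargetMorphology(
        slot_types=slot_types,
        ec_star=ec_star,
        ex_star=ex_star,
        lambda_star=lam,
        params=params,
    )


def default_target() -> TargetMorphology:
    """The packaged eight-slot, four-channel planarian-like axis."""
    from importlib.resources import files

    path = files("morphoinfer.data").joinpath("default_morphology.json")
    return build_target(json.loads(path.read_text()))
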