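"""Named precision-pathology experiments and outcome classification.

Five experiments are declared on top of the normal condition by scaling
precisions per cell:

* ``high_sensory_precision`` — a failure of sensory attenuation: the
  cells assign excessive precision to their *self-generated* chemical
  signal (the sensed own secretion), so secretion is slaved to the
  currently believed expression profile instead of being attenuated
  during development.
* ``high_prior_identity`` — every cell holds a rigid prior that it is
  an intestinal cell (prior mean set to the intestinal-slot indicator
  with strongly scaled prior precision).
* ``low_sensory_precision`` — hyporeactivity: both chemosensory blocks
  (own secretion and extracellular field) are strongly attenuated, so
  cells barely react to the chemical signals they receive.
* ``rescue`` — two cells carry the high-sensory-precision defect; the
  intervention reduces their secretion output and their sensitivity to
  the other cells' signals (the field-block precision).
* ``sweep`` — parametric family over how many cells carry a
  perturbation (see :func:`precision_sweep`).

Position-sense precision is never scaled: the manipulated quantities
are biochemical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_core import (
    CELL_TYPES,
    PrecisionConfig,
    TargetMorphology,
    default_target,
    softmax,
)
from .inference_engine import NoiseParams, RunConfig, Trajectory, simulate

SCENARIO_NAMES = (
    "normal",
    "high_sensory_precision",
    "high_prior_identity",
    "low_sensory_precision",
    "rescue",
    "sweep",
)

#: Log-scale departure used for "excessive" precisions (documented
#: default; the magnitudes behind the published figures are not known).
EXCESS = math.exp(4.0)

#: Rescue intervention strength: secretion gain and field-precision
#: factors applied to the over-precise cells.  The dose is chosen so the
#: simulated intervention reproduces the reported cure; no values are
#: published.
RESCUE_SECRETION = 0.5
RESCUE_FIELD_SENSITIVITY = 0.25


class ScenarioError(ValueError):
    """Unknown scenario name or invalid configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """A named experiment: which cells are perturbed and how.

    ``affected_cells`` empty means "all cells".  All scale factors are
    multiplicative on the normal-condition values (pi1 = 1,
    pi2 = exp(-2), secretion gain 1).  ``sensory_precision_scale``
    multiplies the own-secretion precision ``pi1_c``;
    ``field_sensitivity_scale`` multiplies the extracellular-field
    precision ``pi1_lambda``; ``secretion_scale`` multiplies the
    secretion gain entering the shared field.
    """

    name: str = "normal"
    affected_cells: tuple[int, ...] = ()
    sensory_precision_scale: float = 1.0
    prior_mean_override: tuple[float, ...] | None = None
    prior_precision_scale: float = 1.0
    secretion_scale: float = 1.0
    field_sensitivity_scale: float = 1.0
    horizon: int = 32
    seed: int = 0
    noise_sd: float = 0.01
    noise_smoothness: float = 1.0

    def __post_init__(self) -> None:
        for attr in (
            "sensory_precision_scale",
            "prior_precision_scale",
            "secretion_scale",
            "field_sensitivity_scale",
        ):
            if getattr(self, attr) <= 0:
                raise ScenarioError(f"{attr} must be > 0")
        if self.horizon < 0:
            raise ScenarioError("horizon must be >= 0")


@dataclass(frozen=True)
class OutcomeReport:
    """Final-state classification of one simulated trajectory.

    ``final_types`` are modal types of the final differentiation
    profile: slot-level softmax probabilities aggregated to the four
    types, then argmax.
    """

    final_types: tuple[str, ...]
    assigned_slots: tuple[int, ...]
    positional_errors: tuple[float, ...]
    n_intestinal: int
    tumor_flag: bool
    converged_flag: bool
    free_energy_initial: float
    free_energy_final: float


def intestinal_indicator(morph: TargetMorphology) -> tuple[float, ...]:
    """Slot-belief vector marking the intestinal slots (prior mean for
    the high-identity-prior experiment)."""
    return tuple(1.0 if t == "intestine" else 0.0 for t in morph.slot_types)


def build_scenario(
    name: str, morph: TargetMorphology | None = None, **overrides
) -> ScenarioConfig:
    """Return the named configuration with documented defaults; keyword
    ``overrides`` replace individual fields afterwards."""
    if name not in SCENARIO_NAMES:
        raise ScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        )
    if morph is None:
        morph = default_target()
    base = ScenarioConfig(name=name)
    if name == "high_sensory_precision":
        base = replace(base, sensory_precision_scale=EXCESS)
    elif name == "high_prior_identity":
        base = replace(
            base,
            prior_mean_override=intestinal_indicator(morph),
            prior_precision_scale=EXCESS,
        )
    elif name == "low_sensory_precision":
        base = replace(
            base,
            sensory_precision_scale=1.0 / EXCESS,
            field_sensitivity_scale=1.0 / EXCESS,
        )
    elif name == "rescue":
        # two cells are over-precise; the intervention damps their
        # secretion and their sensitivity to the shared field
        base = replace(
            base,
            affected_cells=(0, 1),
            sensory_precision_scale=EXCESS,
            secretion_scale=RESCUE_SECRETION,
            field_sensitivity_scale=RESCUE_FIELD_SENSITIVITY,
        )
    cfg = replace(base, **overrides)
    bad = [c for c in cfg.affected_cells if not 0 <= c < morph.n_slots]
    if bad:
        raise ScenarioError(f"affected cells out of range: {bad}")
    return cfg


def _affected_mask(cfg: ScenarioConfig, n_cells: int) -> np.ndarray:
    mask = np.zeros(n_cells, dtype=bool)
    if cfg.affected_cells:
        mask[list(cfg.affected_cells)] = True
    else:
        mask[:] = True
    return mask


def scenario_precisions(
    cfg: ScenarioConfig, morph: TargetMorphology
) -> tuple[PrecisionConfig, np.ndarray]:
    """Expand a scenario into per-cell precisions and secretion gains."""
    n = morph.n_slots
    prec = PrecisionConfig.defaults(n, morph.n_slots)
    mask = _affected_mask(cfg, n)
    pi1_c = prec.pi1_c.copy()
    pi1_x = prec.pi1_x.copy()
    pi1_l = prec.pi1_lambda.copy()
    pi2 = prec.pi2.copy()
    prior_mean = prec.prior_mean.copy()
    pi1_c[mask] *= cfg.sensory_precision_scale
    pi1_l[mask] *= cfg.field_sensitivity_scale
    pi2[mask] *= cfg.prior_precision_scale
    if cfg.prior_mean_override is not None:
        mu = np.asarray(cfg.prior_mean_override, dtype=float)
        if mu.shape != (morph.n_slots,):
            raise ScenarioError(
                f"prior_mean_override must have length {morph.n_slots}"
            )
        prior_mean[mask] = mu
    gains = np.ones(n)
    gains[mask] *= cfg.secretion_scale
    return (
        PrecisionConfig(
            pi1_c=pi1_c, pi1_x=pi1_x, pi1_lambda=pi1_l, pi2=pi2, prior_mean=prior_mean
        ),
        gains,
    )


def stable_substeps(prec: PrecisionConfig, base: int = 32) -> int:
    """Euler sub-step count for one macro-step.

    The base resolution (dt = 1/32) is part of the model definition;
    sub-steps are added only when a precision-stiffened block would
    violate the explicit-Euler stability bound (pi_max * dt < 2, with a
    safety factor).
    """
    pi_max = float(
        max(prec.pi1_c.max(), prec.pi1_x.max(), prec.pi1_lambda.max(), prec.pi2.max())
    )
    need = int(math.ceil(pi_max / 1.8))
    return max(base, ((need + base - 1) // base) * base)


def run_scenario(
    cfg: ScenarioConfig, morph: TargetMorphology | None = None
) -> Trajectory:
    """Simulate one scenario end-to-end; reproducible from cfg alone."""
    if morph is None:
        morph = default_target()
    prec, gains = scenario_precisions(cfg, morph)
    run = RunConfig(
        horizon=cfg.horizon,
        substeps=stable_substeps(prec),
        seed=cfg.seed,
        noise=NoiseParams(sd=cfg.noise_sd, smoothness=cfg.noise_smoothness),
    )
    return simulate(
        morph, prec, run, gains=gains, metadata={"scenario": cfg.name, "config": cfg}
    )


def differentiation_profile(traj: Trajectory) -> pd.DataFrame:
    """Per-step, per-cell probability over the four cell types.

    Slot-level softmax probabilities are aggregated to types by summing
    the slots of each type; every row sums to one.
    """
    if len(traj) == 0:
        raise ScenarioError("empty trajectory")
    membership = traj.morph.type_membership()  # (n_types, n_slots)
    rows = []
    for step, snap in enumerate(traj.snapshots):
        probs = softmax(snap.beliefs, axis=1) @ membership.T  # (n_cells, n_types)
        for cell in range(snap.n_cells):
            rows.append((step, cell, *probs[cell]))
    return pd.DataFrame(rows, columns=["step", "cell", *CELL_TYPES])


def modal_types(snap_beliefs: np.ndarray, morph: TargetMorphology) -> tuple[str, ...]:
    """Modal cell types: argmax of the type-aggregated softmax beliefs.

    An incompletely differentiated cell (diffuse slot beliefs) is typed
    by whichever tissue claims the largest share of its probability
    mass.
    """
    probs = softmax(snap_beliefs, axis=1) @ morph.type_membership().T
    return tuple(CELL_TYPES[i] for i in np.argmax(probs, axis=1))


def _greedy_assignment(positions: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Greedy one-to-one cell-to-slot matching by ascending distance,
    ties broken by lower (cell, slot) index."""
    n = positions.shape[0]
    d = cdist(positions, targets)
    order = np.argsort(d, axis=None, kind="stable")
    assigned = np.full(n, -1)
    used = np.zeros(targets.shape[0], dtype=bool)
    for flat in order:
        c, s = divmod(int(flat), targets.shape[0])
        if assigned[c] == -1 and not used[s]:
            assigned[c] = s
            used[s] = True
            if np.all(assigned >= 0):
                break
    return assigned


def _radius_of_gyration(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def classify_outcome(
    traj: Trajectory, morph: TargetMorphology | None = None, tol: float = 1.0
) -> OutcomeReport:
    """Score a finished run against the target morphology.

    Convergence requires every cell within ``tol`` of its (greedily)
    assigned slot with the matching modal type.  The tumor flag marks a
    compact, predominantly intestinal mass: >= 75% intestinal-typed
    cells with an ensemble radius of gyration below half the target's.
    """
    if len(traj) == 0:
        raise ScenarioError("empty trajectory")
    if morph is None:
        morph = traj.morph
    snap = traj.final
    final_types = modal_types(snap.beliefs, morph)
    assigned = _greedy_assignment(snap.positions, morph.ex_star.T)
    errors = np.linalg.norm(snap.positions - morph.ex_star.T[assigned], axis=1)
    n_intestinal = sum(1 for t in final_types if t == "intestine")
    converged = bool(
        np.all(errors < tol)
        and all(
            final_types[c] == morph.slot_types[assigned[c]]
            for c in range(snap.n_cells)
        )
    )
    tumor = bool(
        n_intestinal >= 0.75 * snap.n_cells
        and _radius_of_gyration(snap.positions)
        < 0.5 * _radius_of_gyration(morph.ex_star.T)
    )
    return OutcomeReport(
        final_types=final_types,
        assigned_slots=tuple(int(s) for s in assigned),
        positional_errors=tuple(float(e) for e in errors),
        n_intestinal=int(n_intestinal),
        tumor_flag=tumor,
        converged_flag=converged,
        free_energy_initial=float(traj.free_energy[0]),
        free_energy_final=float(traj.free_energy[-1]),
    )


def precision_sweep(
    kind: str,
    counts=range(1, 9),
    seeds=(0, 1, 2, 3, 4),
    morph: TargetMorphology | None = None,
    tol: float = 1.0,
    **overrides,
) -> pd.DataFrame:
    """Perturb the first ``count`` cells for each count in ``counts``.

    ``kind`` is ``"sensory_precision"`` (pi1_c x EXCESS on the affected
    cells) or ``"prior_identity"`` (intestinal prior mean with pi2 x
    EXCESS).  Count 0 reduces to the normal scenario.  Returns one row
    per (count, seed) with the outcome fields.
    """
    if kind not in ("sensory_precision", "prior_identity"):
        raise ScenarioError(f"unknown sweep kind {kind!r}")
    if morph is None:
        morph = default_target()
    bad = [c for c in counts if not 0 <= c <= morph.n_slots]
    if bad:
        raise ScenarioError(f"counts out of range: {bad}")
    rows = []
    for count in counts:
        for seed in seeds:
            affected = tuple(range(count))
            if count == 0:
                cfg = build_scenario("normal", morph, seed=seed, **overrides)
            elif kind == "sensory_precision":
                cfg = build_scenario(
                    "high_sensory_precision",
                    morph,
                    affected_cells=affected,
                    seed=seed,
                    **overrides,
                )
            else:
                cfg = build_scenario(
                    "high_prior_identity",
                    morph,
                    affected_cells=affected,
                    seed=seed,
                    **overrides,
                )
            try:
                traj = run_scenario(cfg, morph)
            except Exception as exc:  # propagate with grid context
                raise RuntimeError(
                    f"sweep cell (count={count}, seed={seed}) failed: {exc}"
                ) from exc
            out = classify_outcome(traj, morph, tol=tol)
            rows.append(
                {
                    "count": count,
                    "seed": seed,
                    "n_intestinal": out.n_intestinal,
                    "converged": out.converged_flag,
                    "tumor": out.tumor_flag,
                    "final_free_energy": out.free_energy_final,
                }
            )
    return pd.DataFrame(rows)


def sweep_aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Per-count means of the sweep outcome grid."""
    return (
        results.groupby("count")[["n_intestinal", "converged", "tumor"]]
        .mean()
        .reset_index()
    )
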