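"""Shared helpers for the acceptance script: default precisions, random
ensemble states, and the finite-difference free-energy gradient oracle
(independent of the analytic flow it checks)."""

from __future__ import annotations

import numpy as np

from morphoinfer import CellEnsembleState, PrecisionConfig, free_energy, sense


def make_prec(morph, **kw) -> PrecisionConfig:
    base = PrecisionConfig.defaults(morph.n_slots, morph.n_slots)
    fields = dict(
        pi1_c=base.pi1_c,
        pi1_x=base.pi1_x,
        pi1_lambda=base.pi1_lambda,
        pi2=base.pi2,
        prior_mean=base.prior_mean,
    )
    fields.update(kw)
    return PrecisionConfig(**fields)


def random_state(morph, rng, n_orders=3, spread=1.0) -> CellEnsembleState:
    n, S, C = morph.n_slots, morph.n_slots, morph.n_channels
    internal = np.zeros((n, n_orders, S))
    internal[:, 0, :] = spread * rng.standard_normal((n, S))
    active = np.zeros((n, n_orders, 2 + C))
    active[:, 0, :2] = spread * rng.standard_normal((n, 2))
    active[:, 0, 2:] = np.abs(spread * rng.standard_normal((n, C)))
    ens = CellEnsembleState(
        internal=internal,
        active=active,
        sc=np.zeros((n, C)),
        sx=np.zeros((n, 2)),
        s_lambda=np.zeros((n, C)),
    )
    return sense(ens, morph)


def finite_difference_gradients(ens, morph, prec, gains=None, h=1e-6):
    """Central differences of the free energy w.r.t. the lowest-order
    internal and active states, re-sensing (noise-free) after each
    perturbation."""

    def F_of(I0, A0):
        e = CellEnsembleState(
            internal=ens.internal.copy(),
            active=ens.active.copy(),
            sc=ens.sc,
            sx=ens.sx,
            s_lambda=ens.s_lambda,
        )
        e.internal[:, 0, :] = I0
        e.active[:, 0, :] = A0
        e = sense(e, morph, gains)
        return free_energy(e, morph, prec)

    I0 = ens.internal[:, 0, :].copy()
    A0 = ens.active[:, 0, :].copy()
    gI = np.zeros_like(I0)
    gA = np.zeros_like(A0)
    for idx in np.ndindex(I0.shape):
        p = I0.copy(); p[idx] += h
        m = I0.copy(); m[idx] -= h
        gI[idx] = (F_of(p, A0) - F_of(m, A0)) / (2 * h)
    for idx in np.ndindex(A0.shape):
        p = A0.copy(); p[idx] += h
        m = A0.copy(); m[idx] -= h
        gA[idx] = (F_of(I0, p) - F_of(I0, m)) / (2 * h)
    return gI, gA
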