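"""Compiled inner loop for the ensemble integrator.

The public reference implementation lives in
:mod:`morphoinfer.inference_engine` (``flow`` / ``integrate_step``); this
module repeats the same arithmetic in explicit loops so numba can compile
it.  With higher generalized orders initialised to zero they stay zero
under the shift dynamics, so the kernel integrates the lowest order only;
a unit test pins the kernel to the reference step.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _softmax_rows(I, out):
    n, S = I.shape
    for i in range(n):
        m = I[i, 0]
        for s in range(1, S):
            if I[i, s] > m:
                m = I[i, s]
        tot = 0.0
        for s in range(S):
            out[i, s] = np.exp(I[i, s] - m)
            tot += out[i, s]
        for s in range(S):
            out[i, s] /= tot


@njit(cache=True)
def run_kernel(
    I,
    X,
    C,
    noise,
    ec,
    exs,
    lam,
    tau,
    kdiff,
    gains,
    pic,
    pix,
    pil,
    pi2,
    mu,
    substeps,
    horizon,
    bound,
):
    """Integrate the coupled gradient flows; returns trajectories of the
    lowest-order states and sensed blocks at macro-step boundaries.

    noise has shape (horizon * substeps + 1, n, 2*Ch + 2); slice 0 is
    used for the initial sensory sample.  Returns (trajI, trajX, trajC,
    trajSc, trajSx, trajSl, F, status, bad_step) where status is 0 on
    success, 1 on divergence.
    """
    n, S = I.shape
    Ch = ec.shape[0]
    dt = 1.0 / substeps
    trajI = np.zeros((horizon + 1, n, S))
    trajX = np.zeros((horizon + 1, n, 2))
    trajC = np.zeros((horizon + 1, n, Ch))
    trajSc = np.zeros((horizon + 1, n, Ch))
    trajSx = np.zeros((horizon + 1, n, 2))
    trajSl = np.zeros((horizon + 1, n, Ch))
    F = np.zeros(horizon + 1)

    sig = np.zeros((n, S))
    geff = np.zeros(n)
    for i in range(n):
        geff[i] = tau * gains[i]
    kern = np.zeros((n, n))
    d = np.zeros((n, n))
    sc = np.zeros((n, Ch))
    sx = np.zeros((n, 2))
    sl = np.zeros((n, Ch))
    eps_c = np.zeros((n, Ch))
    eps_x = np.zeros((n, 2))
    eps_l = np.zeros((n, Ch))
    W = np.zeros((n, S))
    gI = np.zeros((n, S))
    gX = np.zeros((n, 2))
    gC = np.zeros((n, Ch))
    Amat = np.zeros((n, n))

    def_step = -1
    status = 0
    step_idx = 0
    for rec in range(horizon + 1):
        # sense current state with noise slice step_idx
        for i in range(n):
            for j in range(n):
                dx = X[i, 0] - X[j, 0]
                dy = X[i, 1] - X[j, 1]
                d[i, j] = np.sqrt(dx * dx + dy * dy)
                kern[i, j] = np.exp(-kdiff * d[i, j])
        for i in range(n):
            for ch in range(Ch):
                acc = 0.0
                for j in range(n):
                    acc += kern[i, j] * geff[j] * C[j, ch]
                sl[i, ch] = acc + noise[step_idx, i, Ch + 2 + ch]
                sc[i, ch] = C[i, ch] + noise[step_idx, i, ch]
            sx[i, 0] = X[i, 0] + noise[step_idx, i, Ch]
            sx[i, 1] = X[i, 1] + noise[step_idx, i, Ch + 1]
        _softmax_rows(I, sig)
        # prediction errors and free energy at this boundary
        fe = 0.0
        for i in range(n):
            for ch in range(Ch):
                pred = 0.0
                for s in range(S):
                    pred += sig[i, s] * ec[ch, s]
                eps_c[i, ch] = sc[i, ch] - pred
                predl = 0.0
                for s in range(S):
                    predl += sig[i, s] * lam[ch, s]
                eps_l[i, ch] = sl[i, ch] - predl
                fe += pic[i] * eps_c[i, ch] ** 2 + pil[i] * eps_l[i, ch] ** 2
            for dd in range(2):
                pred = 0.0
                for s in range(S):
                    pred += sig[i, s] * exs[dd, s]
                eps_x[i, dd] = sx[i, dd] - pred
                fe += pix[i] * eps_x[i, dd] ** 2
            for s in range(S):
                fe += pi2[i] * (I[i, s] - mu[i, s]) ** 2
        F[rec] = 0.5 * fe
        for i in range(n):
            for s in range(S):
                trajI[rec, i, s] = I[i, s]
            for dd in range(2):
                trajX[rec, i, dd] = X[i, dd]
                trajSx[rec, i, dd] = sx[i, dd]
            for ch in range(Ch):
                trajC[rec, i, ch] = C[i, ch]
                trajSc[rec, i, ch] = sc[i, ch]
                trajSl[rec, i, ch] = sl[i, ch]
        if rec == horizon:
            break

        # --- integrate one macro-step ---
        for sub in range(substeps):
            # sense (recompute; reuse of boundary values only valid at sub 0)
            if sub > 0:
                for i in range(n):
                    for j in range(n):
                        dx = X[i, 0] - X[j, 0]
                        dy = X[i, 1] - X[j, 1]
                        d[i, j] = np.sqrt(dx * dx + dy * dy)
                        kern[i, j] = np.exp(-kdiff * d[i, j])
                for i in range(n):
                    for ch in range(Ch):
                        acc = 0.0
                        for j in range(n):
                            acc += kern[i, j] * geff[j] * C[j, ch]
                        sl[i, ch] = acc + noise[step_idx, i, Ch + 2 + ch]
                        sc[i, ch] = C[i, ch] + noise[step_idx, i, ch]
                    sx[i, 0] = X[i, 0] + noise[step_idx, i, Ch]
                    sx[i, 1] = X[i, 1] + noise[step_idx, i, Ch + 1]
                _softmax_rows(I, sig)
                for i in range(n):
                    for ch in range(Ch):
                        pred = 0.0
                        predl = 0.0
                        for s in range(S):
                            pred += sig[i, s] * ec[ch, s]
                            predl += sig[i, s] * lam[ch, s]
                        eps_c[i, ch] = sc[i, ch] - pred
                        eps_l[i, ch] = sl[i, ch] - predl
                    for dd in range(2):
                        pred = 0.0
                        for s in range(S):
                            pred += sig[i, s] * exs[dd, s]
                        eps_x[i, dd] = sx[i, dd] - pred

            # gradients
            for i in range(n):
                for s in range(S):
                    acc = 0.0
                    for ch in range(Ch):
                        acc += pic[i] * eps_c[i, ch] * ec[ch, s]
                        acc += pil[i] * eps_l[i, ch] * lam[ch, s]
                    for dd in range(2):
                        acc += pix[i] * eps_x[i, dd] * exs[dd, s]
                    W[i, s] = acc
            for i in range(n):
                dot = 0.0
                for s in range(S):
                    dot += sig[i, s] * W[i, s]
                for s in range(S):
                    gI[i, s] = -sig[i, s] * (W[i, s] - dot) + pi2[i] * (
                        I[i, s] - mu[i, s]
                    )
            for i in range(n):
                for ch in range(Ch):
                    acc = 0.0
                    for m in range(n):
                        acc += kern[m, i] * pil[m] * eps_l[m, ch]
                    gC[i, ch] = pic[i] * eps_c[i, ch] + geff[i] * acc
            for m in range(n):
                for j in range(n):
                    acc = 0.0
                    for ch in range(Ch):
                        acc += pil[m] * eps_l[m, ch] * geff[j] * C[j, ch]
                    Amat[m, j] = acc
            for i in range(n):
                gx0 = pix[i] * eps_x[i, 0]
                gx1 = pix[i] * eps_x[i, 1]
                for j in range(n):
                    if d[i, j] > 1e-12:
                        coef = (
                            -kdiff
                            * kern[i, j]
                            * (Amat[i, j] + Amat[j, i])
                            / d[i, j]
                        )
                        gx0 += coef * (X[i, 0] - X[j, 0])
                        gx1 += coef * (X[i, 1] - X[j, 1])
                gX[i, 0] = gx0
                gX[i, 1] = gx1

            # Euler update
            for i in range(n):
                for s in range(S):
                    I[i, s] -= dt * gI[i, s]
                X[i, 0] -= dt * gX[i, 0]
                X[i, 1] -= dt * gX[i, 1]
                for ch in range(Ch):
                    C[i, ch] -= dt * gC[i, ch]
            step_idx += 1

            # divergence check
            for i in range(n):
                norm2 = 0.0
                for s in range(S):
                    norm2 += I[i, s] ** 2
                for ch in range(Ch):
                    norm2 += C[i, ch] ** 2
                norm2 += X[i, 0] ** 2 + X[i, 1] ** 2
                if not np.isfinite(norm2) or norm2 > bound * bound:
                    status = 1
                    def_step = step_idx
                    return (
                        trajI,
                        trajX,
                        trajC,
                        trajSc,
                        trajSx,
                        trajSl,
                        F,
                        status,
                        def_step,
                    )

    return trajI, trajX, trajC, trajSc, trajSx, trajSl, F, status, def_step
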