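"""Backprop-through-time kernels for low-rank rate networks.

Forward Euler on r_{t+1} = (1-a) r_t + a phi(U (A U^T r_t + iota_t) + eta_t),
a = dt/tau, with phi_i(x) = rmax_i/2 (tanh x + 1).  ``iota`` is the total
latent input (task schedule plus any constant trial bias) per trial and
time step; ``eta_t = lick_vec_k * lick_rate_{k,t}`` is the N-space
proprioceptive lick input; an optional per-trial start index freezes the
state before the trial's (jittered) onset.

The backward pass consumes an arbitrary dL/d(rates) field, so every data
loss (reconstruction, epoch averages, coding projections) is assembled in
NumPy and only the recurrent chain runs in the compiled kernel.  Gradients
are returned for U, A, rmax, the per-step latent inputs, the lick vectors,
and the shared initial state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forward", "backward"]


@njit(cache=True)
def _forward_kernel(U, A, rmax, r0, iota, lick_vec, lick_rate, start_idx, a):
    K, Tm1, P = iota.shape
    N = U.shape[0]
    T = Tm1 + 1
    rates = np.empty((K, T, N))
    tanh_s = np.zeros((K, Tm1, N))
    w_s = np.zeros((K, Tm1, P))
    for k in range(K):
        r = r0.copy()
        rates[k, 0] = r
        for t in range(Tm1):
            if t < start_idx[k]:
                rates[k, t + 1] = r
                continue
            m = np.dot(r, U)
            w = np.dot(A, m) + iota[k, t]
            h = np.dot(U, w) + lick_vec[k] * lick_rate[k, t]
            th = np.tanh(h)
            tanh_s[k, t] = th
            w_s[k, t] = w
            r = (1.0 - a) * r + a * 0.5 * rmax * (th + 1.0)
            rates[k, t + 1] = r
    return rates, tanh_s, w_s


@njit(cache=True)
def _backward_kernel(U, A, rmax, g, rates, tanh_s, w_s, lick_rate, start_idx, a):
    K, T, N = rates.shape
    P = U.shape[1]
    dU = np.zeros((N, P))
    dA = np.zeros((P, P))
    drmax = np.zeros(N)
    diota = np.zeros((K, T - 1, P))
    dlick = np.zeros((K, N))
    dr0 = np.zeros(N)
    At = A.T.copy()
    for k in range(K):
        gnext = g[k, T - 1].copy()
        for t in range(T - 2, -1, -1):
            if t < start_idx[k]:
                gnext = gnext + g[k, t]
                continue
            th = tanh_s[k, t]
            # v = dL/dh_t: through phi' and the Euler mixing weight a
            v = a * 0.5 * rmax * (1.0 - th * th) * gnext
            uv = np.dot(v, U)  # U^T v
            m = np.dot(rates[k, t], U)
            dA += np.outer(uv, m)
            dU += np.outer(v, w_s[k, t]) + np.outer(rates[k, t], np.dot(At, uv))
            diota[k, t] = uv
            dlick[k] += v * lick_rate[k, t]
            drmax += a * 0.5 * (th + 1.0) * gnext
            gnext = g[k, t] + (1.0 - a) * gnext + np.dot(U, np.dot(At, uv))
        dr0 += gnext
    return dU, dA, drmax, diota, dlick, dr0


def forward(U, A, rmax, r0, iota, start_idx=None, a=0.125, lick_vec=None, lick_rate=None):
    """Batched Euler roll-out; returns (rates, caches) with rates (K, T, N)."""
    K, Tm1, _ = iota.shape
    N = U.shape[0]
    if start_idx is None:
        start_idx = np.zeros(K, dtype=np.int64)
    if lick_vec is None:
        lick_vec = np.zeros((K, N))
    if lick_rate is None:
        lick_rate = np.zeros((K, Tm1))
    rates, tanh_s, w_s = _forward_kernel(
        np.ascontiguousarray(U),
        np.ascontiguousarray(A),
        np.ascontiguousarray(rmax),
        np.ascontiguousarray(r0),
        np.ascontiguousarray(iota),
        np.ascontiguousarray(lick_vec),
        np.ascontiguousarray(lick_rate),
        np.ascontiguousarray(start_idx, dtype=np.int64),
        float(a),
    )
    return rates, (tanh_s, w_s, start_idx, lick_rate)


def backward(U, A, rmax, g_rates, rates, caches, a=0.125):
    """Chain an arbitrary dL/d(rates) field back to the parameters.

    Returns (dU, dA, drmax, diota, dlick, dr0); ``diota[k, t]`` is the
    gradient of the latent input applied at step t of trial k, ``dlick[k]``
    of trial k's lick weight vector, and ``dr0`` of the shared initial
    state.
    """
    tanh_s, w_s, start_idx, lick_rate = caches
    return _backward_kernel(
        np.ascontiguousarray(U),
        np.ascontiguousarray(A),
        np.ascontiguousarray(rmax),
        np.ascontiguousarray(g_rates),
        np.ascontiguousarray(rates),
        tanh_s,
        w_s,
        np.ascontiguousarray(lick_rate),
        np.ascontiguousarray(start_idx, dtype=np.int64),
        float(a),
    )
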