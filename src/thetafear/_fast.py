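"""Numba-accelerated conditioning kernel.

The conditioning epoch advances, for one fear cell, M synapses through T
forward-Euler steps (NMDA gating recursions, BPAP/theta spine voltage,
magnesium block, calcium ODE, plasticity ODE). The numpy path in
:mod:`thetafear.synapse` materialises (M, T) arrays; this kernel fuses the
same recurrences into a single pass with O(M) state, using dense lookup
tables for the two smooth calcium nonlinearities (eta, Omega). Tests check
it against the numpy path.

Falls back gracefully: ``HAVE_NUMBA`` is False when numba is missing and
callers use the numpy path.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _cell_epoch_kernel(
    place_bins,        # (M, T) float64 spike counts per bin
    fear_bins,         # (T,) float64
    theta_v,           # (T,) float64 additive spine oscillation, mV
    w,                 # (M,) float64 initial weights, modified in place
    ca_grid_step,      # float: table spacing in uM
    eta_tab,           # (G,) eta values, 1/s
    om_tab,            # (G,) Omega values
    d_gf, d_gs,        # NMDA gating per-step decay factors
    i_f, i_s,
    d_bf, d_bs,        # BPAP per-step decay factors
    i_fbs, i_sbs,
    v_rest, e_ca, mg_over, amp,
    a1_ca, dt, dtp, lam, ach, lam_scales_w,
):
    M, T = place_bins.shape
    gf = np.zeros(M)
    gs = np.zeros(M)
    ca = np.zeros(M)
    bf = 0.0
    bs = 0.0
    n_tab = eta_tab.shape[0]
    inv_step = 1.0 / ca_grid_step
    for t in range(T):
        s = fear_bins[t]
        bf = bf * d_bf + s
        bs = bs * d_bs + s
        v = v_rest + 100.0 * (i_fbs * bf + i_sbs * bs) + theta_v[t]
        h = (v - e_ca) / (1.0 + np.exp(-0.062 * v) * mg_over)
        hamp = amp * h
        for j in range(M):
            # plasticity uses calcium at the current step (before update)
            x = ca[j] * inv_step
            k = int(x)
            if k >= n_tab - 1:
                e = eta_tab[n_tab - 1]
                om = om_tab[n_tab - 1]
            else:
                f = x - k
                e = eta_tab[k] * (1.0 - f) + eta_tab[k + 1] * f
                om = om_tab[k] * (1.0 - f) + om_tab[k + 1] * f
            if lam_scales_w:
                w[j] += dtp * e * (om * ach - lam * w[j])
            else:
                w[j] += dtp * e * (om * ach - lam)
                if w[j] < 0.0:
                    w[j] = 0.0
            # NMDA gating includes the current bin's spikes
            b = place_bins[j, t]
            gf[j] = gf[j] * d_gf + b
            gs[j] = gs[j] * d_gs + b
            ca[j] = a1_ca * ca[j] + dt * hamp * (i_f * gf[j] + i_s * gs[j])
            if ca[j] < 0.0:
                ca[j] = 0.0
    return w


_CA_GRID_STEP = 5e-4
_table_cache: dict = {}


def _tables(p):
    key = (p.p1, p.p2, p.p3, p.p4, p.alpha1, p.alpha2, p.beta1, p.beta2)
    if key not in _table_cache:
        from .synapse import eta as eta_fn, omega as omega_fn

        grid = np.arange(0.0, 10.0 + _CA_GRID_STEP, _CA_GRID_STEP)
        _table_cache[key] = (eta_fn(grid, p), omega_fn(grid, p))
    return _table_cache[key]


def cell_epoch(place_bins, fear_bins, theta_v, w0_vec, p, ach):
    """Run one fear cell's conditioning epoch with the fused kernel.

    Returns the final per-synapse weights. Signature mirrors the numpy
    reference path in :mod:`thetafear.protocols`.
    """
    import math

    ca_grid_step = _CA_GRID_STEP
    eta_tab, om_tab = _tables(p)
    w = np.array(w0_vec, dtype=float)
    return _cell_epoch_kernel(
        np.ascontiguousarray(place_bins, dtype=np.float64),
        np.ascontiguousarray(fear_bins, dtype=np.float64),
        np.ascontiguousarray(theta_v, dtype=np.float64),
        w,
        ca_grid_step,
        eta_tab,
        om_tab,
        math.exp(-p.dt / p.tau_f),
        math.exp(-p.dt / p.tau_s),
        p.i_f,
        p.i_s,
        math.exp(-p.dt / p.tau_fbs),
        math.exp(-p.dt / p.tau_sbs),
        p.i_fbs,
        p.i_sbs,
        p.v_rest,
        p.e_ca,
        p.mg / 3.57,
        p.p0 * p.g_nmda,
        1.0 - p.dt / p.tau_ca,
        p.dt,
        p.dt / 1000.0,
        p.lam,
        ach,
        p.lam_scales_w,
    )
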