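"""Dendritic-spine dynamics and the calcium-controlled plasticity rule.

The spine membrane potential is a linear superposition around rest of
weighted EPSPs (double exponential, suppressed by acetylcholine), BPAPs
triggered by somatic output spikes (fast + slow double exponential peaking
at 100 mV), and a subthreshold theta oscillation. NMDA receptor currents —
the sole calcium source — combine a presynaptic gating trace (fast + slow
exponentials) with the voltage-dependent magnesium-block term H(V).
Calcium obeys d[Ca]/dt = I_NMDA - [Ca]/tau_ca and the synaptic strength
follows the calcium-control rule dW/dt = eta([Ca]) * (Omega([Ca])*ACh - lambda*W)
(weight-proportional decay by default; the constant-decay reading is a
config switch), with eta expressed in 1/s.

Two equivalent computational paths are provided and cross-checked in tests:

* a literal per-step forward-Euler update (:func:`step_state`) on a
  :class:`SynapseState`, convenient for small oracles and traces;
* vectorised trace builders (``*_trace`` functions) that evaluate the
  exponential kernels by exact first-order recursions (``scipy.signal.lfilter``)
  and integrate the two ODEs with the same forward-Euler rule over whole
  epochs at once. These power the protocol runners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .params import ParamSet
from .spike_gen import SpikeTrain

__all__ = [
    "SynapseState",
    "epsp_kernel",
    "calibrate_s",
    "resolve_s",
    "bpap_kernel",
    "mg_block",
    "omega",
    "eta",
    "nmda_current",
    "spine_voltage",
    "step_state",
    "exp_trace",
    "epsp_trace",
    "bpap_trace",
    "nmda_gating_trace",
    "euler_calcium",
    "weight_increments",
    "integrate_weight",
    "weight_trajectory",
    "calcium_trace_clamped",
    "calcium_closed_form_single_spike",
]


# ---------------------------------------------------------------------------
# kernels and pointwise model functions
# ---------------------------------------------------------------------------

def epsp_kernel(t_since, ach: float, s: float, p: ParamSet):
    """EPSP depolarisation (mV) ``t_since`` ms after a presynaptic spike.

    (1 - ACh) * s * (exp(-t/tau1_ep) - exp(-t/tau2_ep)); zero at t = 0 and
    non-negative for tau1_ep > tau2_ep. Fully suppressed at ACh = 1.
    """
    t = np.asarray(t_since, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since must be >= 0")
    out = (1.0 - ach) * s * (np.exp(-t / p.tau1_ep) - np.exp(-t / p.tau2_ep))
    return float(out) if np.isscalar(t_since) else out


def epsp_peak_time(p: ParamSet) -> float:
    """Time of the EPSP kernel maximum: ln(tau1/tau2) * tau1*tau2/(tau1-tau2)."""
    t1, t2 = p.tau1_ep, p.tau2_ep
    return math.log(t1 / t2) * t1 * t2 / (t1 - t2)


def calibrate_s(target_peak: float, p: ParamSet) -> float:
    """Gain ``s`` such that the ACh-free EPSP kernel peaks at ``target_peak`` mV."""
    if target_peak <= 0:
        raise ValueError("target_peak must be > 0")
    tstar = epsp_peak_time(p)
    peak_unit = math.exp(-tstar / p.tau1_ep) - math.exp(-tstar / p.tau2_ep)
    return target_peak / peak_unit


def resolve_s(p: ParamSet) -> float:
    """The configured EPSP gain, calibrating to ``epsp_peak_mv`` when unset."""
    return p.s_epsp if p.s_epsp is not None else calibrate_s(p.epsp_peak_mv, p)


def bpap_kernel(t_since, p: ParamSet):
    """BPAP depolarisation (mV) ``t_since`` ms after a somatic output spike.

    100 * (I_fbs * exp(-t/tau_fbs) + I_sbs * exp(-t/tau_sbs)); peaks at
    100 mV at t = 0 because the two amplitudes sum to 1.
    """
    t = np.asarray(t_since, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since must be >= 0")
    out = 100.0 * (p.i_fbs * np.exp(-t / p.tau_fbs) + p.i_sbs * np.exp(-t / p.tau_sbs))
    return float(out) if np.isscalar(t_since) else out


def mg_block(v, p: ParamSet):
    """Magnesium-block gating times driving force: (V - E_Ca) / (1 + e^(-0.062 V) [Mg]/3.57).

    Negative below the calcium reversal potential; multiplied by the
    negative conductance ``g_nmda`` it yields calcium influx.
    """
    v_arr = np.asarray(v, dtype=float)
    out = (v_arr - p.e_ca) / (1.0 + np.exp(-0.062 * v_arr) * p.mg / 3.57)
    return float(out) if np.isscalar(v) else out


def _sig(x, beta):
    return expit(beta * np.asarray(x, dtype=float))


def omega(ca, p: ParamSet):
    """Sign/magnitude function of calcium-controlled plasticity (dimensionless).

    0.25 + sig_beta2(ca - alpha2) - 0.25 * sig_beta1(ca - alpha1):
    ~0.25 at zero calcium, dips toward 0 between alpha1 and alpha2
    (depression zone), and saturates at 1 for high calcium (potentiation).
    """
    ca_arr = np.asarray(ca, dtype=float)
    out = 0.25 + _sig(ca_arr - p.alpha2, p.beta2) - 0.25 * _sig(ca_arr - p.alpha1, p.beta1)
    return float(out) if np.isscalar(ca) else out


def eta(ca, p: ParamSet):
    """Calcium-dependent learning rate, 1/s: (p1/(p2 + ca^p3) + p4)^-1.

    Monotone increasing in calcium, bounded in (0, 1/p4]; ~1e-4 /s at zero
    calcium with the default p2 = 1e-5, so baseline drift is negligible.
    """
    ca_arr = np.asarray(ca, dtype=float)
    out = 1.0 / (p.p1 / (p.p2 + ca_arr ** p.p3) + p.p4)
    return float(out) if np.isscalar(ca) else out


# ---------------------------------------------------------------------------
# scalar reference path
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    """Time-evolving state of one dendritic spine.

    ``pre_spikes``/``post_spikes`` hold the presynaptic (place-cell) and
    postsynaptic (fear-cell) spike times driving the kernels; ``v_spine``,
    ``ca`` and ``w`` are the instantaneous spine potential (mV), calcium
    concentration (uM) and synaptic strength.
    """

    pre_spikes: SpikeTrain
    post_spikes: SpikeTrain
    v_spine: float = -65.0
    ca: float = 0.0
    w: float = 0.5


def nmda_current(
    t: float,
    state: SynapseState,
    p: ParamSet,
    v: Optional[float] = None,
) -> float:
    """NMDA-mediated calcium influx (uM/ms) at time ``t``.

    Linear (non-saturating) sum of the gating kernel over all presynaptic
    spikes up to ``t``, times the magnesium-block term at the spine voltage
    (``v`` overrides ``state.v_spine`` for clamped-voltage oracles).
    """
    pre = state.pre_spikes.times
    pre = pre[pre <= t]
    if pre.size == 0:
        return 0.0
    dt_since = t - pre
    gate = np.sum(p.i_f * np.exp(-dt_since / p.tau_f) + p.i_s * np.exp(-dt_since / p.tau_s))
    v_now = state.v_spine if v is None else v
    return p.p0 * p.g_nmda * float(gate) * mg_block(v_now, p)


def spine_voltage(
    t: float,
    state: SynapseState,
    p: ParamSet,
    f_theta: Optional[float] = None,
    ach: Optional[float] = None,
    s: Optional[float] = None,
    w_scale: bool = False,
) -> float:
    """Spine membrane potential (mV) at time ``t`` from the kernel sums.

    v_rest + sum_i w~ * EPSP(t - t_i) + sum_0 BPAP(t - t_0)
    [+ a_theta * sin(2*pi*f_theta*t) when enabled], where w~ is W/w0 if
    ``w_scale`` (the recall read-out pathway) and 1 otherwise.
    """
    ach_eff = p.ach if ach is None else ach
    s_eff = resolve_s(p) if s is None else s
    v = p.v_rest
    pre = state.pre_spikes.times
    pre = pre[pre <= t]
    if pre.size and ach_eff < 1.0:
        scale = (state.w / p.w0) if w_scale else 1.0
        v += scale * float(np.sum(epsp_kernel(t - pre, ach_eff, s_eff, p)))
    post = state.post_spikes.times
    post = post[post <= t]
    if post.size:
        v += float(np.sum(bpap_kernel(t - post, p)))
    if f_theta is not None and p.theta_in_spine:
        v += p.a_theta * math.sin(2e-3 * math.pi * f_theta * t)
    return v


def step_state(
    state: SynapseState,
    t: float,
    dt: float,
    plasticity_on: bool,
    p: ParamSet,
    f_theta: Optional[float] = None,
    ach: Optional[float] = None,
    ach_plasticity: Optional[float] = None,
    clamp_v: Optional[float] = None,
) -> SynapseState:
    """Advance the spine by one forward-Euler step from time ``t`` to ``t + dt``.

    Calcium and (when ``plasticity_on``) the weight are updated from the
    state at ``t`` and floored at 0. ``ach`` gates the EPSP, and
    ``ach_plasticity`` multiplies Omega in the weight rule; both default to
    ``p.ach``. ``clamp_v`` pins the voltage (for analytic oracles).
    """
    ach_eff = p.ach if ach is None else ach
    ach_pl = ach_eff if ach_plasticity is None else ach_plasticity
    v = clamp_v if clamp_v is not None else spine_voltage(
        t, state, p, f_theta=f_theta, ach=ach_eff
    )
    i_nmda = nmda_current(t, state, p, v=v)
    ca_next = max(0.0, state.ca + dt * (i_nmda - state.ca / p.tau_ca))
    w_next = state.w
    if plasticity_on:
        decay = p.lam * state.w if p.lam_scales_w else p.lam
        dw = (dt / 1000.0) * eta(state.ca, p) * (omega(state.ca, p) * ach_pl - decay)
        w_next = max(0.0, state.w + dw)
    return SynapseState(
        pre_spikes=state.pre_spikes,
        post_spikes=state.post_spikes,
        v_spine=v,
        ca=ca_next,
        w=w_next,
    )


# ---------------------------------------------------------------------------
# vectorised epoch path
# ---------------------------------------------------------------------------

def exp_trace(impulses: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Sum of exp(-(t - t_i)/tau) over impulses, evaluated on the dt-grid.

    Exact at grid points: implemented as the first-order recursion
    y[n] = exp(-dt/tau) * y[n-1] + impulses[n], vectorised along the last
    axis with ``lfilter``. A spike contributes 1 in its own bin.
    """
    decay = math.exp(-dt / tau)
    return lfilter([1.0], [1.0, -decay], impulses, axis=-1)


def epsp_trace(impulses: np.ndarray, ach: float, s: float, p: ParamSet) -> np.ndarray:
    """EPSP kernel summed over an impulse train on the grid (mV)."""
    return (1.0 - ach) * s * (
        exp_trace(impulses, p.tau1_ep, p.dt) - exp_trace(impulses, p.tau2_ep, p.dt)
    )


def bpap_trace(impulses: np.ndarray, p: ParamSet) -> np.ndarray:
    """BPAP kernel summed over an impulse train on the grid (mV)."""
    return 100.0 * (
        p.i_fbs * exp_trace(impulses, p.tau_fbs, p.dt)
        + p.i_sbs * exp_trace(impulses, p.tau_sbs, p.dt)
    )


def nmda_gating_trace(impulses: np.ndarray, p: ParamSet) -> np.ndarray:
    """Presynaptic NMDA gating trace (dimensionless), linear over spikes."""
    return p.i_f * exp_trace(impulses, p.tau_f, p.dt) + p.i_s * exp_trace(
        impulses, p.tau_s, p.dt
    )


def euler_calcium(influx: np.ndarray, p: ParamSet, ca0: float = 0.0) -> np.ndarray:
    """Forward-Euler calcium trace from an influx array (uM).

    ca[n] = (1 - dt/tau_ca) * ca[n-1] + dt * influx[n-1], matching the
    per-step update of :func:`step_state` exactly (ca[0] = ca0).
    """
    a1 = 1.0 - p.dt / p.tau_ca
    shifted = np.concatenate(
        [np.zeros(influx.shape[:-1] + (1,)), influx[..., :-1]], axis=-1
    )
    # transposed direct-form II: y[0] = b0*x[0] + zi = ca0 since x[0] = 0
    zi = np.full(influx.shape[:-1] + (1,), float(ca0))
    out, _ = lfilter([p.dt], [1.0, -a1], shifted, axis=-1, zi=zi)
    return out


def weight_increments(ca: np.ndarray, ach_plasticity: float, p: ParamSet) -> np.ndarray:
    """Per-step weight changes dt/1000 * eta(ca) * (Omega(ca)*ACh - lambda)."""
    return (p.dt / 1000.0) * eta(ca, p) * (omega(ca, p) * ach_plasticity - p.lam)


def integrate_plasticity(w0, ca: np.ndarray, ach_plasticity: float, p: ParamSet) -> np.ndarray:
    """Final weight after forward-Euler integration of the plasticity rule.

    With the weight-proportional decay (default, ``lam_scales_w``):
    W[n+1] = W[n] + dt' * eta[n] * (Omega[n]*ACh - lambda*W[n]) — a linear
    recursion with time-varying coefficients, solved in closed form via the
    product of per-step factors (dt' = dt/1000, eta in 1/s). With the
    constant-decay reading, the per-step floor at 0 is applied via
    :func:`integrate_weight`. Vectorised along the last axis.
    """
    dtp = p.dt / 1000.0
    e = eta(ca, p)
    om_drive = dtp * e * (omega(ca, p) * ach_plasticity)
    if not p.lam_scales_w:
        return integrate_weight(w0, om_drive - dtp * e * p.lam)
    # W_T = exp(L_T) * (w0 + sum_n b[n] * exp(-L[n])), L = cumsum(log a)
    log_a = np.log1p(-dtp * p.lam * e)
    cum = np.cumsum(log_a, axis=-1)
    total = cum[..., -1]
    return np.exp(total) * (w0 + np.sum(om_drive * np.exp(-cum), axis=-1))


def plasticity_trajectory(w0: float, ca: np.ndarray, ach_plasticity: float,
                          p: ParamSet) -> np.ndarray:
    """Full weight trajectory under the plasticity rule (1-d calcium trace).

    Same recursions as :func:`integrate_plasticity` but returning every
    step; used for trace dumps and diagnostics.
    """
    dtp = p.dt / 1000.0
    e = eta(ca, p)
    om_drive = dtp * e * (omega(ca, p) * ach_plasticity)
    if not p.lam_scales_w:
        return weight_trajectory(w0, om_drive - dtp * e * p.lam)
    cum = np.cumsum(np.log1p(-dtp * p.lam * e))
    return np.exp(cum) * (w0 + np.cumsum(om_drive * np.exp(-cum)))


def plasticity_equilibrium_drift(w0, duration_ms: float, ca: float,
                                 ach_plasticity: float, p: ParamSet):
    """Closed-form weight after ``duration_ms`` at constant calcium ``ca``.

    Used for synapses receiving no input (calcium pinned at a constant,
    typically 0): with weight-proportional decay the weight relaxes toward
    Omega*ACh/lambda at rate eta*lambda; with constant decay it moves
    linearly (floored at 0).
    """
    e = eta(ca, p)
    om = omega(ca, p) * ach_plasticity
    t_s = duration_ms / 1000.0
    if not p.lam_scales_w:
        return np.maximum(np.asarray(w0) + e * (om - p.lam) * t_s, 0.0)
    if p.lam == 0:
        return np.asarray(w0) + e * om * t_s
    w_eq = om / p.lam
    return w_eq + (np.asarray(w0) - w_eq) * math.exp(-e * p.lam * t_s)


def increment_interpolator(ach_plasticity: float, p: ParamSet, ca_max: float = 10.0,
                           n_grid: int = 20001):
    """Tabulated per-step weight increment as a function of calcium.

    eta and Omega are smooth scalar functions of calcium alone, so the Euler
    increment dt/1000 * eta(ca) * (Omega(ca)*ACh - lambda) is precomputed on
    a dense grid and evaluated by linear interpolation (both saturate well
    below ``ca_max``, where the table is clamped). Returns a callable
    mapping a calcium array to increments; used by the protocol runners,
    cross-checked against :func:`weight_increments` in tests.
    """
    grid = np.linspace(0.0, ca_max, n_grid)
    table = weight_increments(grid, ach_plasticity, p)

    def interp(ca: np.ndarray) -> np.ndarray:
        return np.interp(ca, grid, table)

    return interp


def integrate_weight(w0, increments: np.ndarray) -> np.ndarray:
    """Final weight after applying ``increments`` with a floor at 0 each step.

    Uses the reflection (Lindley) identity for the recursion
    W[n] = max(0, W[n-1] + d[n]):  W[n] = max(w0 + S[n], S[n] - min_{k<=n} S[k])
    with S the running sum. Vectorised along the last axis (``w0`` may be a
    scalar or an array matching the leading dimensions); returns the final
    weight(s).
    """
    s_total = np.cumsum(increments, axis=-1)
    run_min = np.minimum(s_total.min(axis=-1), 0.0)
    return np.maximum(w0 + s_total[..., -1], s_total[..., -1] - run_min)


def weight_trajectory(w0: float, increments: np.ndarray) -> np.ndarray:
    """Full floored-weight trajectory (same recursion as :func:`integrate_weight`)."""
    s_total = np.cumsum(increments, axis=-1)
    run_min = np.minimum(np.minimum.accumulate(s_total, axis=-1), 0.0)
    return np.maximum(w0 + s_total, s_total - run_min)


def calcium_trace_clamped(
    pre_bins: np.ndarray, v_clamp: float, p: ParamSet
) -> np.ndarray:
    """Euler calcium trace with the spine voltage clamped at ``v_clamp``."""
    influx = p.p0 * p.g_nmda * mg_block(v_clamp, p) * nmda_gating_trace(pre_bins, p)
    return euler_calcium(influx, p)


def calcium_closed_form_single_spike(
    t: np.ndarray, t_spike: float, v_clamp: float, p: ParamSet
) -> np.ndarray:
    """Analytic calcium response to one presynaptic spike at clamped voltage.

    With I(t) = A * (I_f e^(-t/tau_f) + I_s e^(-t/tau_s)) driving
    dCa/dt = I - Ca/tau_ca from zero, each exponential component x yields
    A*I_x * tau_x*tau_ca/(tau_x - tau_ca) * (e^(-t/tau_x) - e^(-t/tau_ca)).
    Independent oracle for the Euler integrator.
    """
    amp = p.p0 * p.g_nmda * mg_block(v_clamp, p)
    tt = np.asarray(t, dtype=float) - t_spike
    out = np.zeros_like(tt)
    mask = tt >= 0
    for i_x, tau_x in ((p.i_f, p.tau_f), (p.i_s, p.tau_s)):
        if math.isclose(tau_x, p.tau_ca):
            # degenerate equal-time-constant case: A*I_x * t * e^(-t/tau)
            out[mask] += amp * i_x * tt[mask] * np.exp(-tt[mask] / tau_x)
        else:
            coeff = amp * i_x * tau_x * p.tau_ca / (tau_x - p.tau_ca)
            out[mask] += coeff * (
                np.exp(-tt[mask] / tau_x) - np.exp(-tt[mask] / p.tau_ca)
            )
    return out
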