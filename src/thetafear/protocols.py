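"""Stimulation protocols: tetanus, contextual conditioning, recall, freezing.

Three experiments drive the spine model:

* **Tetanus** — a presynaptic train (100 spikes at a chosen frequency)
  with no postsynaptic spiking, decay constant lambda = 1 and EPSP gain
  s = 1.45; probes the frequency dependence of the plasticity rule in
  isolation. The default drive is the same theta-modulated Poisson train
  the place-cell generator produces (a regular evenly spaced train is
  available as an option).
* **Conditioning** — the simulated animal spends 100 theta periods in each
  of two compartments (safe/threat). Each fear cell receives its own
  subpopulation of place cells per compartment (independent spike trains
  across fear cells); place cells of the occupied compartment fire
  theta-modulated Poisson trains while fear cells fire homogeneous Poisson
  trains (slow in the safe, faster in the threat compartment, reflecting
  noxious input), each output spike broadcasting a BPAP to all of that
  cell's spines. ACh = 1: EPSPs are suppressed and the calcium-control
  rule is active, so weights record the place->fear coincidence structure.
* **Recall** — ACh = 0 and plasticity is frozen; theta runs at 5 Hz for 25
  periods per compartment. Fear-cell somata average their spine potentials
  (EPSPs now active, scaled by the learned W/w0) and fire when crossing
  threshold, after which all spines reset and relax back toward rest with
  the membrane time constant. Freezing is declared in a compartment when
  the population mean output rate exceeds ``r_freeze``.

During conditioning the EPSP suppression at ACh = 1 makes both the spine
voltage and the calcium trace independent of the evolving weights, so each
epoch is integrated in closed vectorised form (kernel recursions, Euler
calcium, linear weight recursion) rather than step-by-step; the recall
phase has genuine state dependence (threshold/reset) and uses an
event-driven threshold scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import _fast
from . import synapse as sy
from .params import ParamSet
from .spike_gen import SpikeTrain, place_cell_rate, sample_homogeneous_poisson
from .spectral import PowerSpectrum, population_spectrum

__all__ = [
    "COMPARTMENTS",
    "ConditioningResult",
    "RecallResult",
    "run_tetanus",
    "run_conditioning",
    "conditioning_trace",
    "run_recall",
    "freezing_probability",
]

COMPARTMENTS = ("safe", "threat")


def _as_seedseq(stream) -> np.random.SeedSequence:
    if isinstance(stream, np.random.SeedSequence):
        return stream
    return np.random.SeedSequence(stream)


@dataclass(frozen=True)
class ConditioningResult:
    """Final synaptic strengths after a conditioning run.

    ``weights`` has shape (n_fear, 2, n_pc) indexed by fear cell,
    compartment (order :data:`COMPARTMENTS`) and place cell, in absolute
    units; ``relative`` divides by w0 (the quantity reported in results).
    """

    weights: np.ndarray
    f_theta_cond: float
    w0: float
    seed_entropy: object = None

    @property
    def relative(self) -> np.ndarray:
        return self.weights / self.w0

    def mean_relative(self, compartment: str) -> float:
        """Mean W/w0 over all synapses of one compartment."""
        return float(self.relative[:, COMPARTMENTS.index(compartment), :].mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (fear_cell_id, place_cell_id, compartment, w, w_rel)."""
        n_fear, _, n_pc = self.weights.shape
        rows = []
        for i in range(n_fear):
            for c, comp in enumerate(COMPARTMENTS):
                for j in range(n_pc):
                    rows.append((i, j, comp, self.weights[i, c, j]))
        df = pd.DataFrame(rows, columns=["fear_cell_id", "place_cell_id", "compartment", "w"])
        df["w_rel"] = df["w"] / self.w0
        df["f_theta_cond"] = self.f_theta_cond
        return df


@dataclass(frozen=True)
class RecallResult:
    """Fear-cell output during recall, per compartment.

    ``mean_rate`` is the population mean output rate (Hz); ``froze`` flags
    compartments whose mean rate exceeds the freezing threshold.
    """

    fear_spike_trains: Dict[str, list]
    mean_rate: Dict[str, float]
    froze: Dict[str, bool]
    spectrum: Dict[str, PowerSpectrum]
    f_theta_recall: float
    duration: float


def run_tetanus(
    f_stim: float,
    n_spikes: int = 100,
    p: Optional[ParamSet] = None,
    train: str = "theta",
    rng_stream=None,
    n_realizations: int = 1,
) -> float:
    """Final relative weight W/w0 after a rate-induced plasticity train.

    ``n_spikes`` presynaptic spikes (in expectation) are delivered at
    frequency ``f_stim`` Hz with no output spiking, decay constant
    lambda = 1 and EPSP gain s = 1.45 (plasticity gate fully open, the
    EPSP active as the depolarisation source).

    ``train`` selects the drive:

    * ``"theta"`` (default) — the place-cell generator's theta-modulated
      inhomogeneous Poisson train plus the subthreshold theta oscillation
      of the spine, i.e. the same rhythmic drive the conditioning protocol
      delivers, averaged over ``n_realizations`` seeded train draws;
    * ``"regular"`` — a deterministic evenly spaced train with no theta
      term (classic in-vitro tetanus timing).

    Reproducible: the default stream derives from ``p.seed``.
    """
    if f_stim <= 0:
        raise ValueError("f_stim must be > 0")
    if train not in ("theta", "regular"):
        raise ValueError("train must be 'theta' or 'regular'")
    p = (p or ParamSet()).replace(lam=1.0, s_epsp=1.45)
    dt = p.dt
    duration = n_spikes * 1000.0 / f_stim
    n_steps = int(round(duration / dt))
    grid_t = np.arange(n_steps) * dt
    if train == "regular":
        bins_list = [np.zeros(n_steps)]
        idx = np.minimum(
            np.round(np.arange(n_spikes) * (1000.0 / f_stim) / dt).astype(np.int64),
            n_steps - 1,
        )
        np.add.at(bins_list[0], idx, 1.0)
        theta_v = 0.0
    else:
        ss = _as_seedseq(rng_stream if rng_stream is not None else p.seed)
        prob = place_cell_rate(grid_t, f_stim, n_spikes, duration, dt) * dt
        bins_list = [
            (np.random.default_rng(child).random(n_steps) < prob).astype(float)
            for child in ss.spawn(n_realizations)
        ]
        theta_v = (
            p.a_theta * np.sin(2e-3 * np.pi * f_stim * grid_t)
            if p.theta_in_spine
            else 0.0
        )
    finals = []
    for bins in bins_list:
        v = p.v_rest + sy.epsp_trace(bins, 0.0, 1.45, p) + theta_v
        influx = p.p0 * p.g_nmda * sy.nmda_gating_trace(bins, p) * sy.mg_block(v, p)
        ca = sy.euler_calcium(influx, p)
        finals.append(float(sy.integrate_plasticity(p.w0, ca, 1.0, p)))
    return float(np.mean(finals)) / p.w0


def _zero_calcium_drift(weights: np.ndarray, duration_ms: float, p: ParamSet) -> np.ndarray:
    """Weights of input-free synapses after an epoch at zero calcium.

    Applied to the inactive compartment's synapses during the other
    compartment's epoch (closed-form; negligible at defaults since
    eta(0) ~ 1e-4 /s, but kept for exactness).
    """
    return sy.plasticity_equilibrium_drift(weights, duration_ms, 0.0, p.ach, p)


def _sample_place_bins(
    ss: np.random.SeedSequence, prob: np.ndarray, n_pc: int
) -> np.ndarray:
    """Bernoulli spike bins for ``n_pc`` place cells from child streams of ``ss``."""
    bins = np.empty((n_pc, prob.size))
    for j, child in enumerate(ss.spawn(n_pc)):
        rng = np.random.default_rng(child)
        bins[j] = rng.random(prob.size) < prob
    return bins


def _cell_epoch_numpy(
    place_bins: np.ndarray,
    fear_bins: np.ndarray,
    theta_v,
    w_start: np.ndarray,
    p: ParamSet,
) -> np.ndarray:
    """Reference vectorised path for one fear cell's conditioning epoch.

    ACh = 1 suppresses EPSPs, so the spine voltage (BPAPs + theta around
    rest) and hence calcium are independent of the evolving weights and the
    whole epoch integrates in closed vectorised form.
    """
    v = p.v_rest + sy.bpap_trace(fear_bins, p) + theta_v
    h = sy.mg_block(v, p)
    influx = (p.p0 * p.g_nmda) * sy.nmda_gating_trace(place_bins, p) * h
    ca = sy.euler_calcium(influx, p)
    return sy.integrate_plasticity(w_start, ca, p.ach, p)


def _conditioning_epoch(
    weights: np.ndarray,
    f_theta: float,
    r_fear: float,
    p: ParamSet,
    ss: np.random.SeedSequence,
    use_fast: Optional[bool] = None,
) -> np.ndarray:
    """Advance ``weights`` (n_fear, n_pc) through one conditioning epoch.

    Each fear cell receives its own place-cell subpopulation (independent
    spike trains; see the module docstring) and its own exogenous Poisson
    output train at ``r_fear`` broadcasting BPAPs to all its spines.
    """
    n_fear, n_pc = weights.shape
    duration = p.n_cycles_cond / f_theta * 1000.0
    n_steps = int(round(duration / p.dt))
    k = p.k_for_cycles(p.n_cycles_cond)
    grid_t = np.arange(n_steps) * p.dt
    prob = place_cell_rate(grid_t, f_theta, k, duration, p.dt) * p.dt
    theta_v = (
        p.a_theta * np.sin(2e-3 * np.pi * f_theta * grid_t)
        if p.theta_in_spine
        else np.zeros(n_steps)
    )
    if use_fast is None:
        use_fast = _fast.HAVE_NUMBA
    out = np.empty_like(weights)
    for i, cell_ss in enumerate(ss.spawn(n_fear)):
        place_ss, fear_ss = cell_ss.spawn(2)
        place_bins = _sample_place_bins(place_ss, prob, n_pc)
        fear_train = sample_homogeneous_poisson(
            r_fear, duration, np.random.default_rng(fear_ss), dt=p.dt, cell_id=i
        )
        fear_bins = fear_train.to_bins(p.dt)
        if use_fast:
            out[i] = _fast.cell_epoch(
                place_bins, fear_bins, theta_v, weights[i], p, p.ach
            )
        else:
            out[i] = _cell_epoch_numpy(place_bins, fear_bins, theta_v, weights[i], p)
    return out


def run_conditioning(
    f_theta: float,
    p: Optional[ParamSet] = None,
    rng_stream=None,
    use_fast: Optional[bool] = None,
) -> ConditioningResult:
    """Simulate contextual conditioning at theta frequency ``f_theta`` (Hz).

    The agent spends ``n_cycles_cond`` theta periods in the safe and then
    the threat compartment with ACh = 1. Returns the final weights of every
    (fear cell, compartment, place cell) synapse.
    """
    if f_theta <= 0:
        raise ValueError("f_theta must be > 0")
    p = p or ParamSet()
    ss = _as_seedseq(rng_stream if rng_stream is not None else p.seed)
    epoch_ss = ss.spawn(2)
    n_pc = p.n_pc_per_compartment
    weights = np.full((p.n_fear, 2, n_pc), float(p.w0))
    rates = {"safe": p.r_safe, "threat": p.r_threat}
    for c, comp in enumerate(COMPARTMENTS):
        duration = p.n_cycles_cond / f_theta * 1000.0
        weights[:, c, :] = _conditioning_epoch(
            weights[:, c, :], f_theta, rates[comp], p, epoch_ss[c], use_fast=use_fast
        )
        other = 1 - c
        weights[:, other, :] = _zero_calcium_drift(weights[:, other, :], duration, p)
    return ConditioningResult(
        weights=weights,
        f_theta_cond=f_theta,
        w0=p.w0,
        seed_entropy=ss.entropy,
    )


def _threshold_scan(
    drive: np.ndarray, relax: np.ndarray, v_thr: float, refract_steps: int
) -> np.ndarray:
    """Indices of threshold crossings with reset-relaxation and refractoriness.

    ``drive`` is the soma potential absent any reset; after a spike at step
    s the relaxation ``relax[k]`` (k steps since the spike) is added until
    the next spike. Crossings during the refractory window are ignored.
    """
    n = drive.size
    spikes: list[int] = []
    idx = 0
    last = -1
    while idx < n:
        if last < 0:
            above = drive[idx:] > v_thr
        else:
            k0 = idx - last
            above = (drive[idx:] + relax[k0 : k0 + n - idx]) > v_thr
        j = int(np.argmax(above))
        if not above[j]:
            break
        s = idx + j
        spikes.append(s)
        last = s
        idx = s + max(refract_steps, 1)
    return np.asarray(spikes, dtype=np.int64)


def conditioning_trace(
    f_theta: float,
    p: Optional[ParamSet] = None,
    rng_stream=None,
    compartment: str = "threat",
    fear_cell: int = 0,
    place_cell: int = 0,
) -> pd.DataFrame:
    """Per-step state trace (t, V_s, Ca, W) of one designated synapse.

    Reproduces exactly the spike trains the corresponding synapse receives
    in :func:`run_conditioning` under the same stream (same seed tree), and
    returns the full spine-voltage, calcium and weight trajectories as a
    table. Intended for diagnostics and trace dumps, not bulk simulation.
    """
    p = p or ParamSet()
    c = COMPARTMENTS.index(compartment)
    r_fear = {"safe": p.r_safe, "threat": p.r_threat}[compartment]
    ss = _as_seedseq(rng_stream if rng_stream is not None else p.seed)
    epoch_ss = ss.spawn(2)[c]
    duration = p.n_cycles_cond / f_theta * 1000.0
    n_steps = int(round(duration / p.dt))
    grid_t = np.arange(n_steps) * p.dt
    k = p.k_for_cycles(p.n_cycles_cond)
    prob = place_cell_rate(grid_t, f_theta, k, duration, p.dt) * p.dt
    cell_ss = epoch_ss.spawn(p.n_fear)[fear_cell]
    place_ss, fear_ss = cell_ss.spawn(2)
    place_bins = _sample_place_bins(place_ss, prob, p.n_pc_per_compartment)
    fear_train = sample_homogeneous_poisson(
        r_fear, duration, np.random.default_rng(fear_ss), dt=p.dt
    )
    theta_v = (
        p.a_theta * np.sin(2e-3 * np.pi * f_theta * grid_t)
        if p.theta_in_spine
        else np.zeros(n_steps)
    )
    v = p.v_rest + sy.bpap_trace(fear_train.to_bins(p.dt), p) + theta_v
    gating = sy.nmda_gating_trace(place_bins[place_cell], p)
    ca = sy.euler_calcium(p.p0 * p.g_nmda * gating * sy.mg_block(v, p), p)
    w = sy.plasticity_trajectory(p.w0, ca, p.ach, p)
    return pd.DataFrame({"t_ms": grid_t, "v_spine_mv": v, "ca_um": ca, "w": w})


def run_recall(
    cond: ConditioningResult,
    p: Optional[ParamSet] = None,
    rng_stream=None,
    compute_spectra: bool = True,
    weights_override: Optional[np.ndarray] = None,
) -> RecallResult:
    """Simulate contextual recall from conditioned weights.

    ACh = 0 (EPSPs on, plasticity off), theta at ``f_theta_recall`` for
    ``n_cycles_recall`` periods per compartment. The soma of each fear cell
    is the average of its spine potentials; output spikes fire on crossing
    ``v_thr``, resetting every spine to ``v_reset`` with relaxation back to
    rest at the membrane time constant (BPAPs are excluded from the somatic
    drive — plasticity is off and they would only self-excite).

    ``weights_override`` (same shape as ``cond.weights``) substitutes the
    learned weights, e.g. a uniform w0 array for a pre-conditioning
    baseline.
    """
    p = p or ParamSet()
    weights = cond.weights if weights_override is None else weights_override
    if weights.shape != (p.n_fear, 2, p.n_pc_per_compartment):
        raise ValueError(
            "weights shape %s does not match populations (n_fear=%d, n_pc=%d)"
            % (weights.shape, p.n_fear, p.n_pc_per_compartment)
        )
    ss = _as_seedseq(rng_stream if rng_stream is not None else p.seed)
    epoch_ss = ss.spawn(2)
    f_rec = p.f_theta_recall
    duration = p.n_cycles_recall / f_rec * 1000.0
    n_steps = int(round(duration / p.dt))
    grid_t = np.arange(n_steps) * p.dt
    k = p.k_for_cycles(p.n_cycles_recall)
    s_gain = sy.resolve_s(p)
    theta_v = (
        p.a_theta * np.sin(2e-3 * np.pi * f_rec * grid_t) if p.theta_in_spine else 0.0
    )
    relax = (p.v_reset - p.v_rest) * np.exp(-grid_t / p.tau_m)
    refract_steps = int(round(p.t_refract / p.dt))

    trains: Dict[str, list] = {}
    mean_rate: Dict[str, float] = {}
    froze: Dict[str, bool] = {}
    spectra: Dict[str, PowerSpectrum] = {}
    for c, comp in enumerate(COMPARTMENTS):
        cell_ss = epoch_ss[c].spawn(p.n_fear)
        prob = place_cell_rate(grid_t, f_rec, k, duration, p.dt) * p.dt
        comp_trains = []
        total_spikes = 0
        for i in range(p.n_fear):
            place_bins = _sample_place_bins(cell_ss[i], prob, p.n_pc_per_compartment)
            epsp = sy.epsp_trace(place_bins, 0.0, s_gain, p)
            w_rel = weights[i, c, :] / p.w0
            # soma = average over ALL 2M spines of the cell; the other
            # compartment's place cells are silent, so their spines sit at
            # rest (plus the common theta/reset terms) and dilute the drive
            drive = p.v_rest + theta_v + (w_rel @ epsp) / (2 * p.n_pc_per_compartment)
            spike_idx = _threshold_scan(drive, relax, p.v_thr, refract_steps)
            comp_trains.append(
                SpikeTrain(times=grid_t[spike_idx], duration=duration, cell_id=i)
            )
            total_spikes += spike_idx.size
        trains[comp] = comp_trains
        mean_rate[comp] = 1000.0 * total_spikes / (p.n_fear * duration)
        froze[comp] = mean_rate[comp] > p.r_freeze
        if compute_spectra:
            spectra[comp] = population_spectrum(comp_trains)
    return RecallResult(
        fear_spike_trains=trains,
        mean_rate=mean_rate,
        froze=froze,
        spectrum=spectra,
        f_theta_recall=f_rec,
        duration=duration,
    )


def freezing_probability(
    f_theta_cond: float,
    n_sims: int = 100,
    p: Optional[ParamSet] = None,
    master_seed=None,
    return_rates: bool = False,
):
    """Fraction of simulations in which each compartment elicits freezing.

    Runs ``n_sims`` independent conditioning + recall pairs (child seed
    streams of ``master_seed``) and counts, per compartment, the fraction
    whose fear-cell population mean rate exceeds ``r_freeze``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p = p or ParamSet()
    ss = _as_seedseq(master_seed if master_seed is not None else p.seed)
    frozen = {comp: 0 for comp in COMPARTMENTS}
    rates = {comp: [] for comp in COMPARTMENTS}
    for sim_ss in ss.spawn(n_sims):
        cond_ss, recall_ss = sim_ss.spawn(2)
        cond = run_conditioning(f_theta_cond, p, cond_ss)
        recall = run_recall(cond, p, recall_ss, compute_spectra=False)
        for comp in COMPARTMENTS:
            frozen[comp] += int(recall.froze[comp])
            rates[comp].append(recall.mean_rate[comp])
    fractions = {comp: frozen[comp] / n_sims for comp in COMPARTMENTS}
    if return_rates:
        return fractions, {comp: np.asarray(r) for comp, r in rates.items()}
    return fractions
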