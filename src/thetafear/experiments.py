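"""Reproducible figure-level experiments emitting data tables.

Each ``run_figure*`` function regenerates, from a :class:`ParamSet` and a
master seed, the quantities behind the published figures as pandas tables:

* figure 2 — final relative synaptic strength versus stimulation frequency
  (rate-induced plasticity protocol);
* figure 3 — relative weights per compartment and theta frequency, recall
  rate distributions, and the freezing-probability table;
* figure 4 — fear-cell spike-train power spectra per compartment before
  and after conditioning at each theta frequency.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .params import ParamSet
from .protocols import COMPARTMENTS, run_conditioning, run_recall, run_tetanus
from .spectral import PowerSpectrum, theta_peak_summary

__all__ = ["run_figure2", "run_figure3", "run_figure4", "default_frequency_grid"]


def default_frequency_grid() -> np.ndarray:
    """0.5 to 15 Hz in 0.5 Hz steps."""
    return np.arange(0.5, 15.0 + 1e-9, 0.5)


def run_figure2(
    p: Optional[ParamSet] = None,
    freqs: Optional[Sequence[float]] = None,
    n_spikes: int = 100,
    train: str = "theta",
    n_realizations: int = 16,
) -> pd.DataFrame:
    """Frequency dependence of plasticity: one tetanus run per frequency.

    Returns a table (f_stim_hz, w_rel) with the final weight relative to
    baseline; deterministic given the ParamSet seed.
    """
    p = p or ParamSet()
    freqs = default_frequency_grid() if freqs is None else np.asarray(freqs, float)
    w = [
        run_tetanus(f, n_spikes, p, train=train, n_realizations=n_realizations)
        for f in freqs
    ]
    return pd.DataFrame({"f_stim_hz": freqs, "w_rel": w})


def run_figure3(
    p: Optional[ParamSet] = None,
    n_sims: int = 100,
    master_seed=None,
    freqs: Sequence[float] = (5.5, 6.0),
) -> Dict[str, pd.DataFrame]:
    """Conditioning strength, recall rates and freezing probabilities.

    Returns three tables: ``weights`` (mean relative synaptic strength and
    SEM per frequency x compartment), ``rates`` (per-simulation population
    mean recall rates), and ``freezing`` (fraction of simulations above
    the freezing threshold).
    """
    p = p or ParamSet()
    seed = master_seed if master_seed is not None else p.seed
    weight_rows, rate_rows, freeze_rows = [], [], []
    for f_idx, f in enumerate(freqs):
        ss = np.random.SeedSequence((seed, f_idx))
        rel = {comp: [] for comp in COMPARTMENTS}
        rates = {comp: [] for comp in COMPARTMENTS}
        frozen = {comp: 0 for comp in COMPARTMENTS}
        for sim_ss in ss.spawn(n_sims):
            c_ss, r_ss = sim_ss.spawn(2)
            cond = run_conditioning(f, p, c_ss)
            rec = run_recall(cond, p, r_ss, compute_spectra=False)
            for comp in COMPARTMENTS:
                rel[comp].append(cond.mean_relative(comp))
                rates[comp].append(rec.mean_rate[comp])
                frozen[comp] += int(rec.froze[comp])
        for comp in COMPARTMENTS:
            arr = np.asarray(rel[comp])
            weight_rows.append(
                (f, comp, arr.mean(), arr.std(ddof=1) / np.sqrt(len(arr)))
            )
            for r in rates[comp]:
                rate_rows.append((f, comp, r))
            freeze_rows.append((f, comp, frozen[comp] / n_sims))
    return {
        "weights": pd.DataFrame(
            weight_rows, columns=["f_theta_hz", "compartment", "w_rel_mean", "w_rel_sem"]
        ),
        "rates": pd.DataFrame(rate_rows, columns=["f_theta_hz", "compartment", "rate_hz"]),
        "freezing": pd.DataFrame(
            freeze_rows, columns=["f_theta_hz", "compartment", "freeze_fraction"]
        ),
    }


def run_figure4(
    p: Optional[ParamSet] = None,
    n_sims: int = 20,
    master_seed=None,
    freqs: Sequence[float] = (5.5, 6.0),
) -> Dict[str, pd.DataFrame]:
    """Fear-cell output power spectra before and after conditioning.

    For each conditioning frequency and compartment, averages the
    population spectrum over ``n_sims`` seeded simulations, both with the
    learned weights ("post") and with all weights at baseline ("pre").
    Returns ``spectra`` (long table of freq_hz, power per condition) and
    ``peaks`` (theta-band peak summary).
    """
    p = p or ParamSet()
    seed = master_seed if master_seed is not None else p.seed
    mean_spectra: Dict[str, Dict[str, PowerSpectrum]] = {}
    rows = []
    baseline = np.full((p.n_fear, 2, p.n_pc_per_compartment), float(p.w0))
    for f_idx, f in enumerate(freqs):
        ss = np.random.SeedSequence((seed, 40 + f_idx))
        acc: Dict[str, Dict[str, list]] = {"pre": {}, "post": {}}
        freq_grid = None
        for sim_ss in ss.spawn(n_sims):
            c_ss, r_ss, b_ss = sim_ss.spawn(3)
            cond = run_conditioning(f, p, c_ss)
            post = run_recall(cond, p, r_ss)
            pre = run_recall(cond, p, b_ss, weights_override=baseline)
            for phase, rec in (("pre", pre), ("post", post)):
                for comp in COMPARTMENTS:
                    spec = rec.spectrum[comp]
                    acc[phase].setdefault(comp, []).append(spec.power)
                    freq_grid = spec.freqs
        for phase in ("pre", "post"):
            label = f"{f:g} Hz {phase}"
            mean_spectra[label] = {}
            for comp in COMPARTMENTS:
                power = np.mean(acc[phase][comp], axis=0)
                spec = PowerSpectrum(freqs=freq_grid, power=power)
                mean_spectra[label][comp] = spec
                for fr, pw in zip(spec.freqs, spec.power):
                    rows.append((label, comp, fr, pw))
    return {
        "spectra": pd.DataFrame(
            rows, columns=["condition", "compartment", "freq_hz", "power"]
        ),
        "peaks": theta_peak_summary(mean_spectra),
    }
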