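"""Presynaptic spike-train generation.

Place cells fire theta-modulated inhomogeneous Poisson trains whose rate is
proportional to ``1 + sin(2*pi*f_theta*t)``, normalised so that the expected
spike count over the epoch equals the gain K. Fear cells fire homogeneous
Poisson trains (rate ``r_safe`` or ``r_threat``). Both samplers use per-step
Bernoulli thinning on the shared integration grid, so spike times are exactly
representable on the Euler grid of the synapse integrator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "place_cell_rate",
    "sample_inhomogeneous_poisson",
    "sample_homogeneous_poisson",
    "spike_trains_to_csv",
    "spike_trains_from_csv",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms from epoch start) for one cell over one epoch."""

    times: np.ndarray
    duration: float
    cell_id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be a 1-d array")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate over the epoch, Hz."""
        return 1000.0 * self.times.size / self.duration

    def to_bins(self, dt: float) -> np.ndarray:
        """Spike counts per dt-bin over the epoch (length ``round(duration/dt)``)."""
        n = int(round(self.duration / dt))
        bins = np.zeros(n)
        if self.times.size:
            idx = np.minimum((self.times / dt).astype(np.int64), n - 1)
            np.add.at(bins, idx, 1.0)
        return bins


def place_cell_rate(
    t: Union[float, np.ndarray],
    f_theta: float,
    k: float,
    duration: float,
    dt: float,
) -> Union[float, np.ndarray]:
    """Theta-modulated place-cell rate, spikes/ms, at time(s) ``t``.

    rate(t) = K * (1 + sin(2*pi*f_theta*t)) / sum_steps[(1 + sin) * dt],
    with the sum taken over the epoch's dt-grid, so that the expected spike
    count ``sum rate(t_j) * dt`` over all steps equals K exactly.

    Parameters use ms for ``t``, ``duration``, ``dt`` and Hz for ``f_theta``.
    """
    if f_theta <= 0:
        raise ValueError("f_theta must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr >= duration):
        raise ValueError("t must lie in [0, duration)")
    grid = np.arange(int(round(duration / dt))) * dt
    norm = np.sum(1.0 + np.sin(2e-3 * np.pi * f_theta * grid)) * dt
    out = k * (1.0 + np.sin(2e-3 * np.pi * f_theta * t_arr)) / norm
    return float(out) if np.isscalar(t) else out


def _bernoulli_bins(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.flatnonzero(rng.random(prob.size) < prob)


def _as_rng(rng_stream) -> np.random.Generator:
    if isinstance(rng_stream, np.random.Generator):
        return rng_stream
    return np.random.default_rng(rng_stream)


def sample_inhomogeneous_poisson(
    rate_fn,
    duration: float,
    rng_stream,
    dt: float = 0.1,
    cell_id: int = 0,
) -> SpikeTrain:
    """Sample an inhomogeneous Poisson train by per-step Bernoulli thinning.

    ``rate_fn`` maps an array of times (ms) to rates in spikes/ms; each
    dt-step emits a spike with probability ``rate(t) * dt``. A warning is
    issued if that probability ever reaches 0.1 (thinning bias grows with
    rate * dt).
    """
    rng = _as_rng(rng_stream)
    grid = np.arange(int(round(duration / dt))) * dt
    prob = np.asarray(rate_fn(grid), dtype=float) * dt
    if np.any(prob >= 0.1):
        warnings.warn(
            "rate * dt reaches %.3f >= 0.1; thinning approximation is coarse"
            % float(prob.max()),
            RuntimeWarning,
            stacklevel=2,
        )
    idx = _bernoulli_bins(prob, rng)
    return SpikeTrain(times=grid[idx], duration=duration, cell_id=cell_id)


def sample_homogeneous_poisson(
    rate: float,
    duration: float,
    rng_stream,
    dt: float = 0.1,
    cell_id: int = 0,
) -> SpikeTrain:
    """Sample a homogeneous Poisson train at ``rate`` Hz over ``duration`` ms."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = _as_rng(rng_stream)
    n = int(round(duration / dt))
    if rate == 0:
        return SpikeTrain(times=np.empty(0), duration=duration, cell_id=cell_id)
    p = rate * dt / 1000.0
    idx = np.flatnonzero(rng.random(n) < p)
    return SpikeTrain(times=idx * dt, duration=duration, cell_id=cell_id)


def spike_trains_to_csv(trains: Iterable[SpikeTrain], path: Union[str, Path]) -> None:
    """Write spike trains as a two-column CSV ``(cell_id, time_ms)``."""
    frames = [
        pd.DataFrame({"cell_id": tr.cell_id, "time_ms": tr.times}) for tr in trains
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell_id", "time_ms"]
    )
    df.to_csv(path, index=False)


def spike_trains_from_csv(path: Union[str, Path], duration: float) -> list[SpikeTrain]:
    """Read spike trains from a ``(cell_id, time_ms)`` CSV written by this module."""
    df = pd.read_csv(path)
    trains = []
    for cell_id, group in df.groupby("cell_id"):
        times = np.sort(group["time_ms"].to_numpy(dtype=float))
        trains.append(SpikeTrain(times=times, duration=duration, cell_id=int(cell_id)))
    return trains
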