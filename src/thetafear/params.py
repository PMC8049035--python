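"""Model parameters and simulation controls.

All quantities use fixed units: time in ms (rates in Hz where noted),
voltage in mV, calcium in uM. ``ParamSet`` carries every symbol of the
spine/plasticity model plus the protocol and integration controls; the
defaults reproduce the published contextual-conditioning configuration.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, TextIO, Union

__all__ = ["ParamSet", "load_params", "dump_params", "ParamError"]


class ParamError(ValueError):
    """Raised when a configuration value violates a model invariant."""


@dataclass(frozen=True)
class ParamSet:
    """Full parameter vector for the fear-conditioning model.

    Membrane / spine
    ----------------
    tau_m : membrane time constant (ms); used for the post-reset relaxation
        of spines toward rest during recall.
    v_rest, v_thr, v_reset : resting, firing-threshold and reset potentials (mV).
    tau1_ep, tau2_ep : slow/fast EPSP time constants (ms).
    s_epsp : EPSP normalisation gain; ``None`` means "calibrate so the
        ACh-free kernel peaks at ``epsp_peak_mv``". The tetanus protocol
        overrides it with 1.45.
    a_theta : amplitude of the intracellular theta oscillation (mV), added
        to the spine potential in phase with the place-cell rate (switchable
        via ``theta_in_spine``).
    i_fbs, i_sbs, tau_fbs, tau_sbs : fast/slow BPAP amplitudes (sum to 1)
        and time constants (ms); the BPAP kernel peaks at 100 mV.

    Calcium / NMDA
    --------------
    tau_ca : calcium decay time constant (ms).
    p0 : NMDA channel opening probability.
    g_nmda : NMDA conductance, uM/(ms*mV); negative by convention so that
        the negative driving force below the calcium reversal potential
        yields calcium influx.
    i_f, i_s, tau_f, tau_s : fast/slow NMDA current fractions (sum to 1)
        and time constants (ms).
    e_ca : calcium reversal potential (mV).
    mg : extracellular magnesium concentration (mM); not fixed by the
        published parameter table — the default was set once by the
        documented calibration of the freezing probabilities (see the
        methods note) and governs how strongly depolarisation gates
        calcium influx.

    Plasticity
    ----------
    lam : synaptic strength decay constant (1.0 in the tetanus protocol).
    alpha1, alpha2, beta1, beta2 : thresholds and slopes of the Omega
        function (sign and magnitude of calcium-controlled change).
    p1, p2, p3, p4 : learning-rate (eta) parameters; eta is in 1/s.
    lam_scales_w : if True (default) the passive decay term is
        lambda * W (weight-proportional, the source plasticity model's
        form); if False the printed constant-decay reading is used.
    w0 : initial synaptic weight; results are reported as W/w0.

    Protocols
    ---------
    k_gain : expected place-cell spike count per epoch; ``None`` means one
        spike per theta cycle (i.e. the number of cycles in the epoch).
    r_safe, r_threat : fear-cell Poisson rates (Hz) in the two compartments.
    f_theta_cond, f_theta_recall : theta frequency (Hz) during conditioning
        and recall.
    n_cycles_cond, n_cycles_recall : epoch lengths in theta periods.
    ach : acetylcholine level in [0, 1]; 1 during conditioning (plasticity
        on, EPSPs suppressed), 0 during recall.
    r_freeze : population mean-rate threshold (Hz) above which the simulated
        animal freezes.
    t_refract : absolute refractory period after a fear-cell output spike (ms).
    n_fear, n_pc_per_compartment : population sizes.

    Controls
    --------
    dt : forward-Euler step (ms). seed : master random seed.
    """

    # membrane / spine
    tau_m: float = 20.0
    v_rest: float = -65.0
    v_thr: float = -55.0
    v_reset: float = -75.0
    tau1_ep: float = 50.0
    tau2_ep: float = 5.0
    s_epsp: float | None = None
    epsp_peak_mv: float = 8.0
    a_theta: float = 3.0
    theta_in_spine: bool = True
    i_fbs: float = 0.75
    i_sbs: float = 0.25
    tau_fbs: float = 3.0
    tau_sbs: float = 25.0
    # calcium / NMDA
    tau_ca: float = 50.0
    p0: float = 0.5
    g_nmda: float = -1.0 / 500.0
    i_f: float = 0.5
    i_s: float = 0.5
    tau_f: float = 50.0
    tau_s: float = 200.0
    e_ca: float = 130.0
    mg: float = 1.965
    # plasticity
    lam: float = 0.1
    alpha1: float = 0.35
    alpha2: float = 0.55
    beta1: float = 80.0
    beta2: float = 80.0
    p1: float = 0.1
    p2: float = 1e-5
    p3: float = 3.0
    p4: float = 1.0
    lam_scales_w: bool = True
    w0: float = 0.5
    # protocols
    k_gain: float | None = None
    r_safe: float = 0.85
    r_threat: float = 1.85
    f_theta_cond: float = 6.0
    f_theta_recall: float = 5.0
    n_cycles_cond: int = 100
    n_cycles_recall: int = 25
    ach: float = 1.0
    r_freeze: float = 1.5
    t_refract: float = 2.0
    n_fear: int = 32
    n_pc_per_compartment: int = 9
    # controls
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every model invariant; raise :class:`ParamError` naming the field."""
        positive = (
            "tau_m", "tau1_ep", "tau2_ep", "tau_fbs", "tau_sbs", "tau_ca",
            "tau_f", "tau_s", "dt", "epsp_peak_mv", "f_theta_cond",
            "f_theta_recall", "r_freeze",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParamError(f"{name} must be > 0 (got {getattr(self, name)!r})")
        pairs = (("tau1_ep", "tau2_ep"), ("tau_s", "tau_f"), ("tau_sbs", "tau_fbs"))
        for slow, fast in pairs:
            if not getattr(self, slow) > getattr(self, fast):
                raise ParamError(
                    f"{slow} must exceed {fast} "
                    f"({getattr(self, slow)!r} <= {getattr(self, fast)!r})"
                )
        if not (self.v_reset < self.v_rest < self.v_thr):
            raise ParamError(
                "require v_reset < v_rest < v_thr "
                f"(got {self.v_reset}, {self.v_rest}, {self.v_thr})"
            )
        if not 0.0 <= self.ach <= 1.0:
            raise ParamError(f"ach must lie in [0, 1] (got {self.ach!r})")
        if not 0.0 <= self.p0 <= 1.0:
            raise ParamError(f"p0 must lie in [0, 1] (got {self.p0!r})")
        if not math.isclose(self.i_f + self.i_s, 1.0, abs_tol=1e-12):
            raise ParamError(f"i_f + i_s must equal 1 (got {self.i_f + self.i_s!r})")
        if not math.isclose(self.i_fbs + self.i_sbs, 1.0, abs_tol=1e-12):
            raise ParamError(
                f"i_fbs + i_sbs must equal 1 (got {self.i_fbs + self.i_sbs!r})"
            )
        if not self.r_threat > self.r_safe:
            raise ParamError(
                f"r_threat must exceed r_safe ({self.r_threat!r} <= {self.r_safe!r})"
            )
        if self.r_safe < 0:
            raise ParamError(f"r_safe must be >= 0 (got {self.r_safe!r})")
        for name in ("n_fear", "n_pc_per_compartment", "n_cycles_cond", "n_cycles_recall"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ParamError(f"{name} must be a positive integer (got {v!r})")
        if self.w0 < 0:
            raise ParamError(f"w0 must be >= 0 (got {self.w0!r})")
        if self.lam < 0:
            raise ParamError(f"lam must be >= 0 (got {self.lam!r})")
        if self.t_refract < 0:
            raise ParamError(f"t_refract must be >= 0 (got {self.t_refract!r})")
        if self.s_epsp is not None and self.s_epsp <= 0:
            raise ParamError(f"s_epsp must be > 0 or None (got {self.s_epsp!r})")
        if self.k_gain is not None and self.k_gain <= 0:
            raise ParamError(f"k_gain must be > 0 or None (got {self.k_gain!r})")

    def replace(self, **changes: Any) -> "ParamSet":
        """Return a copy with ``changes`` applied (re-validated)."""
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def k_for_cycles(self, n_cycles: int) -> float:
        """Expected place-cell spikes for an epoch of ``n_cycles`` theta periods.

        The gain K is "one spike per oscillatory cycle" unless an explicit
        ``k_gain`` override (e.g. the literal 900) is configured.
        """
        return float(self.k_gain) if self.k_gain is not None else float(n_cycles)


_FIELDS = {f.name: f for f in dataclasses.fields(ParamSet)}
_BOOL_FIELDS = {"theta_in_spine", "lam_scales_w"}
_INT_FIELDS = {"n_fear", "n_pc_per_compartment", "n_cycles_cond", "n_cycles_recall", "seed"}
_OPTIONAL_FIELDS = {"s_epsp", "k_gain"}


def _coerce(name: str, raw: Any) -> Any:
    if isinstance(raw, str):
        text = raw.strip()
        if name in _OPTIONAL_FIELDS and text.lower() in ("none", "null", ""):
            return None
        if name in _BOOL_FIELDS:
            if text.lower() in ("true", "yes", "1", "on"):
                return True
            if text.lower() in ("false", "no", "0", "off"):
                return False
            raise ParamError(f"{name}: cannot parse boolean from {raw!r}")
        try:
            return int(text) if name in _INT_FIELDS else float(text)
        except ValueError as exc:
            raise ParamError(f"{name}: cannot parse number from {raw!r}") from exc
    if raw is None and name in _OPTIONAL_FIELDS:
        return None
    if name in _BOOL_FIELDS:
        return bool(raw)
    if name in _INT_FIELDS:
        if isinstance(raw, float) and not raw.is_integer():
            raise ParamError(f"{name}: expected integer, got {raw!r}")
        return int(raw)
    return float(raw)


def load_params(source: Union[str, Path, TextIO, Mapping[str, Any], None] = None) -> ParamSet:
    """Build a :class:`ParamSet` from a plain-text ``key: value`` config.

    ``source`` may be a mapping, a path to a config file, an open text
    stream, the config text itself, or ``None`` (pure defaults). Lines that
    are blank or start with ``#`` are ignored. Missing keys take the
    defaults; unknown keys and invalid values raise :class:`ParamError`.
    """
    if source is None:
        return ParamSet()
    if isinstance(source, Mapping):
        items = dict(source)
    else:
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str):
            p = Path(source)
            # a path-like string without newlines is treated as a file path
            text = p.read_text() if ("\n" not in source and p.is_file()) else source
        else:
            text = source.read()
        items = {}
        for lineno, line in enumerate(io.StringIO(text), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if ":" not in stripped:
                raise ParamError(f"line {lineno}: expected 'key: value', got {line!r}")
            key, _, value = stripped.partition(":")
            items[key.strip()] = value.strip()
    unknown = set(items) - set(_FIELDS)
    if unknown:
        raise ParamError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
    coerced = {name: _coerce(name, raw) for name, raw in items.items()}
    return ParamSet(**coerced)


def dump_params(p: ParamSet) -> str:
    """Serialize ``p`` as ``key: value`` text; round-trips through :func:`load_params`."""
    lines = []
    for f in dataclasses.fields(ParamSet):
        value = getattr(p, f.name)
        if value is None:
            rendered = "none"
        elif isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, float):
            rendered = repr(value)
        else:
            rendered = str(value)
        lines.append(f"{f.name}: {rendered}")
    return "\n".join(lines) + "\n"
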