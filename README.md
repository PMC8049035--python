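# thetafear

A biophysical simulation of how the frequency of the hippocampal theta
rhythm during contextual fear conditioning controls learned fear — and
why the small (~0.5 Hz) theta slowing common to all anxiolytic drugs is
enough to blunt conditioned freezing.

The package is for computational neuroscientists who want to run,
perturb, or extend the model: theta-modulated hippocampal place cells
drive NMDA-receptor-dependent calcium influx at dendritic spines of
amygdalar "fear cells", and synaptic strength follows the
calcium-control rule

    dV_s/dt :  V_s(t) = V_r + EPSP(t) + BPAP(t) + A_θ sin(2π f_θ t)
    d[Ca]/dt = I_NMDA(t) − [Ca]/τ_Ca
    dW/dt    = η([Ca]) · ( Ω([Ca]) · [ACh] − λ·W )

where Ω sets the sign of plasticity by calcium level (depression between
0.35 and 0.55 µM, potentiation above), η is a calcium-dependent learning
rate, and acetylcholine switches the circuit between an encoding mode
(ACh = 1: plasticity on, EPSPs suppressed) and a recall mode (ACh = 0:
EPSPs on, plasticity frozen). During recall, each fear cell fires when
the average potential of its dendritic spines crosses threshold, and the
simulated animal "freezes" when the population mean rate exceeds
1.5 Hz. Conditioning with theta at 6.0 Hz versus 5.5 Hz is the entire
difference between the drug-free and anxiolytic conditions.

See `docs/methods.md` for the full model description, the calibration of
the parameters the source material leaves unstated, and known limits.

## Worked example

```python
import numpy as np
from thetafear import ParamSet, run_conditioning, run_recall

p = ParamSet()                                # calibrated defaults
ss = np.random.SeedSequence(7)
c_ss, r_ss = ss.spawn(2)

cond = run_conditioning(6.0, p, c_ss)         # 100 theta cycles/compartment
print("mean W/w0 safe  :", round(cond.mean_relative("safe"), 2))
print("mean W/w0 threat:", round(cond.mean_relative("threat"), 2))

rec = run_recall(cond, p, r_ss)               # ACh = 0, theta at 5 Hz
print("recall rates    :", {k: round(v, 2) for k, v in rec.mean_rate.items()})
print("froze           :", rec.froze)
```

prints

```
mean W/w0 safe  : 2.34
mean W/w0 threat: 2.89
recall rates    : {'safe': 0.66, 'threat': 1.79}
froze           : {'safe': False, 'threat': True}
```

Conditioning potentiated the threat-compartment synapses more than the
safe-compartment ones (W/w0 2.89 vs 2.34, relative to the initial
weight), so during recall the fear-cell population fires above the
1.5 Hz freezing threshold only in the threatening compartment. Repeating
this with `run_conditioning(5.5, ...)` leaves the threat compartment
below threshold in most simulations — the anxiolytic effect.

The same experiments are available from the shell:

```
thetafear freeze --f-theta 6.0 --n-sims 100 --seed 1 --out-dir out/
thetafear figure2                      # plasticity vs drive frequency
thetafear figure3 --n-sims 100         # weights, rates, freezing table
thetafear figure4 --n-sims 20          # output spectra pre/post conditioning
```

Every run writes CSV/JSON tables plus a manifest with the resolved
parameters and seeds sufficient to re-execute it bit-identically.

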