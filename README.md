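# aecclamp

Single-electrode **dynamic clamp** with **active electrode compensation
(AEC)** — plus a fully simulated "virtual rig" so that every stage of the
workflow can be developed, validated and reproduced without hardware.

## The problem

In a dynamic clamp experiment a neuron's membrane potential is measured,
a model current (for instance through a simulated gap junction) is
computed, and that current is injected back into the same cell — every
cycle, at kilohertz rates. When a single microelectrode both records and
injects, the electrode's resistance and capacitance superimpose a large
voltage artifact on the recording:

```
V_raw(t) = V_m(t) + V_e(t),        V_e(t) = (K_e * I)(t)
```

where `K_e` is the electrode's impulse-response *kernel* (its integral is
the electrode resistance `R_e`, its decay constant the electrode time
constant `τ_e`). The artifact can exceed the biological signal by an
order of magnitude, and in the closed loop any compensation error is fed
back and amplified. Analog bridge balance subtracts only `R·I` and lags,
which at strong coupling produces damped oscillations and ultimately
destroys the experiment.

AEC instead calibrates a digital model of the electrode and subtracts the
artifact in software, every cycle:

1. **Calibration** — inject a known white-noise current (10 kHz, ±0.5 nA,
   ~5 s) and estimate the *full kernel* `K` of electrode + passive
   membrane by least squares (Toeplitz normal equations built from the
   probe autocorrelation).
2. **Separation** — model the measurement as
   `K = K_e + (K_m * K_e)/ΣK_e`, fit the slow exponential tail to get the
   membrane kernel `K_m` (`R_m`, `τ_m`), then solve for `K_e` by damped
   fixed-point iteration. Valid when `τ_m/τ_e > 10`.
3. **Compensation** — in a soft-real-time loop the cycle periods vary, so
   each cycle the fixed-bin "base kernel" is resampled onto the observed
   sampling intervals (bins inside an interval are summed, straddling
   bins split proportionally to overlap — implemented exactly via the
   kernel's cumulative mass), and `V_e = K_e^tr * I` is subtracted.

The package also implements the semi-automated vetting protocol that
precedes calibration: electrode linearity (`σ_R/μ_R < 15%` across DC
levels), electrode speed (`τ_e ≤ 0.5–1 ms`), time-scale ratio
(`τ_m/τ_e > 10`), stationarity repeats, and spike-count quality control.

The **virtual rig** simulates the standard validation hardware: a passive
three-RC "model cell" (fast electrode RC in series with a slow membrane
RC, exact exponential integration), a second artifact-free control
electrode, a presynaptic spike generator, gap-junction coupling with a
±10 nA DAQ limit, timestep jitter, recording noise, electrode
polarization, and amplifier bridge-balance / capacitance-neutralization
emulation.

## Worked example

Calibrate the default model cell (electrode 50 MΩ / 0.35 ms, membrane
50 MΩ / 23 ms) with the default probe and the standard 50 ms / 3 ms
kernel lengths:

```sh
$ aecclamp calibrate --seed 1 --full-kernel-ms 50 --electrode-kernel-ms 3 \
      --report report.json --kernel ke.tsv
R_e = 50.587 MOhm, tau_e = 0.3498 ms, R_m = 48.929 MOhm, tau_m = 22.527 ms
applicability [linearity]: pass
applicability [speed]: pass
applicability [tau ratio]: pass
```

All four circuit parameters are recovered within ~2% of the simulated
ground truth, and the three applicability criteria pass (CV of the
steady-state resistance below 15%, `τ_e` under 1 ms, `τ_m/τ_e ≈ 64`).

The same calibration drives the closed loop. Coupling the model cell to
the spike generator through a 500 nS gap junction (spikes every 100 ms,
20% timestep jitter) and comparing the compensated voltage against the
artifact-free control electrode:

```
AEC    RMS error: 1.046 mV   (peak artifact 497 mV)
bridge RMS error: 114.930 mV
```

The artifact is an order of magnitude larger than the membrane response
and is removed to ~0.2% by AEC, while the lagged bridge balance feeds its
error back into the loop and develops large oscillations — the failure
mode that motivates digital compensation.

Library use mirrors the CLI:

```python
from aecclamp import (NoiseProtocol, RigConfig, VirtualRig,
                      run_aec_calibration, Compensator, run_closed_loop,
                      SpikeGenParams)

rig = VirtualRig(RigConfig(rng_seed=1))
report = run_aec_calibration(rig, protocol=NoiseProtocol(rng_seed=1),
                             full_kernel_ms=50.0, electrode_kernel_ms=3.0)
comp = Compensator(report.separation.electrode_kernel)
record = run_closed_loop(RigConfig(rng_seed=1),
                         SpikeGenParams(spike_times=(50.0,)), g=500.0,
                         compensator=comp, duration=200.0)
```

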