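"""Virtual electrophysiology rig.

Simulates the hardware side of a single-electrode dynamic clamp experiment
end to end: a passive "model cell" consisting of a fast parallel-RC
electrode in series with a slower parallel-RC membrane, a presynaptic
spike generator, an amplifier-style bridge-balance (and capacitance
neutralization) emulation, and a soft-real-time closed loop in which the
computed gap-junction current is injected with one cycle of latency and
variable timesteps.

The recorded voltage is always the sum of the membrane potential and the
voltage drop across the electrode, ``V_raw = V_m + V_e`` (plus optional
recording noise).  A second, passive electrode carries no current and
therefore reports the membrane potential without any artifact; it serves
as the ground-truth control channel in validation runs.

Units follow one project-wide convention: mV, nA, MΩ, ms, nF, nS, so
that mV = nA·MΩ, ms = MΩ·nF and nA = nS·mV / 1000.

All randomness (recording noise, timestep jitter) derives from the single
``rng_seed`` of the :class:`RigConfig` through fixed sub-streams, so runs
are bit-reproducible and toggling one noise source does not shift the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .errors import InvalidArgumentError, StateError

__all__ = [
    "RCParams",
    "CellCircuitState",
    "RigConfig",
    "SpikeGenParams",
    "BridgeSettings",
    "SimulationRecord",
    "VirtualRig",
    "step_circuit",
    "spike_generator_voltage",
    "gap_junction_current",
    "bridge_balance_display",
    "sample_timestep",
    "run_closed_loop",
]

# Fixed spawn keys for the per-purpose random sub-streams derived from the
# single rig seed (see RigConfig.rng_seed).
_STREAM_NOISE = 1
_STREAM_JITTER = 2


@dataclass(frozen=True)
class RCParams:
    """A parallel resistor-capacitor element.

    Parameters
    ----------
    resistance : float
        DC resistance in MΩ; must be positive.
    time_constant : float
        RC time constant in ms.  Zero means a pure resistor
        (instantaneous equilibration).
    """

    resistance: float  # MΩ
    time_constant: float = 0.0  # ms

    def __post_init__(self) -> None:
        if not self.resistance > 0:
            raise InvalidArgumentError(f"resistance must be > 0, got {self.resistance}")
        if self.time_constant < 0:
            raise InvalidArgumentError(
                f"time_constant must be >= 0, got {self.time_constant}"
            )

    @property
    def capacitance(self) -> float:
        """Capacitance in nF (= time_constant / resistance)."""
        return self.time_constant / self.resistance


@dataclass(frozen=True)
class CellCircuitState:
    """Instantaneous state of the simulated electrode + membrane circuit."""

    v_electrode: float  # mV, drop across the series electrode element
    v_membrane: float  # mV, membrane potential relative to ground
    t: float = 0.0  # ms

    @property
    def v_raw(self) -> float:
        """The single-electrode recording: membrane plus electrode drop."""
        return self.v_membrane + self.v_electrode


@dataclass(frozen=True)
class SpikeGenParams:
    """Presynaptic spike-generator waveform parameters.

    The generator idles at ``resting_potential`` and emits a smooth
    raised-cosine bump of total duration ``spike_width`` centred on each
    entry of ``spike_times``, peaking at ``resting_potential +
    spike_height``.
    """

    resting_potential: float = -60.0  # mV
    spike_height: float = 80.0  # mV
    spike_width: float = 3.0  # ms
    spike_times: tuple = ()  # ms, strictly increasing

    def __post_init__(self) -> None:
        if not self.spike_width > 0:
            raise InvalidArgumentError("spike_width must be > 0")
        times = tuple(float(x) for x in self.spike_times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("spike_times must be strictly increasing")
        object.__setattr__(self, "spike_times", times)


@dataclass(frozen=True)
class RigConfig:
    """Full description of the simulated rig.

    ``polarization_ratio`` multiplies the electrode resistance whenever the
    injected current is negative (1 = linear/Ohmic electrode); a strongly
    polarized electrode violates the linearity assumption of active
    electrode compensation and should be flagged by the calibration
    checks.  ``cap_neutralization`` is the amplifier's capacitance
    neutralization setting in nF: it reduces the effective electrode
    capacitance to ``C_e - cap_neutralization``, speeding up the
    electrode; settings at or beyond ``C_e`` are rejected as unstable.
    ``membrane=None`` models the electrode alone in the bath solution.
    """

    electrode: RCParams = RCParams(50.0, 0.35)
    membrane: RCParams | None = RCParams(50.0, 23.0)
    resting_potential: float = -60.0  # mV
    control_electrode: RCParams = RCParams(50.0, 0.35)
    recording_noise_sd: float = 0.05  # mV
    polarization_ratio: float = 1.0
    cap_neutralization: float = 0.0  # nF
    daq_current_limit: float = 10.0  # nA
    timestep_base: float = 0.1  # ms
    timestep_jitter_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.daq_current_limit > 0:
            raise InvalidArgumentError("daq_current_limit must be > 0")
        if not self.timestep_base > 0:
            raise InvalidArgumentError("timestep_base must be > 0")
        if self.polarization_ratio < 0:
            raise InvalidArgumentError("polarization_ratio must be >= 0")
        if not 0 <= self.timestep_jitter_fraction < 1:
            raise InvalidArgumentError("timestep_jitter_fraction must be in [0, 1)")
        if self.cap_neutralization < 0:
            raise InvalidArgumentError("cap_neutralization must be >= 0")
        if (
            self.cap_neutralization > 0
            and self.cap_neutralization >= self.electrode.capacitance
        ):
            raise InvalidArgumentError(
                "cap_neutralization >= electrode capacitance is unstable"
            )

    def effective_electrode(self, I: float) -> tuple[float, float]:
        """Effective (R_e, tau_e) seen by a current ``I``.

        Applies sign-dependent polarization to the resistance and
        capacitance neutralization to the time constant.  The physical
        capacitance is unchanged by polarization, so the time constant
        scales with the resistance.
        """
        R = self.electrode.resistance
        tau = self.electrode.time_constant
        if I < 0 and self.polarization_ratio != 1.0:
            R *= self.polarization_ratio
            tau *= self.polarization_ratio
        if self.cap_neutralization > 0 and tau > 0:
            tau = R * (self.electrode.capacitance - self.cap_neutralization)
        return R, tau


@dataclass(frozen=True)
class BridgeSettings:
    """Amplifier bridge-balance emulation: subtract ``R_bridge * I`` after
    passing the current through a first-order low-pass of time constant
    ``lag`` (the delay a real bridge circuit introduces)."""

    R_bridge: float  # MΩ
    lag: float = 0.2  # ms

    def __post_init__(self) -> None:
        if self.R_bridge < 0:
            raise InvalidArgumentError("R_bridge must be >= 0")
        if self.lag < 0:
            raise InvalidArgumentError("lag must be >= 0")


def _exp_relax(v: float, target: float, dt: float, tau: float) -> float:
    """Exact exponential relaxation of ``v`` toward ``target`` over ``dt``."""
    if tau <= 0.0:
        return target
    return target + (v - target) * math.exp(-dt / tau)


def step_circuit(
    state: CellCircuitState, I: float, dt: float, rig: RigConfig
) -> CellCircuitState:
    """Advance the model cell by one interval of constant injected current.

    Both circuit elements are driven by the same injected current, so the
    two first-order ODEs

        dV_e/dt = I/C_e - V_e/(R_e C_e)
        dV_m/dt = (E_rest - V_m)/(R_m C_m) + I/C_m

    decouple and admit the exact update for piecewise-constant input:
    each state relaxes exponentially toward its DC target (``I R_e`` for
    the electrode, ``E_rest + I R_m`` for the membrane).  There is no
    integration error regardless of how an interval is subdivided.
    """
    if not dt > 0:
        raise InvalidArgumentError(f"dt must be > 0, got {dt}")
    Re, tau_e = rig.effective_electrode(I)
    ve = _exp_relax(state.v_electrode, I * Re, dt, tau_e)
    if rig.membrane is None:
        vm = rig.resting_potential
    else:
        target = rig.resting_potential + I * rig.membrane.resistance
        vm = _exp_relax(state.v_membrane, target, dt, rig.membrane.time_constant)
    return CellCircuitState(v_electrode=ve, v_membrane=vm, t=state.t + dt)


def spike_generator_voltage(params: SpikeGenParams, t) -> float | np.ndarray:
    """Presynaptic voltage at time(s) ``t`` (ms).

    Raised-cosine bump: within ``spike_width/2`` of a spike time the
    output is ``rest + height * (1 + cos(2π (t - t_s)/width)) / 2``; the
    waveform is continuous (and zero-valued in its deviation) at the
    window edges and peaks exactly at each spike time.
    """
    t_arr = np.asarray(t, dtype=float)
    v = np.full(t_arr.shape, params.resting_potential)
    half = params.spike_width / 2.0
    for ts in params.spike_times:
        d = t_arr - ts
        mask = np.abs(d) < half
        if np.any(mask):
            bump = 0.5 * (1.0 + np.cos(2.0 * np.pi * d[mask] / params.spike_width))
            v[mask] += params.spike_height * bump
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(v)
    return v


def gap_junction_current(g: float, V_pre: float, V_post: float, limit: float) -> float:
    """Ohmic (gap-junction) coupling current in nA, clipped to the DAQ range.

    nS × mV gives pA, hence the division by 1000; the result is clipped
    to ``[-limit, +limit]`` to emulate the D/A converter's output range.
    """
    if g < 0:
        raise InvalidArgumentError(f"gap junction conductance must be >= 0, got {g}")
    I = g * (V_pre - V_post) / 1000.0
    return float(np.clip(I, -limit, limit))


def _lagged_current(I: np.ndarray, t: np.ndarray, lag: float) -> np.ndarray:
    """First-order low-pass of a piecewise-constant current, variable dt."""
    if lag == 0.0:
        return np.asarray(I, dtype=float).copy()
    out = np.empty(len(I))
    acc = 0.0  # system at rest (zero current) before the record
    prev_t = t[0] - (t[1] - t[0]) if len(t) > 1 else t[0] - 1.0
    for n in range(len(I)):
        dtn = t[n] - prev_t
        acc += (1.0 - math.exp(-dtn / lag)) * (I[n] - acc)
        out[n] = acc
        prev_t = t[n]
    return out


def bridge_balance_display(V_raw, I, t, R_bridge: float, lag: float) -> np.ndarray:
    """Voltage the amplifier would display under bridge-balance compensation.

    Subtracts ``R_bridge`` times a low-pass-filtered copy of the injected
    current from the raw recording.  ``lag = 0`` is an ideal
    (instantaneous) bridge; a positive lag reproduces the delayed,
    imperfect compensation of a real bridge circuit, which leaves a
    transient residual artifact decaying with time constant ``lag`` after
    every current step.
    """
    V_raw = np.asarray(V_raw, dtype=float)
    I = np.asarray(I, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (len(V_raw) == len(I) == len(t)):
        raise InvalidArgumentError("V_raw, I and t must have equal lengths")
    if R_bridge < 0:
        raise InvalidArgumentError("R_bridge must be >= 0")
    if lag < 0:
        raise InvalidArgumentError("lag must be >= 0")
    if R_bridge == 0.0:
        return V_raw.copy()
    return V_raw - R_bridge * _lagged_current(I, t, lag)


def sample_timestep(base: float, jitter_fraction: float, rng: np.random.Generator) -> float:
    """Draw one soft-real-time cycle duration: ``base * (1 + u)`` with
    ``u ~ Uniform[-jitter_fraction, +jitter_fraction]``."""
    if not base > 0:
        raise InvalidArgumentError("base timestep must be > 0")
    if not 0 <= jitter_fraction < 1:
        raise InvalidArgumentError("jitter_fraction must be in [0, 1)")
    if jitter_fraction == 0.0:
        return float(base)
    u = rng.uniform(-jitter_fraction, jitter_fraction)
    return float(base * (1.0 + u))


@dataclass
class SimulationRecord:
    """Per-cycle record of a closed-loop (or open-loop) run.

    ``V_control`` is the membrane potential reported by the passive second
    electrode: it carries no current, hence has zero artifact and equals
    the circuit's true membrane potential exactly.
    """

    t: np.ndarray  # ms
    dt: np.ndarray  # ms
    I_injected: np.ndarray  # nA, current that flowed during the row's interval
    V_raw: np.ndarray  # mV
    V_control: np.ndarray  # mV
    V_comp: np.ndarray  # mV, compensated estimate fed to the controller
    Ve_true: np.ndarray  # mV
    Ve_est: np.ndarray  # mV

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_ms": self.t,
                "dt_ms": self.dt,
                "I_nA": self.I_injected,
                "V_raw_mV": self.V_raw,
                "V_control_mV": self.V_control,
                "V_comp_mV": self.V_comp,
                "Ve_true_mV": self.Ve_true,
                "Ve_est_mV": self.Ve_est,
            }
        )


def _rng_stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


class VirtualRig:
    """Stateful wrapper around the circuit model plus its noise streams.

    A fresh ``VirtualRig`` built from the same :class:`RigConfig` always
    produces bit-identical recordings.
    """

    def __init__(self, config: RigConfig):
        self.config = config
        self.reset()

    def reset(self) -> None:
        """Return the circuit to rest and rewind the random streams."""
        rest = (
            self.config.resting_potential if self.config.membrane is not None else self.config.resting_potential
        )
        self.state = CellCircuitState(v_electrode=0.0, v_membrane=rest, t=0.0)
        self._noise_rng = _rng_stream(self.config.rng_seed, _STREAM_NOISE)
        self._jitter_rng = _rng_stream(self.config.rng_seed, _STREAM_JITTER)

    # -- open-loop recording ------------------------------------------------

    def _can_vectorize(self, I: np.ndarray) -> bool:
        cfg = self.config
        return cfg.polarization_ratio == 1.0 or not np.any(I < 0)

    def record(self, I, dt: float):
        """Inject a piecewise-constant current train at uniform ``dt`` and
        record the response.

        Sample ``n`` of the returned arrays is taken at the end of the
        interval during which ``I[n]`` flowed (calibration and electrode
        tests run in tightly controlled, constant-timestep mode).

        Returns
        -------
        dict with arrays ``t``, ``I``, ``V_raw`` (with recording noise),
        ``V_m`` (true membrane potential = control channel), ``Ve_true``.
        """
        I = np.asarray(I, dtype=float)
        if not dt > 0:
            raise InvalidArgumentError("dt must be > 0")
        n = len(I)
        t = self.state.t + dt * np.arange(1, n + 1)
        cfg = self.config
        if self._can_vectorize(I):
            ve = self._filter_element(
                I,
                dt,
                cfg.effective_electrode(0.0),
                x0=self.state.v_electrode,
                offset=0.0,
            )
            if cfg.membrane is None:
                vm = np.full(n, cfg.resting_potential)
            else:
                vm = self._filter_element(
                    I,
                    dt,
                    (cfg.membrane.resistance, cfg.membrane.time_constant),
                    x0=self.state.v_membrane - cfg.resting_potential,
                    offset=cfg.resting_potential,
                )
        else:
            ve = np.empty(n)
            vm = np.empty(n)
            st = self.state
            for k in range(n):
                st = step_circuit(st, I[k], dt, cfg)
                ve[k] = st.v_electrode
                vm[k] = st.v_membrane
        self.state = CellCircuitState(v_electrode=ve[-1], v_membrane=vm[-1], t=t[-1])
        v_raw = ve + vm
        if cfg.recording_noise_sd > 0:
            v_raw = v_raw + self._noise_rng.normal(0.0, cfg.recording_noise_sd, n)
        return {"t": t, "I": I, "V_raw": v_raw, "V_m": vm, "Ve_true": ve}

    @staticmethod
    def _filter_element(I, dt, r_tau, x0, offset):
        """Exact-update recursion x_n = a x_{n-1} + (1-a) R I_n via lfilter."""
        R, tau = r_tau
        if tau <= 0.0:
            return offset + R * I
        a = math.exp(-dt / tau)
        b = [(1.0 - a) * R]
        den = [1.0, -a]
        zi = np.array([a * x0])
        y, _ = lfilter(b, den, I, zi=zi)
        return offset + y

    def settle(self, duration: float, I: float = 0.0) -> None:
        """Hold a constant current for ``duration`` without recording."""
        self.state = step_circuit(self.state, I, duration, self.config) if duration > 0 else self.state


def run_closed_loop(
    rig: RigConfig,
    spikegen: SpikeGenParams,
    g: float,
    compensator=None,
    duration: float = 500.0,
) -> SimulationRecord:
    """Run the dynamic clamp feedback loop on the virtual rig.

    Per cycle: a jittered timestep is drawn; the current computed in the
    previous cycle is injected (one-cycle feedback latency, as on a real
    DAQ loop); the raw voltage is read with recording noise; the selected
    compensation mode produces the membrane-potential estimate ``V_comp``;
    the gap-junction current toward the spike generator is computed from
    it and held for the next cycle.

    ``compensator`` selects the compensation mode: ``None`` (no
    compensation, the raw voltage is used), a :class:`BridgeSettings`
    (amplifier bridge balance with lag), or a calibrated
    :class:`aecclamp.compensation.Compensator` (active electrode
    compensation).  Identical config + seed gives bit-identical records.
    """
    from .compensation import Compensator  # deferred: avoid import cycle

    if isinstance(compensator, Compensator) and compensator.base_kernel is None:
        raise StateError("AEC compensator has no calibrated base kernel")
    vr = VirtualRig(rig)
    cols ={k: [] for k in ("t", "dt", "I", "V_raw", "V_c", "V_comp", "Ve", "Ve_est")}
    I_prev = 0.0
    t = 0.0
    bridge_acc = 0.0
    while t < duration:
        dtn = sample_timestep(
            rig.timestep_base, rig.timestep_jitter_fraction, vr._jitter_rng
        )
        vr.state = step_circuit(vr.state, I_prev, dtn, rig)
        t = vr.state.t
        v_raw = vr.state.v_raw
        if rig.recording_noise_sd > 0:
            v_raw += vr._noise_rng.normal(0.0, rig.recording_noise_sd)
        if compensator is None:
            v_est = v_raw
            ve_est = 0.0
        elif isinstance(compensator, BridgeSettings):
            if compensator.lag > 0:
                bridge_acc += (1.0 - math.exp(-dtn / compensator.lag)) * (
                    I_prev - bridge_acc
                )
            else:
                bridge_acc = I_prev
            ve_est = compensator.R_bridge * bridge_acc
            v_est = v_raw - ve_est
        else:  # AEC
            v_est = compensator.compensate(v_raw, I_prev, t)
            ve_est = v_raw - v_est
        v_pre = spike_generator_voltage(spikegen, t)
        I_next = gap_junction_current(g, v_pre, v_est, rig.daq_current_limit)
        cols["t"].append(t)
        cols["dt"].append(dtn)
        cols["I"].append(I_prev)
        cols["V_raw"].append(v_raw)
        cols["V_c"].append(vr.state.v_membrane)
        cols["V_comp"].append(v_est)
        cols["Ve"].append(vr.state.v_electrode)
        cols["Ve_est"].append(ve_est)
        I_prev = I_next
    return SimulationRecord(
        t=np.array(cols["t"]),
        dt=np.array(cols["dt"]),
        I_injected=np.array(cols["I"]),
        V_raw=np.array(cols["V_raw"]),
        V_control=np.array(cols["V_c"]),
        V_comp=np.array(cols["V_comp"]),
        Ve_true=np.array(cols["Ve"]),
        Ve_est=np.array(cols["Ve_est"]),
    )
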