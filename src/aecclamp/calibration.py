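"""Semi-automated electrode and membrane measurement, vetting, and AEC
calibration orchestration.

Workflow mirrors a real single-electrode dynamic clamp session: the
electrode is first characterized in the bath (steady-state resistance at
several DC levels, linearity, speed), re-checked after impalement, the
passive membrane is measured with hyperpolarizing steps, the three
applicability criteria are evaluated, and finally the noise-probe
calibration estimates and separates the kernels and cross-checks the
derived scalars against the step measurements.

Applicability criteria (all pure functions of the measured statistics):

- linearity: coefficient of variation of the steady-state resistance
  across DC levels below 15%;
- speed: electrode time constant at or below a threshold (default 1 ms,
  stricter 0.5 ms selectable);
- time-scale ratio: tau_m / tau_e above 10, the prerequisite for a clean
  numerical separation of the two kernels.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InstabilityError,
    InvalidArgumentError,
    QualityError,
    RecalibrationAdvised,
)
from .kernels import (
    NoiseProtocol,
    SeparationResult,
    estimate_full_kernel,
    generate_probe_current,
    separate_kernels,
)
from .rig import VirtualRig

__all__ = [
    "ElectrodeStats",
    "MembraneStats",
    "ApplicabilityFlags",
    "CalibrationReport",
    "measure_electrode",
    "measure_membrane",
    "check_applicability",
    "run_aec_calibration",
    "assess_stationarity",
    "estimate_artifact_range",
    "count_spikes",
    "auto_kernel_lengths",
]

LINEARITY_CV_MAX = 0.15  # sd/mean of steady-state R across DC levels
RATIO_MIN = 10.0  # minimum tau_m / tau_e
SPEED_THRESHOLD_DEFAULT = 1.0  # ms; stricter 0.5 ms selectable
MAX_CALIBRATION_SPIKES = 5
CROSS_CHECK_REL_TOL = 0.25  # step-measured vs separated R_e/tau_e


@dataclass
class ElectrodeStats:
    """Steady-state electrode statistics from a DC-level series."""

    mean_R: float  # MΩ (mu_R)
    sd_R: float  # MΩ (sigma_R)
    cv: float  # sigma_R / mu_R
    tau_e: float  # ms
    per_level: list  # [(I nA, R MΩ), ...] for nonzero levels


@dataclass
class MembraneStats:
    """Passive membrane statistics from hyperpolarizing steps."""

    R_m: float  # MΩ
    tau_m: float  # ms
    sd_R_m: float  # MΩ across repeats
    sd_tau_m: float  # ms across repeats


@dataclass
class ApplicabilityFlags:
    linearity_pass: bool
    speed_pass: bool
    ratio_pass: bool

    @property
    def all_pass(self) -> bool:
        return self.linearity_pass and self.speed_pass and self.ratio_pass


@dataclass
class CalibrationReport:
    """Everything a calibration run produced, with every threshold used
    recorded so each pass/fail flag can be re-derived from the report."""

    electrode_in_bath: ElectrodeStats | None
    electrode_in_cell: ElectrodeStats
    membrane: MembraneStats
    separation: SeparationResult
    applicability: ApplicabilityFlags
    spike_count: int
    artifact_range: tuple  # (mV, mV)
    protocol: NoiseProtocol
    full_kernel_ms: float
    electrode_kernel_ms: float
    offset: float  # mV, fitted voltage offset
    cross_check_ok: bool
    warnings: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


def _steady(x: np.ndarray, fraction: float = 0.2) -> float:
    """Mean of the last ``fraction`` of a step response."""
    k = max(1, int(round(fraction * len(x))))
    return float(np.mean(x[-k:]))


def measure_electrode(
    rig: VirtualRig,
    I_min: float = -1.0,
    I_max: float = 1.0,
    n_levels: int = 11,
    step_duration: float | None = None,
    expected_tau: float = 0.35,
    settle_duration: float | None = None,
    drift_tolerance: float = 10.0,
) -> ElectrodeStats:
    """Series of DC current injections measuring electrode R and tau.

    For each nonzero level the steady-state resistance is the
    baseline-subtracted voltage deflection (mean of the last 20% of the
    step) divided by the current; the zero level, if present, is excluded
    from the statistics.  The electrode time constant comes from an
    exponential fit to the pooled, normalized step onsets.

    ``step_duration`` defaults to five electrode time constants (the
    rule of thumb for keeping the evoked cell response minimal while the
    electrode is on a cell).
    """
    if n_levels < 3:
        raise InvalidArgumentError("n_levels must be >= 3")
    if not I_min < I_max:
        raise InvalidArgumentError("I_min must be < I_max")
    levels = np.linspace(I_min, I_max, n_levels)
    nonzero = levels[np.abs(levels) > 1e-12]
    if len(nonzero) == 0:
        raise InvalidArgumentError("all current levels are zero")
    if len(nonzero) < 2:
        raise InvalidArgumentError(
            "at least two nonzero current levels are required (variance undefined)"
        )
    if step_duration is None:
        step_duration = 5.0 * expected_tau
    if settle_duration is None:
        # long enough for the (fast) electrode and most of any residual
        # membrane charge from the previous level to decay
        settle_duration = max(step_duration, 40.0 * expected_tau)
    dt = rig.config.timestep_base
    n_step = max(5, int(round(step_duration / dt)))
    n_base = max(5, int(round(settle_duration / dt)))

    per_level = []
    baselines = []
    onsets = []  # (t, normalized deflection) for tau fit
    t_rel = dt * np.arange(1, n_step + 1)
    for I in levels:
        base_rec = rig.record(np.zeros(n_base), dt)
        v0 = _steady(base_rec["V_raw"])
        step_rec = rig.record(np.full(n_step, I), dt)
        baselines.append(v0)
        if abs(I) <= 1e-12:
            continue
        dv_ss = _steady(step_rec["V_raw"]) - v0
        R = dv_ss / I
        per_level.append((float(I), float(R)))
        if dv_ss != 0.0:
            onsets.append((step_rec["V_raw"] - v0) / dv_ss)
    if max(baselines) - min(baselines) > drift_tolerance:
        raise QualityError(
            f"baseline drift {max(baselines) - min(baselines):.3g} mV exceeds "
            f"tolerance {drift_tolerance} mV"
        )
    Rs = np.array([r for _, r in per_level])
    mean_R = float(Rs.mean())
    sd_R = float(Rs.std(ddof=1))
    cv = sd_R / abs(mean_R) if mean_R != 0 else math.inf
    tau_e = _fit_onset_tau(t_rel[: int(0.8 * n_step) or 1], np.mean(onsets, axis=0)[: int(0.8 * n_step) or 1])
    return ElectrodeStats(mean_R=mean_R, sd_R=sd_R, cv=cv, tau_e=tau_e, per_level=per_level)


def _fit_onset_tau(t: np.ndarray, y_norm: np.ndarray) -> float:
    """Time constant of a normalized charging curve ``1 - exp(-t/tau)``.

    Log-linear fit to the residual ``1 - y`` on samples where it is
    clearly positive; a response that is complete within the first
    sample (a pure resistor at this sampling rate) returns 0.0.
    """
    resid = 1.0 - y_norm
    usable = resid > 0.02
    if usable.sum() < 3:
        return 0.0
    tt, rr = t[usable], resid[usable]
    w = rr**2
    ly = np.log(rr)
    W = w.sum()
    tbar = (w * tt).sum() / W
    ybar = (w * ly).sum() / W
    var = (w * (tt - tbar) ** 2).sum()
    if var == 0:
        return 0.0
    slope = (w * (tt - tbar) * (ly - ybar)).sum() / var
    if slope >= 0:
        return 0.0
    return float(-1.0 / slope)


def measure_membrane(
    rig: VirtualRig,
    electrode: ElectrodeStats,
    I_level: float = -0.1,
    step_duration: float = 150.0,
    n_repeats: int = 3,
    settle_duration: float | None = None,
    instability_tol: float = 0.5,
) -> MembraneStats:
    """Passive membrane R and tau from repeated DC steps.

    A hyperpolarizing level is recommended (a warning is issued for
    positive currents, which risk evoking spikes).  After discarding an
    initial window of ten electrode time constants, a single exponential
    is fitted to the slow approach to steady state of each repeat;
    ``R_m`` is the total steady deflection over current minus the
    (step-measured) electrode resistance.  High across-repeat scatter in
    the fitted time constant (relative sd above ``instability_tol``)
    raises :class:`InstabilityError`, advising stronger hyperpolarization.
    """
    if not step_duration > 0:
        raise InvalidArgumentError("step_duration must be > 0")
    if n_repeats < 1:
        raise InvalidArgumentError("n_repeats must be >= 1")
    if I_level == 0:
        raise InvalidArgumentError("I_level must be nonzero")
    if I_level > 0:
        _warnings.warn(
            "positive current during membrane measurement risks evoking spikes; "
            "hyperpolarization is recommended",
            UserWarning,
            stacklevel=2,
        )
    dt = rig.config.timestep_base
    if settle_duration is None:
        settle_duration = step_duration
    n_step = int(round(step_duration / dt))
    n_base = max(5, int(round(settle_duration / dt)))
    discard = 10.0 * max(electrode.tau_e, dt)
    R_ms, taus = [], []
    for _ in range(n_repeats):
        base_rec = rig.record(np.zeros(n_base), dt)
        v0 = _steady(base_rec["V_raw"])
        rec = rig.record(np.full(n_step, I_level), dt)
        t = rec["t"] - rec["t"][0] + dt
        v = rec["V_raw"]
        v_ss = _steady(v)
        dv_total = v_ss - v0
        R_total = dv_total / I_level
        R_ms.append(R_total - electrode.mean_R)
        keep = t >= discard
        resid = (v_ss - v[keep]) / (v_ss - v0) if dv_total != 0 else np.zeros(keep.sum())
        tau = _fit_residual_tau(t[keep], resid)
        if not math.isfinite(tau) or tau <= 0:
            raise InstabilityError(
                "membrane exponential fit failed; repeat with stronger "
                "hyperpolarizing current"
            )
        taus.append(tau)
    R_m = float(np.mean(R_ms))
    tau_m = float(np.mean(taus))
    sd_R = float(np.std(R_ms, ddof=1)) if n_repeats > 1 else 0.0
    sd_tau = float(np.std(taus, ddof=1)) if n_repeats > 1 else 0.0
    if tau_m > 0 and sd_tau / tau_m > instability_tol:
        raise InstabilityError(
            f"across-repeat tau_m scatter {sd_tau / tau_m:.2f} exceeds "
            f"{instability_tol}; the cell is not stationary — repeat with "
            "stronger hyperpolarizing current"
        )
    return MembraneStats(R_m=R_m, tau_m=tau_m, sd_R_m=sd_R, sd_tau_m=sd_tau)


def _fit_residual_tau(t: np.ndarray, resid: np.ndarray) -> float:
    """Exponential decay constant of a normalized step residual."""
    usable = resid > 1e-3
    if usable.sum() < 5:
        return math.nan
    tt, rr = t[usable], resid[usable]
    w = rr**2
    ly = np.log(rr)
    W = w.sum()
    tbar = (w * tt).sum() / W
    ybar = (w * ly).sum() / W
    var = (w * (tt - tbar) ** 2).sum()
    if var == 0:
        return math.nan
    slope = (w * (tt - tbar) * (ly - ybar)).sum() / var
    if slope >= 0:
        return math.nan
    return float(-1.0 / slope)


def check_applicability(
    e: ElectrodeStats,
    m: MembraneStats,
    speed_threshold: float = SPEED_THRESHOLD_DEFAULT,
) -> ApplicabilityFlags:
    """Evaluate the three applicability criteria (purely functional)."""
    ratio = m.tau_m / e.tau_e if e.tau_e > 0 else math.inf
    return ApplicabilityFlags(
        linearity_pass=e.cv < LINEARITY_CV_MAX,
        speed_pass=e.tau_e <= speed_threshold,
        ratio_pass=ratio > RATIO_MIN,
    )


def count_spikes(
    V, threshold: float, refractory: float = 2.0, dt: float | None = None, t=None
) -> int:
    """Count upward threshold crossings separated by a refractory interval."""
    if refractory < 0:
        raise InvalidArgumentError("refractory must be >= 0")
    V = np.asarray(V, dtype=float)
    if len(V) < 2:
        return 0
    if t is None:
        if dt is None:
            raise InvalidArgumentError("provide either dt or t")
        t = dt * np.arange(len(V))
    t = np.asarray(t, dtype=float)
    crossings = np.flatnonzero((V[:-1] < threshold) & (V[1:] >= threshold)) + 1
    count = 0
    last = -math.inf
    for idx in crossings:
        if t[idx] - last >= refractory:
            count += 1
            last = t[idx]
    return count


def auto_kernel_lengths(tau_e: float, tau_m: float) -> tuple[float, float]:
    """Default (full, electrode) kernel lengths in ms.

    Chosen to land inside the broad stable region of the calibration:
    full kernel 30-100 ms (twice the membrane time constant when that
    fits), electrode kernel 2-5 ms (ten electrode time constants when
    that fits).
    """
    full = min(100.0, max(30.0, 2.0 * tau_m))
    elec = min(5.0, max(2.0, 10.0 * tau_e))
    return full, elec


def estimate_artifact_range(R_e: float, I_min: float, I_max: float) -> tuple[float, float]:
    """Ohm's-law estimate of the expected artifact range ``[I_min R_e,
    I_max R_e]`` (mV) — the extra voltage range the digitizer must cover."""
    if not R_e > 0:
        raise InvalidArgumentError("R_e must be > 0")
    if I_min > I_max:
        raise InvalidArgumentError("I_min must be <= I_max")
    return (I_min * R_e, I_max * R_e)


def run_aec_calibration(
    rig: VirtualRig,
    protocol: NoiseProtocol | None = None,
    full_kernel_ms: float | None = None,
    electrode_kernel_ms: float | None = None,
    electrode_stats: ElectrodeStats | None = None,
    membrane_stats: MembraneStats | None = None,
    electrode_in_bath: ElectrodeStats | None = None,
    speed_threshold: float = SPEED_THRESHOLD_DEFAULT,
    spike_threshold: float | None = None,
    spike_refractory: float = 2.0,
    max_spikes: int = MAX_CALIBRATION_SPIKES,
) -> CalibrationReport:
    """Full AEC calibration: probe, estimate, separate, vet, report.

    When electrode or membrane statistics are not supplied they are
    measured first with the default step protocols; unset kernel lengths
    are auto-derived from the measured time constants
    (:func:`auto_kernel_lengths`).  The probe response is screened for
    spikes (threshold defaults to baseline + 20 mV, refractory 2 ms);
    more than ``max_spikes`` raises :class:`RecalibrationAdvised`.  The
    separated R_e and tau_e are cross-checked against the step-measured
    values; a relative difference above 25% flags the report
    (``cross_check_ok=False``) with a warning advising recalibration.
    """
    if protocol is None:
        protocol = NoiseProtocol()
    if electrode_stats is None:
        electrode_stats = measure_electrode(rig)
    if membrane_stats is None:
        membrane_stats = measure_membrane(rig, electrode_stats)
    if full_kernel_ms is None or electrode_kernel_ms is None:
        auto_full, auto_elec = auto_kernel_lengths(
            electrode_stats.tau_e, membrane_stats.tau_m
        )
        full_kernel_ms = full_kernel_ms if full_kernel_ms is not None else auto_full
        electrode_kernel_ms = (
            electrode_kernel_ms if electrode_kernel_ms is not None else auto_elec
        )

    dt = protocol.dt
    probe = generate_probe_current(protocol)
    rig.settle(200.0, protocol.holding_current)  # let transients decay
    rec = rig.record(probe, dt)
    baseline = rig.config.resting_potential
    thr = spike_threshold if spike_threshold is not None else baseline + 20.0
    # screen on a 0.5 ms boxcar-smoothed trace: genuine action potentials
    # (>= 1-2 ms wide) survive, while the sub-millisecond white-probe
    # artifact averages out and cannot masquerade as spikes
    from scipy.ndimage import uniform_filter1d

    k_smooth = max(1, int(round(0.5 / dt)))
    v_screen = uniform_filter1d(rec["V_raw"], k_smooth, mode="nearest")
    spike_count = count_spikes(v_screen, thr, spike_refractory, dt=dt)
    if spike_count > max_spikes:
        raise RecalibrationAdvised(
            f"{spike_count} spikes during probing (> {max_spikes}); repeat the "
            "calibration with a mild hyperpolarizing holding current"
        )
    n_bins = int(round(full_kernel_ms / dt))
    electrode_bins = int(round(electrode_kernel_ms / dt))
    full, offset = estimate_full_kernel(rec["I"], rec["V_raw"], n_bins, bin_width=dt)
    sep = separate_kernels(full, electrode_bins)

    report_warnings = list(sep.warnings)
    ok_R = _rel_close(sep.R_e, electrode_stats.mean_R, CROSS_CHECK_REL_TOL)
    ok_tau = (
        _rel_close(sep.tau_e, electrode_stats.tau_e, CROSS_CHECK_REL_TOL)
        if electrode_stats.tau_e > 0
        else True
    )
    cross_check_ok = ok_R and ok_tau
    if not cross_check_ok:
        report_warnings.append(
            "separated electrode properties differ significantly from the "
            f"step-measured values (R_e {sep.R_e:.2f} vs "
            f"{electrode_stats.mean_R:.2f} MΩ, tau_e {sep.tau_e:.3f} vs "
            f"{electrode_stats.tau_e:.3f} ms); calibration should be repeated"
        )
    flags = ApplicabilityFlags(
        linearity_pass=electrode_stats.cv < LINEARITY_CV_MAX,
        speed_pass=sep.tau_e <= speed_threshold,
        ratio_pass=(sep.tau_m / sep.tau_e > RATIO_MIN) if sep.tau_e > 0 else True,
    )
    limit = rig.config.daq_current_limit
    return CalibrationReport(
        electrode_in_bath=electrode_in_bath,
        electrode_in_cell=electrode_stats,
        membrane=membrane_stats,
        separation=sep,
        applicability=flags,
        spike_count=spike_count,
        artifact_range=estimate_artifact_range(sep.R_e, -limit, limit),
        protocol=protocol,
        full_kernel_ms=float(full_kernel_ms),
        electrode_kernel_ms=float(electrode_kernel_ms),
        offset=offset,
        cross_check_ok=cross_check_ok,
        warnings=report_warnings,
        thresholds={
            "linearity_cv_max": LINEARITY_CV_MAX,
            "ratio_min": RATIO_MIN,
            "speed_threshold_ms": speed_threshold,
            "max_spikes": max_spikes,
            "cross_check_rel_tol": CROSS_CHECK_REL_TOL,
            "spike_threshold_mV": thr,
            "spike_refractory_ms": spike_refractory,
        },
    )


def _rel_close(a: float, b: float, tol: float) -> bool:
    ref = max(abs(a), abs(b))
    return ref == 0 or abs(a - b) / ref <= tol


def assess_stationarity(
    reports: list, max_repeats: int = 10
) -> dict:
    """Judge whether repeated electrode measurements have stabilized.

    ``stationary`` requires the last two mean resistances to agree within
    5% relative and the last two time constants within 10% relative;
    ``trend`` is the per-repeat slope of the mean resistance.  Electrode
    properties that keep drifting after ``max_repeats`` repeats indicate
    the electrode should be replaced.
    """
    if len(reports) < 2:
        raise InvalidArgumentError("at least two repeated measurements are required")
    if len(reports) > max_repeats:
        raise InvalidArgumentError(
            f"more than max_repeats={max_repeats} measurements supplied"
        )
    mu = np.array([r.mean_R for r in reports])
    taus = np.array([r.tau_e for r in reports])
    dR = abs(mu[-1] - mu[-2]) / max(abs(mu[-2]), 1e-12)
    ref_tau = max(abs(taus[-2]), 1e-12)
    dtau = abs(taus[-1] - taus[-2]) / ref_tau
    trend = float(np.polyfit(np.arange(len(mu)), mu, 1)[0])
    return {"stationary": bool(dR < 0.05 and dtau < 0.10), "trend": trend}
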