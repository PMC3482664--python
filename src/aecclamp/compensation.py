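"""Online artifact estimation and subtraction under variable timesteps.

The electrode artifact at sample time ``t_n`` is the convolution of the
calibrated electrode kernel with the recent injected-current history.  In
a soft-real-time loop the sampling intervals vary from cycle to cycle, so
the fixed-bin "base kernel" recorded during calibration is resampled each
cycle onto the observed intervals: bins falling inside one interval are
summed, and bins straddling an interval border are split proportionally
to overlap.  This is realized exactly (and in linear time) by evaluating
the kernel's cumulative-mass function at the interval boundaries; total
mass over the kernel support is conserved to machine precision, so the
DC limit ``V_e = R_e · I`` holds exactly once a constant current has been
held for a full support length.

Alignment convention: kernel bin 0 multiplies the current injected over
the most recent *completed* interval — currents are attributed to the
interval over which they flowed, matching the piecewise-constant
injection model.  During warm-up (before a full kernel support of history
exists) missing history is treated as zero current.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, StateError
from .kernels import Kernel

__all__ = ["resample_base_kernel", "Compensator", "compensate_trace"]


def resample_base_kernel(base: Kernel, interval_widths) -> np.ndarray:
    """Integrate the base kernel's density over arbitrary intervals.

    Parameters
    ----------
    base : Kernel
        Fixed-bin kernel in mass convention.
    interval_widths : array-like of float
        Consecutive interval widths in ms, first interval starting at
        lag 0 (the newest completed sampling interval).  All widths must
        be positive.  Intervals extending beyond the kernel support
        receive the remaining (possibly zero) mass; if the intervals do
        not cover the support, the uncovered tail mass is simply not
        assigned (warm-up).

    Returns
    -------
    ndarray of per-interval masses (MΩ); total equals the base kernel's
    mass over the covered range exactly.
    """
    widths = np.asarray(interval_widths, dtype=float)
    if widths.ndim != 1:
        raise InvalidArgumentError("interval_widths must be one-dimensional")
    if np.any(widths <= 0):
        raise InvalidArgumentError("all interval widths must be > 0")
    edges = np.concatenate(([0.0], np.cumsum(widths)))
    # cumulative mass of the piecewise-constant kernel density
    xp = np.arange(len(base.masses) + 1) * base.bin_width
    fp = np.concatenate(([0.0], np.cumsum(base.masses)))
    cum = np.interp(edges, xp, fp)  # clamps beyond the support
    return np.diff(cum)


class Compensator:
    """Sliding-window state for per-cycle artifact estimation.

    Holds the calibrated base (electrode) kernel plus the recent injected
    currents and their sample times.  The window spans the kernel support
    ``L_e``; older entries are dropped, so memory stays bounded.

    Parameters
    ----------
    base_kernel : Kernel
        Electrode kernel from calibration.
    start_time : float
        Time (ms) at which the current history begins; the first call to
        :meth:`compensate` defines its interval relative to this origin.
    """

    def __init__(self, base_kernel: Kernel, start_time: float = 0.0):
        if base_kernel is None or len(base_kernel.masses) == 0:
            raise StateError("compensator requires a calibrated base kernel")
        self.base_kernel = base_kernel
        self.window_span = base_kernel.support
        self._last_t = float(start_time)
        # newest interval last; one (width, current) pair per interval
        self._widths: deque = deque()
        self._currents: deque = deque()

    # -- state inspection ---------------------------------------------------

    @property
    def last_time(self) -> float:
        return self._last_t

    @property
    def warmed_up(self) -> bool:
        """True once the stored history covers the full kernel support."""
        return sum(self._widths) >= self.window_span

    def estimate_artifact(self) -> float:
        """Electrode-artifact estimate (mV) at the newest stored time.

        The base kernel is resampled onto the stored interval widths
        (newest interval ↔ kernel bin 0) and dotted with the stored
        currents.  Missing history beyond the window counts as zero
        current.
        """
        if not self._widths:
            raise StateError("empty current-history window")
        widths = np.fromiter(reversed(self._widths), dtype=float, count=len(self._widths))
        currents = np.fromiter(
            reversed(self._currents), dtype=float, count=len(self._currents)
        )
        masses = resample_base_kernel(self.base_kernel, widths)
        return float(masses @ currents)

    def compensate(self, V_raw: float, I: float, t: float) -> float:
        """Process one sample: subtract the artifact and update the window.

        ``I`` is the current that flowed over the elapsed interval
        ``(last_time, t]``; the corrected voltage is ``V_raw`` minus the
        artifact estimate at ``t`` including that newest interval.
        """
        if t <= self._last_t:
            raise InvalidArgumentError(
                f"non-increasing timestamp: {t} after {self._last_t}"
            )
        self._widths.append(t - self._last_t)
        self._currents.append(I)
        self._last_t = float(t)
        v_corr = V_raw - self.estimate_artifact()
        self._trim()
        return v_corr

    def _trim(self) -> None:
        # keep the minimal suffix of intervals covering the kernel support
        total = sum(self._widths)
        while self._widths and total - self._widths[0] >= self.window_span:
            total -= self._widths.popleft()
            self._currents.popleft()


def compensate_trace(base: Kernel, t, I, V, start_time: float | None = None):
    """Offline batch application of the online compensation rule.

    Folds :meth:`Compensator.compensate` over a timestamped trace; pure
    function of its inputs.  ``I[n]`` is the current injected over the
    interval ending at ``t[n]``.

    Returns
    -------
    (V_corrected, Ve_est, warm_up) arrays; ``warm_up`` flags samples
    recorded before a full kernel support of history existed, so callers
    can exclude them from error statistics.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(I, dtype=float)
    V = np.asarray(V, dtype=float)
    if not (len(t) == len(I) == len(V)):
        raise InvalidArgumentError("t, I and V must have equal lengths")
    if len(t) == 0:
        return np.array([]), np.array([]), np.array([], dtype=bool)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("trace timestamps must be strictly increasing")
    if start_time is None:
        start_time = t[0] - (t[1] - t[0]) if len(t) > 1 else t[0] - 1.0
    comp = Compensator(base, start_time=start_time)
    v_corr = np.empty(len(t))
    warm = np.empty(len(t), dtype=bool)
    for n in range(len(t)):
        v_corr[n] = comp.compensate(V[n], I[n], t[n])
        warm[n] = not comp.warmed_up
    return v_corr, V - v_corr, warm
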