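"""Kernel estimation and electrode/membrane separation.

The calibration phase injects a known white-noise current train and
records the single-electrode voltage response.  The linear impulse
response ("full kernel") of electrode + passive membrane in series is
estimated by least squares; it is then separated numerically into a fast
electrode kernel K_e and a slow membrane kernel K_m, exploiting their
different time scales.  The electrode kernel's integral is the electrode
resistance R_e and its decay constant the electrode time constant tau_e;
K_e becomes the "base kernel" used online for artifact subtraction.

Kernels are stored in a discrete *mass* convention: bin ``j`` of a kernel
with bin width Δ covers ``[jΔ, (j+1)Δ)`` and holds the integral of the
continuous kernel density over that bin, in MΩ.  The sum of the masses is
therefore the DC resistance, and convolving masses with a piecewise-
constant current history directly yields millivolts.

Separation model: the measured full kernel is modelled as

    K = K_e + (K_m * K_e) / ΣK_e

i.e. the membrane contribution reaches the recording filtered through the
normalized electrode kernel.  Given the tail fit for K_m, the electrode
kernel solves the fixed-point equation ``K_e = K_trunc - (K_m * K_e)/ΣK_e``
on the electrode support, which we iterate with damping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz
from scipy.signal import fftconvolve

from .errors import EstimationError, InvalidArgumentError, QualityError, SeparationError

__all__ = [
    "Kernel",
    "NoiseProtocol",
    "SeparationResult",
    "generate_probe_current",
    "estimate_full_kernel",
    "separate_kernels",
    "compose_kernels",
    "kernel_scalar_props",
    "exponential_kernel",
]


@dataclass
class Kernel:
    """Fixed-bin discrete impulse response in mass convention (MΩ/bin)."""

    bin_width: float  # ms
    masses: np.ndarray  # MΩ per bin
    label: str = "full"  # one of {"full", "electrode", "membrane"}

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise InvalidArgumentError("bin_width must be > 0")
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.ndim != 1:
            raise InvalidArgumentError("masses must be one-dimensional")
        if not np.all(np.isfinite(self.masses)):
            raise InvalidArgumentError("kernel masses must be finite")

    @property
    def total_resistance(self) -> float:
        """Σ masses, the DC resistance in MΩ."""
        return float(self.masses.sum())

    @property
    def support(self) -> float:
        """Kernel support length in ms."""
        return len(self.masses) * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return (np.arange(len(self.masses)) + 0.5) * self.bin_width


@dataclass(frozen=True)
class NoiseProtocol:
    """Probe-current protocol for kernel calibration.

    Defaults are the recommended calibration conditions: 10 kHz current
    steps, 0.5 nA amplitude, 5 s duration (4-5 s gathers a statistically
    sufficient number of samples), zero holding current.
    """

    sample_rate: float = 10.0  # kHz
    duration: float = 5.0  # s
    amplitude: float = 0.5  # nA
    holding_current: float = 0.0  # nA
    rng_seed: int = 0
    law: str = "uniform"  # "uniform" levels in ±amplitude, or "binary"

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise InvalidArgumentError("sample_rate must be > 0")
        if not self.duration > 0:
            raise InvalidArgumentError("duration must be > 0")
        if self.amplitude < 0:
            raise InvalidArgumentError("amplitude must be >= 0")
        if self.law not in ("uniform", "binary"):
            raise InvalidArgumentError(f"unknown probe law {self.law!r}")

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * 1000.0 * self.duration))


def generate_probe_current(
    protocol: NoiseProtocol, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random piecewise-constant probe-current series (nA).

    Each step equals ``holding_current + amplitude * u`` with ``u``
    uniform on [-1, 1] (or ±1 for the binary law); zero-mean about the
    holding current in expectation and reproducible under the protocol
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.rng_seed)
    n = protocol.n_samples
    if protocol.amplitude == 0.0:
        return np.full(n, protocol.holding_current)
    if protocol.law == "binary":
        u = rng.integers(0, 2, n) * 2.0 - 1.0
    else:
        u = rng.uniform(-1.0, 1.0, n)
    return protocol.holding_current + protocol.amplitude * u


def estimate_full_kernel(
    I,
    V,
    n_bins: int,
    bin_width: float | None = None,
    solver: str = "toeplitz",
    ridge: float = 1e-8,
) -> tuple[Kernel, float]:
    """Least-squares estimate of the full kernel from a probe recording.

    Solves ``V_n ≈ offset + Σ_j K_j I_{n-j}`` for the ``n_bins`` kernel
    masses, with sample means of I and V subtracted first and the offset
    reported separately (the resting potential absorbs the holding
    current's DC response).  The normal equations are built from the
    auto-/cross-correlations of the mean-subtracted series, which makes
    the system Toeplitz; a small ridge term (``ridge`` times the trace,
    spread over the diagonal) guards against ill-conditioning.

    Parameters
    ----------
    I, V : array-like
        Injected current (nA) and recorded voltage (mV), uniformly
        sampled; sample ``n`` of V is taken at the end of the interval
        during which ``I[n]`` flowed, so kernel bin 0 multiplies the most
        recent completed interval.
    n_bins : int
        Number of kernel bins (support = ``n_bins * bin_width``).
    bin_width : float, optional
        Sampling interval in ms, stored on the returned kernel (defaults
        to 1.0 if not given; it does not affect the solution).
    solver : {"toeplitz", "dense"}
        "toeplitz" uses the stationary correlation approximation of the
        normal equations (fast, the default); "dense" solves the exact
        least-squares problem on the lagged design matrix and serves as a
        cross-check.

    Returns
    -------
    (Kernel, offset) with masses in MΩ and offset in mV.
    """
    I = np.asarray(I, dtype=float)
    V = np.asarray(V, dtype=float)
    if I.shape != V.shape or I.ndim != 1:
        raise InvalidArgumentError("I and V must be equal-length 1-D series")
    if n_bins < 2:
        raise InvalidArgumentError("n_bins must be >= 2")
    N = len(I)
    if N < 10 * n_bins:
        raise EstimationError(
            f"record too short: {N} samples for {n_bins} bins (need >= {10 * n_bins})"
        )
    i = I - I.mean()
    v = V - V.mean()
    if np.std(i) == 0.0:
        raise EstimationError("probe current is constant; kernel is unidentifiable")
    if solver == "dense":
        X = np.lib.stride_tricks.sliding_window_view(I[::-1], n_bins)[::-1]
        # row n of X is [I_n, I_{n-1}, ..., I_{n-n_bins+1}] for n >= n_bins-1
        y = V[n_bins - 1 :]
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        offset, masses = coef[0], coef[1:]
    elif solver == "toeplitz":
        r = fftconvolve(i, i[::-1], mode="full")[N - 1 : N - 1 + n_bins]
        gvec = fftconvolve(v, i[::-1], mode="full")[N - 1 : N - 1 + n_bins]
        r = r.copy()
        r[0] += ridge * n_bins * r[0]
        if r[0] <= 0:
            raise EstimationError("degenerate probe autocorrelation")
        try:
            masses = solve_toeplitz((r, r), gvec)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise EstimationError(f"singular normal equations: {exc}") from exc
        offset = V.mean() - float(masses.sum()) * I.mean()
    else:
        raise InvalidArgumentError(f"unknown solver {solver!r}")
    if not np.all(np.isfinite(masses)):
        raise EstimationError("non-finite kernel estimate (ill-conditioned probe)")
    return Kernel(bin_width=bin_width or 1.0, masses=masses, label="full"), float(offset)


def _fit_exponential(
    t: np.ndarray, m: np.ndarray
) -> tuple[float, float]:
    """Weighted log-linear fit ``m ≈ A exp(-t/tau)`` on positive values.

    Weights proportional to ``m**2`` make the log-domain fit equivalent to
    a first-order linear-domain least squares, which keeps small noisy
    tail bins from dominating.  Returns (A, tau); raises SeparationError
    when no decaying exponential can be fitted.
    """
    pos = m > 0
    if pos.sum() < 3:
        raise SeparationError("too few positive bins for an exponential fit")
    tt, mm = t[pos], m[pos]
    w = mm**2
    y = np.log(mm)
    W = w.sum()
    tbar = (w * tt).sum() / W
    ybar = (w * y).sum() / W
    cov = (w * (tt - tbar) * (y - ybar)).sum()
    var = (w * (tt - tbar) ** 2).sum()
    if var == 0.0:
        raise SeparationError("degenerate time support in exponential fit")
    slope = cov / var
    if slope >= 0.0:
        raise SeparationError("non-decaying tail: exponential fit impossible")
    tau = -1.0 / slope
    A = math.exp(ybar - slope * tbar)
    return A, tau


def _mean_lag(k: Kernel) -> float:
    """Mass-weighted mean lag of a kernel (fallback time-constant)."""
    m = k.masses
    total = m.sum()
    if total <= 0:
        return math.nan
    return float((m * k.bin_centers()).sum() / total)


def kernel_scalar_props(k: Kernel) -> tuple[float, float]:
    """Scalar (resistance, time constant) summary of a kernel.

    R is the mass sum; tau comes from an exponential fit to the masses,
    falling back to the mass-weighted mean lag when the fit is impossible.
    An all-zero kernel yields ``(0.0, nan)``.
    """
    if len(k.masses) == 0:
        raise InvalidArgumentError("empty kernel")
    R = k.total_resistance
    if not np.any(k.masses != 0.0):
        return 0.0, math.nan
    try:
        _, tau = _fit_exponential(k.bin_centers(), k.masses)
    except SeparationError:
        tau = _mean_lag(k)
    return R, float(tau)


@dataclass
class SeparationResult:
    """Outcome of electrode/membrane kernel separation."""

    electrode_kernel: Kernel
    membrane_kernel: Kernel
    R_e: float  # MΩ
    tau_e: float  # ms
    R_m: float  # MΩ
    tau_m: float  # ms
    iterations: int
    converged: bool
    warnings: list = field(default_factory=list)


def _masses_convolve(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """First ``n`` bins of the discrete mass convolution (Σ_s a_s b_{j-s})."""
    if len(a) > n:
        a = a[:n]
    if len(b) > n:
        b = b[:n]
    return fftconvolve(a, b)[:n]


def compose_kernels(ke: Kernel, km: Kernel, n_bins: int | None = None) -> Kernel:
    """Forward model: full kernel from electrode and membrane kernels.

    ``K = K_e + (K_m * K_e)/ΣK_e`` in mass convention.  Used as the
    independent oracle for separation tests and the consistency check.
    """
    if ke.bin_width != km.bin_width:
        raise InvalidArgumentError("kernels must share a bin width")
    n = n_bins if n_bins is not None else max(len(ke.masses), len(km.masses))
    Re = ke.total_resistance
    if Re <= 0:
        raise InvalidArgumentError("electrode kernel must have positive mass")
    ke_m = np.zeros(n)
    ke_m[: min(n, len(ke.masses))] = ke.masses[:n]
    filt = _masses_convolve(km.masses, ke.masses, n) / Re
    return Kernel(bin_width=ke.bin_width, masses=ke_m + filt, label="full")


def separate_kernels(
    full: Kernel,
    electrode_bins: int,
    tol: float = 1e-6,
    max_iter: int = 100,
    damping: float = 0.5,
    min_tail_bins: int = 10,
) -> SeparationResult:
    """Split a full kernel into electrode and membrane kernels.

    Procedure:

    1. Fit ``A exp(-t/tau_m)`` to the full-kernel tail (bins beyond the
       electrode support), giving the membrane kernel.  The membrane
       kernel is materialized on an extended support (about nine membrane
       time constants) so that its mass sum equals the membrane DC
       resistance R_m to better than 0.1%.
    2. Solve ``K_e = K_trunc - (K_m * K_e)/ΣK_e`` on the electrode
       support by damped fixed-point iteration, starting from the full
       kernel minus the membrane extrapolation.  Convergence is a
       relative L1 update below ``tol``; non-convergence is flagged on
       the result, never silent.
    3. Report R_e = ΣK_e and tau_e from an exponential fit to K_e
       (mass-weighted mean lag as fallback).

    Negative electrode-kernel bins are retained; only a non-positive
    total R_e raises a quality error.  A separated time-constant ratio
    tau_m/tau_e at or below 10 attaches an applicability warning.
    """
    n = len(full.masses)
    if not 1 <= electrode_bins < n:
        raise InvalidArgumentError(
            f"electrode_bins must be in [1, {n}), got {electrode_bins}"
        )
    dt = full.bin_width
    tail_t = full.bin_centers()[electrode_bins:]
    tail_m = full.masses[electrode_bins:]
    if np.allclose(tail_m, 0.0):
        # no membrane contribution: the electrode kernel is the full kernel
        electrode = Kernel(
            bin_width=dt, masses=full.masses[:electrode_bins].copy(), label="electrode"
        )
        R_e = electrode.total_resistance
        if R_e <= 0:
            raise QualityError("electrode resistance is non-positive")
        try:
            _, tau_e = _fit_exponential(electrode.bin_centers(), electrode.masses)
        except SeparationError:
            tau_e = _mean_lag(electrode)
        return SeparationResult(
            electrode_kernel=electrode,
            membrane_kernel=Kernel(bin_width=dt, masses=np.zeros(1), label="membrane"),
            R_e=R_e,
            tau_e=float(tau_e),
            R_m=0.0,
            tau_m=math.nan,
            iterations=0,
            converged=True,
        )
    if (tail_m > 0).sum() < min_tail_bins:
        raise SeparationError(
            "too few positive tail bins for the membrane fit; "
            "use a longer full kernel"
        )
    A, tau_m = _fit_exponential(tail_t, tail_m)
    n_mem = max(n, int(math.ceil(9.5 * tau_m / dt)))
    mem_centers = (np.arange(n_mem) + 0.5) * dt
    km = A * np.exp(-mem_centers / tau_m)
    membrane = Kernel(bin_width=dt, masses=km, label="membrane")
    R_m = membrane.total_resistance

    ktrunc = full.masses[:electrode_bins].copy()
    km_e = km[:electrode_bins]
    ke = ktrunc - km_e
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = ke.sum()
        if denom <= 0:
            raise QualityError(
                "electrode kernel mass became non-positive during separation"
            )
        corr = _masses_convolve(km, ke, electrode_bins) / denom
        new = ktrunc - corr
        step = damping * (new - ke)
        ke_next = ke + step
        ref = np.abs(ke).sum()
        rel = np.abs(ke_next - ke).sum() / ref if ref > 0 else np.inf
        ke = ke_next
        if rel < tol:
            converged = True
            break
    electrode = Kernel(bin_width=dt, masses=ke, label="electrode")
    R_e = electrode.total_resistance
    if R_e <= 0:
        raise QualityError(f"separated electrode resistance is non-positive ({R_e:.3g} MΩ)")
    try:
        _, tau_e = _fit_exponential(electrode.bin_centers(), ke)
    except SeparationError:
        tau_e = _mean_lag(electrode)
    warnings: list[str] = []
    if tau_e > 0 and tau_m / tau_e <= 10.0:
        warnings.append(
            f"tau_m/tau_e = {tau_m / tau_e:.2f} <= 10: "
            "electrode too slow for reliable compensation"
        )
    if not converged:
        warnings.append(f"fixed-point iteration did not converge in {max_iter} steps")
    return SeparationResult(
        electrode_kernel=electrode,
        membrane_kernel=membrane,
        R_e=R_e,
        tau_e=float(tau_e),
        R_m=R_m,
        tau_m=float(tau_m),
        iterations=it,
        converged=converged,
        warnings=warnings,
    )


def exponential_kernel(
    R: float, tau: float, bin_width: float, n_bins: int, label: str = "electrode"
) -> Kernel:
    """Discretized single-exponential kernel with exact mass sum.

    Bin ``j`` holds ``R (1 - α) α^j`` with ``α = exp(-Δ/τ)``: the exact
    per-bin response increments of a parallel-RC element probed with
    piecewise-constant current, whose infinite sum is exactly ``R``.
    """
    if tau <= 0:
        masses = np.zeros(n_bins)
        masses[0] = R
        return Kernel(bin_width=bin_width, masses=masses, label=label)
    alpha = math.exp(-bin_width / tau)
    j = np.arange(n_bins)
    return Kernel(bin_width=bin_width, masses=R * (1 - alpha) * alpha**j, label=label)
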