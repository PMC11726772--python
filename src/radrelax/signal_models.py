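"""Closed-form relaxation signal equations and voxel-level fitting.

These functions drive both the forward simulator (evaluating contrast at
the acquisition's effective times) and the voxelwise map fitting:

* saturation-recovery look-locker signal and its five-parameter fit,
  yielding the apparent recovery time ``T1eff`` under continuous
  small-flip-angle readout;
* the flip-angle driven-equilibrium correction from ``T1eff`` to ``T1``;
* T1-corrected normalization of spin-lock (T1rho) decay series and the
  asymptotic / slow-component log-slope estimators;
* plain mono-exponential fitting used for single-component T1rho and
  2D multi-contrast T2 mapping.

All fitting is magnitude-domain unless complex data are supplied, in
which case a global phase is estimated.  Voxelwise fit failures return
NaN rather than raising, so map computation is robust to degenerate
voxels; callers count NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("radrelax")

# Bounds for all fitted time constants, seconds.  Wide enough for every
# tissue and phantom in scope; keeps the optimizer out of degenerate
# corners on flat curves.
TIME_CONSTANT_BOUNDS_S = (1e-3, 100.0)


class CorrectionInstabilityError(ValueError):
    """T1eff -> T1 flip-angle correction produced a non-positive rate.

    Carries the offending apparent rate so callers can report which
    voxels were affected.  Occurs when the readout perturbation term
    ``ln(cos alpha)/tau`` exceeds the apparent relaxation rate, i.e. at
    high flip angles and long T1eff.
    """

    def __init__(self, rate: float):
        self.rate = float(rate)
        super().__init__(
            f"T1eff->T1 correction unstable: corrected rate {rate:.6g} 1/s <= 0 "
            "(flip angle too high for this T1eff)"
        )


@dataclass
class RelaxationParameters:
    """Ground-truth relaxation parameters of one tissue/compartment.

    t1 in seconds, t1rho and t2 in milliseconds, m0 in arbitrary signal
    units (equilibrium magnetization amplitude).
    """

    t1: float
    t1rho: float
    t2: float
    m0: float = 1.0

    def __post_init__(self):
        if not (self.t1 > 0 and self.t1rho > 0 and self.t2 > 0):
            raise ValueError("all relaxation time constants must be > 0")
        if not np.isfinite(self.m0) or self.m0 < 0:
            raise ValueError("m0 must be finite and >= 0")


@dataclass
class LookLockerCurve:
    """One saturation-recovery curve sampled at frame times (seconds)."""

    times: np.ndarray
    signal: np.ndarray
    t1eff: float | None = None
    sat_efficiency: float | None = None
    steady_state: float | None = None
    offset: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal)
        if self.times.ndim != 1 or self.times.shape != self.signal.shape[:1]:
            raise ValueError("times and signal must be 1-D and equal length")
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] < 0):
            raise ValueError("times must be non-negative and strictly increasing")


@dataclass
class SpinLockSeries:
    """Signal vs spin-lock duration (TSL, ms) for one voxel.

    ``t1_reference`` (seconds) is the voxel's T1 used for the recovery
    normalization; ``np.inf`` disables the T1 correction.
    """

    tsl: np.ndarray
    signal: np.ndarray
    t1_reference: float = np.inf

    def __post_init__(self):
        self.tsl = np.asarray(self.tsl, dtype=float)
        self.signal = np.asarray(self.signal)
        if self.tsl.size < 2:
            raise ValueError("need at least 2 TSL points")
        if self.tsl[0] != 0:
            raise ValueError("first TSL must be 0 (normalization reference)")
        if np.any(np.diff(self.tsl) <= 0) or np.any(self.tsl < 0):
            raise ValueError("tsl must be non-negative and strictly increasing")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def sat_recovery_signal(t, steady_state, sat_efficiency, t1eff, offset=0.0):
    """Saturation-recovery look-locker signal at recovery time ``t`` (s).

    ``offset + steady_state * (1 - sat_efficiency * exp(-t/t1eff))``.
    Monotone non-decreasing in ``t`` for ``sat_efficiency > 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("recovery time must be >= 0")
    if not t1eff > 0:
        raise ValueError("t1eff must be > 0")
    if not (0 <= sat_efficiency <= 1):
        raise ValueError("sat_efficiency must be in [0, 1]")
    out = offset + steady_state * (1.0 - sat_efficiency * np.exp(-t / t1eff))
    return out if out.ndim else float(out)


def apparent_rate(t1: float, flip_angle: float, spoke_time: float) -> float:
    """Forward map T1 -> apparent rate: R1eff = 1/T1 - ln(cos alpha)/tau."""
    alpha = np.deg2rad(flip_angle)
    return 1.0 / t1 - np.log(np.cos(alpha)) / spoke_time


def correct_t1eff_to_t1(t1eff: float, flip_angle: float, spoke_time: float) -> float:
    """Correct the apparent look-locker time to T1 (both seconds).

    Driven-equilibrium correction ``1/T1 = 1/T1eff + ln(cos alpha)/tau``
    for flip angle ``alpha`` (degrees) and spoke duration ``tau`` (s).
    Exact inverse of :func:`apparent_rate`.  Raises
    :class:`CorrectionInstabilityError` when the corrected rate is
    non-positive, which happens at high flip angles — the regime where
    the correction is known to become unreliable.
    """
    if not (0 <= flip_angle < 90):
        raise ValueError("flip angle must be in [0, 90) degrees")
    if not spoke_time > 0:
        raise ValueError("spoke_time must be > 0")
    if not t1eff > 0:
        raise ValueError("t1eff must be > 0")
    rate = 1.0 / t1eff + np.log(np.cos(np.deg2rad(flip_angle))) / spoke_time
    if rate <= 0:
        raise CorrectionInstabilityError(rate)
    return 1.0 / rate


def t1_recovery_fraction(t1_reference: float, readout_duration: float) -> float:
    """Readout-average recovery weight f in (0, 1].

    The spin-lock frame signal is modeled as the readout-average of the
    longitudinal recovery after the preparation block:
    ``S(tsl) = M0 * (1 - (1 - exp(-tsl/T1rho)) * f)`` with
    ``f = (T1/T_read) * (1 - exp(-T_read/T1))``.  f -> 1 as T1 -> inf
    (no recovery during readout, pure mono-exponential decay).
    """
    if not readout_duration > 0:
        raise ValueError("readout duration must be > 0")
    if not t1_reference > 0:
        raise ValueError("t1_reference must be > 0")
    if np.isinf(t1_reference):
        return 1.0
    x = readout_duration / t1_reference
    return float((1.0 - np.exp(-x)) / x)


def spinlock_frame_signal(tsl_ms, t1rho_ms, m0=1.0, recovery_fraction=1.0):
    """Spin-lock prepared frame intensity (forward model for simulation)."""
    tsl_ms = np.asarray(tsl_ms, dtype=float)
    e_rho = np.exp(-tsl_ms / t1rho_ms)
    return m0 * (1.0 - (1.0 - e_rho) * recovery_fraction)


def normalize_spinlock(series: SpinLockSeries, protocol=None) -> np.ndarray:
    """Normalize a spin-lock series to a pure mono-exponential decay.

    Divides by the TSL=0 signal and inverts the T1-driven recovery of
    the readout, using ``series.t1_reference`` and the protocol's
    inter-preparation readout duration (``prep_period * spoke_time``).
    The normalized value at TSL=0 is exactly 1; with
    ``t1_reference = inf`` the normalization reduces to plain division.

    Raises ZeroDivisionError when the TSL=0 signal is zero (caller
    excludes the voxel from mapping).
    """
    s = np.abs(np.asarray(series.signal, dtype=float)) if np.iscomplexobj(
        series.signal) else np.asarray(series.signal, dtype=float)
    s0 = s[0]
    if s0 == 0:
        raise ZeroDivisionError("TSL=0 signal is zero; voxel cannot be normalized")
    y = s / s0
    if protocol is not None and np.isfinite(series.t1_reference):
        t_read = protocol.prep_period * protocol.spoke_time
        f = t1_recovery_fraction(series.t1_reference, t_read)
    else:
        f = 1.0
    # invert S/S0 = 1 - (1 - E_rho) * f  ->  E_rho = 1 - (1 - y)/f
    norm = 1.0 - (1.0 - y) / f
    norm[0] = 1.0
    return norm


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_monoexp(x, y):
    """Least-squares fit of ``y = A * exp(-x/tau)``; returns (A, tau).

    ``x`` and ``tau`` share units.  Log-linear regression over positive
    samples initializes the nonlinear fit, so noiseless mono-exponential
    input is recovered exactly.  Degenerate input (no decay, non-positive
    signal everywhere, non-convergence) returns ``(nan, nan)``.
    Non-finite input raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must match and contain >= 2 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to fit_monoexp")

    pos = y > 0
    if pos.sum() < 2:
        return np.nan, np.nan
    slope, logA = np.polyfit(x[pos], np.log(y[pos]), 1)
    if slope >= 0:  # no decay: tau would be infinite/negative
        return np.nan, np.nan
    tau0 = float(np.clip(-1.0 / slope, *_scaled_bounds(x)))
    A0 = float(np.exp(logA))

    def resid(p):
        return p[0] * np.exp(-x / p[1]) - y

    lo, hi = _scaled_bounds(x)
    try:
        res = least_squares(resid, [A0, tau0], bounds=([0.0, lo], [np.inf, hi]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:  # pragma: no cover - optimizer edge cases
        return np.nan, np.nan
    if not res.success:
        return np.nan, np.nan
    if res.x[1] >= 0.99 * hi:  # at the bound: no decay resolvable, censor
        return np.nan, np.nan
    return float(res.x[0]), float(res.x[1])


def _scaled_bounds(x):
    """Time-constant bounds scaled to the span of the time axis: decays
    slower than ~100x the sampled window are not resolvable from it."""
    span = float(np.max(np.abs(x))) or 1.0
    return TIME_CONSTANT_BOUNDS_S[0] * span, TIME_CONSTANT_BOUNDS_S[1] * span


def fit_looklocker(curve: LookLockerCurve, fit_offset: bool = False):
    """Five-parameter saturation-recovery fit.

    Returns ``(steady_state, sat_efficiency, t1eff, offset, phase)``.
    For magnitude input the phase is fixed at 0; for complex input a
    global phase is estimated.  The constant offset is fixed at 0 unless
    ``fit_offset`` — with a free offset the model
    ``offset + S*(1 - eff*exp(-t/T))`` has only three identifiable real
    degrees of freedom, so the default keeps the parameters meaningful.
    Flat or degenerate curves return all-NaN instead of raising.
    """
    t = curve.times
    sig = np.asarray(curve.signal)
    if t.size < 6:
        raise ValueError("need >= 6 samples for the five-parameter fit")
    nan = (np.nan,) * 5

    is_complex = np.iscomplexobj(sig)
    if is_complex:
        phase0 = float(np.angle(np.sum(sig)))
        y = np.real(sig * np.exp(-1j * phase0))
    else:
        phase0 = 0.0
        y = sig.astype(float)

    span = float(np.ptp(y))
    if not np.all(np.isfinite(y)) or span == 0 or np.max(np.abs(y)) == 0:
        return nan

    # heuristic start: plateau ~ max, full saturation, T1eff ~ median time
    t10 = float(np.clip(np.median(t[t > 0]) if np.any(t > 0) else 1.0,
                        *TIME_CONSTANT_BOUNDS_S))
    p0 = [float(np.max(y)), 0.98, t10]
    lo = [0.0, 0.0, TIME_CONSTANT_BOUNDS_S[0]]
    hi = [np.inf, 1.0, TIME_CONSTANT_BOUNDS_S[1]]
    if fit_offset:
        p0.append(float(np.min(y)))
        lo.append(-np.inf)
        hi.append(np.inf)

    def model(p):
        off = p[3] if fit_offset else 0.0
        return off + p[0] * (1.0 - p[1] * np.exp(-t / p[2]))

    def resid(p):
        return model(p) - y

    try:
        res = least_squares(resid, p0, bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:  # pragma: no cover
        return nan
    if not res.success:
        return nan
    ss, eff, t1eff = res.x[:3]
    if t1eff >= 0.99 * TIME_CONSTANT_BOUNDS_S[1]:  # unresolvable recovery
        return nan
    off = float(res.x[3]) if fit_offset else 0.0
    if is_complex:
        # refine the global phase against the fitted real-valued model
        m = model(res.x)
        phase = phase0 + float(np.angle(np.vdot(m, sig * np.exp(-1j * phase0))))
    else:
        phase = 0.0
    return float(ss), float(eff), float(t1eff), off, float(phase)


def t1rho_asymptotic(tsl_ms, normalized) -> float:
    """Asymptotic-average T1rho (ms): log-slope over the first two points.

    ``-(tsl[1]-tsl[0]) / (ln S[1] - ln S[0])``; NaN when either
    normalized value is non-positive or the slope is zero.
    """
    tsl_ms = np.asarray(tsl_ms, dtype=float)
    s = np.asarray(normalized, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 points")
    if s[0] <= 0 or s[1] <= 0:
        return np.nan
    d = np.log(s[1]) - np.log(s[0])
    if d == 0:
        return np.nan
    return float(-(tsl_ms[1] - tsl_ms[0]) / d)


def t1rho_slow(tsl_ms, normalized, skip: int = 2) -> float:
    """Slow-component T1rho (ms): -1/slope of the late log-domain line.

    Ordinary least squares of ``ln S`` vs TSL over points ``skip:``
    (default drops the first two, which carry the fast component).
    NaN when fewer than two usable (positive) points remain or the
    slope is non-negative.
    """
    tsl_ms = np.asarray(tsl_ms, dtype=float)[skip:]
    s = np.asarray(normalized, dtype=float)[skip:]
    ok = s > 0
    if ok.sum() < 2:
        return np.nan
    slope = np.polyfit(tsl_ms[ok], np.log(s[ok]), 1)[0]
    if slope >= 0:
        return np.nan
    return float(-1.0 / slope)
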