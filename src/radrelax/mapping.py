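"""Voxelwise relaxation-time map computation.

Maps are fitted pixel-by-pixel from reconstructed image series:

* T1: five-parameter saturation-recovery fit per voxel (T1eff map),
  followed by the flip-angle driven-equilibrium correction to T1;
* T1rho: T1-corrected normalization of the spin-lock series, then a
  two-parameter mono-exponential fit (single-component T1rho) and the
  asymptotic / slow log-slope surrogates (T1rho_a, T1rho_s);
* generic 2D multi-contrast mono-exponential mapping (T2, 2D T1rho).

Fit failures yield NaN voxels (never exceptions); failure counts are
logged and stored.  Maps carry a units tag and can be written as NIfTI
with a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from . import signal_models as sm
from .geometry import SequenceProtocol
from .simulate import ImageSeries

logger = logging.getLogger("radrelax")


@dataclass
class RelaxationMap:
    """Voxel grid of one tissue parameter; NaN outside mask / failed fits."""

    values: np.ndarray
    units: str
    mask: np.ndarray
    fit_quality: np.ndarray | None = None
    n_failed: int = 0
    voxel_size_mm: float = 1.0
    name: str = ""

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")

    def finite_values(self, submask=None) -> np.ndarray:
        m = self.mask if submask is None else (self.mask & submask)
        v = self.values[m]
        return v[np.isfinite(v)]

    def to_nifti(self, path: str) -> None:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.values.astype(np.float32), affine)
        img.header["descrip"] = f"{self.name} [{self.units}]".encode()[:79]
        nib.save(img, path)
        with open(path + ".json", "w") as f:
            json.dump({"name": self.name, "units": self.units,
                       "n_failed": int(self.n_failed),
                       "n_masked": int(self.mask.sum())}, f, indent=1)


def auto_mask(series: ImageSeries, threshold_frac: float = 0.05) -> np.ndarray:
    """Deterministic support mask: first-frame magnitude above
    ``threshold_frac`` of its 99th percentile (T1rho: TSL=0 frame; T1:
    the last/most-recovered frame gives the stablest support, so the
    maximum over frames is used)."""
    mag = np.abs(series.frames).max(axis=0)
    return mag > threshold_frac * np.percentile(mag, 99)


def map_t1(series: ImageSeries, protocol: SequenceProtocol,
           mask: np.ndarray | None = None):
    """Voxelwise (T1eff, T1) maps in seconds.

    Fits the saturation-recovery model to each masked voxel's magnitude
    curve, then applies the flip-angle correction
    ``1/T1 = 1/T1eff + ln(cos a)/tau``.  Correction-unstable voxels and
    failed fits are NaN and counted.
    """
    if protocol.spoke_time is None or protocol.flip_angle is None:
        raise ValueError("protocol timing (spoke_time, flip_angle) required")
    if series.frame_times is None or not len(series.frame_times):
        raise ValueError("series frame times required")
    if mask is None:
        mask = auto_mask(series)
    t = series.frame_times
    mag = np.abs(series.frames)
    N = series.matrix
    t1eff = np.full((N, N, N), np.nan)
    t1 = np.full((N, N, N), np.nan)
    quality = np.full((N, N, N), np.nan)
    n_failed = 0
    for i, j, k in zip(*np.nonzero(mask)):
        curve = sm.LookLockerCurve(times=t, signal=mag[:, i, j, k])
        ss, eff, te, off, _ = sm.fit_looklocker(curve)
        if not np.isfinite(te):
            n_failed += 1
            continue
        t1eff[i, j, k] = te
        resid = sm.sat_recovery_signal(t, ss, eff, te, off) - mag[:, i, j, k]
        quality[i, j, k] = np.linalg.norm(resid)
        if protocol.flip_angle == 0:
            t1[i, j, k] = te
        else:
            try:
                t1[i, j, k] = sm.correct_t1eff_to_t1(
                    te, protocol.flip_angle, protocol.spoke_time)
            except sm.CorrectionInstabilityError:
                n_failed += 1
    if n_failed:
        logger.info("map_t1: %d voxel fits failed", n_failed)
    mk = dict(mask=mask, fit_quality=quality, n_failed=n_failed)
    return (RelaxationMap(t1eff, "s", name="T1eff", **mk),
            RelaxationMap(t1, "s", name="T1", **mk))


def map_t1rho(series: ImageSeries, t1_map: RelaxationMap | None,
              protocol: SequenceProtocol, mask: np.ndarray | None = None):
    """Voxelwise (T1rho, T1rho_a, T1rho_s) maps in ms.

    Normalizes each voxel's spin-lock decay for T1 recovery using the
    supplied T1 map (``None`` disables the correction), then fits the
    two-parameter mono-exponential and computes both log-slope
    surrogates.  The surrogates are computed only where all normalized
    points are positive (log-domain validity).
    """
    tsl = series.frame_times
    if tsl[0] != 0:
        raise ValueError("T1rho series must include TSL=0")
    if t1_map is not None and t1_map.values.shape != series.frames.shape[1:]:
        raise ValueError("T1 map grid does not match series grid")
    if mask is None:
        mask = auto_mask(series)
    mag = np.abs(series.frames)
    N = series.matrix
    out = {k: np.full((N, N, N), np.nan) for k in ("t1rho", "a", "s")}
    quality = np.full((N, N, N), np.nan)
    n_failed = 0
    for i, j, k in zip(*np.nonzero(mask)):
        sig = mag[:, i, j, k]
        t1ref = np.inf
        if t1_map is not None and np.isfinite(t1_map.values[i, j, k]):
            t1ref = t1_map.values[i, j, k]
        try:
            ser = sm.SpinLockSeries(tsl=tsl, signal=sig, t1_reference=t1ref)
            norm = sm.normalize_spinlock(ser, protocol)
        except (ZeroDivisionError, ValueError):
            n_failed += 1
            continue
        amp, tau = sm.fit_monoexp(tsl, norm)
        if np.isfinite(tau):
            out["t1rho"][i, j, k] = tau
            quality[i, j, k] = np.linalg.norm(amp * np.exp(-tsl / tau) - norm)
        else:
            n_failed += 1
        if np.all(norm > 0):
            out["a"][i, j, k] = sm.t1rho_asymptotic(tsl, norm)
            out["s"][i, j, k] = sm.t1rho_slow(tsl, norm)
    if n_failed:
        logger.info("map_t1rho: %d voxel fits failed", n_failed)
    return (RelaxationMap(out["t1rho"], "ms", mask=mask, fit_quality=quality,
                          n_failed=n_failed, name="T1rho"),
            RelaxationMap(out["a"], "ms", mask=mask, name="T1rho_a"),
            RelaxationMap(out["s"], "ms", mask=mask, name="T1rho_s"))


def map_monoexp_2d(stack: np.ndarray, times: np.ndarray,
                   mask: np.ndarray | None = None, units: str = "ms",
                   name: str = "T2") -> RelaxationMap:
    """Mono-exponential map from a multi-contrast stack.

    ``stack``: (n_contrasts, ...) magnitude images indexed by the
    contrast times (TE list for T2, TSL list for spin-lock).  Fits
    ``A exp(-t/tau)`` per voxel; constant/degenerate voxels are NaN.
    """
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need >= 2 contrast times")
    stack = np.abs(np.asarray(stack))
    spatial = stack.shape[1:]
    if mask is None:
        mask = stack[0] > 0.05 * np.percentile(stack[0], 99)
    vals = np.full(spatial, np.nan)
    n_failed = 0
    for idx in zip(*np.nonzero(mask)):
        sig = stack[(slice(None),) + idx]
        amp, tau = sm.fit_monoexp(times, sig)
        if np.isfinite(tau):
            vals[idx] = tau
        else:
            n_failed += 1
    if n_failed:
        logger.info("map_monoexp_2d: %d voxel fits failed", n_failed)
    return RelaxationMap(vals, units, mask=mask, n_failed=n_failed, name=name)
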