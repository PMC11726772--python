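"""Forward simulation: phantom + protocol -> multi-frame radial k-space.

Each frame is modeled as a static contrast-weighted image (intra-frame
relaxation is below the binning granularity used for fitting):

* T1 mode — frame j evaluates the saturation-recovery signal at the
  frame's mean post-saturation time, with steady-state amplitude
  ``m0 * t1eff/t1`` (driven-equilibrium amplitude under continuous
  small-flip readout) and configurable saturation efficiency;
* T1rho mode — frame j applies the spin-lock decay at its TSL plus the
  readout-average T1 recovery factor (the same convention the mapping
  normalization inverts).

Sampling evaluates the non-uniform Fourier transform of each frame
along its spokes and adds i.i.d. circular complex Gaussian noise.  A
single receive channel is assumed (volume transceiver coil).
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from . import signal_models as sm
from .geometry import SequenceProtocol, SpokeSet
from .nufft import KaiserBesselGrid, dft_forward, spoke_sample_coords
from .phantom import PhantomDefinition

DEFAULT_SAT_EFFICIENCY = 0.95


@dataclass
class ImageSeries:
    """Stack of co-registered contrast-weighted 3D images.

    ``frames`` has shape (n_frames, N, N, N), complex; ``frame_times``
    is the recovery time (s, T1 mode) or TSL (ms, T1rho mode).
    """

    frames: np.ndarray
    frame_times: np.ndarray
    mode: str
    protocol: SequenceProtocol | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.shape[0] != self.frame_times.size:
            raise ValueError("frames/frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def matrix(self) -> int:
        return self.frames.shape[1]


@dataclass
class RadialKSpace:
    """Complex samples along center-out spokes, (n_spokes, samples_per_spoke)."""

    samples: np.ndarray
    spokes: SpokeSet
    protocol: SequenceProtocol
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.samples.shape[0] != len(self.spokes):
            raise ValueError("sample count inconsistent with spoke set")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite k-space samples")

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            self.spokes.to_hdf5(f.create_group("spokes"))
            g = f.create_group("protocol")
            for k, v in self.protocol.to_dict().items():
                g.attrs[k] = v if not isinstance(v, tuple) else list(v)
            f.attrs["noise_sigma"] = self.noise_sigma
            f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path: str) -> "RadialKSpace":
        with h5py.File(path, "r") as f:
            spokes = SpokeSet.from_hdf5(f["spokes"])
            pdict = {k: v for k, v in f["protocol"].attrs.items()}
            if "tsl_list" in pdict:
                pdict["tsl_list"] = tuple(np.atleast_1d(pdict["tsl_list"]).tolist())
            for k in ("matrix", "spokes_total", "spokes_per_curve", "n_frames",
                      "prep_period", "samples_per_spoke"):
                if k in pdict:
                    pdict[k] = int(pdict[k])
            protocol = SequenceProtocol(**pdict)
            return cls(samples=f["samples"][:], spokes=spokes, protocol=protocol,
                       noise_sigma=float(f.attrs["noise_sigma"]),
                       seed=int(f.attrs["seed"]))


def frame_images(phantom: PhantomDefinition, protocol: SequenceProtocol,
                 frame_times: np.ndarray,
                 sat_efficiency: float = DEFAULT_SAT_EFFICIENCY,
                 t1_recovery: bool = True) -> ImageSeries:
    """Evaluate per-frame contrast-weighted images of a phantom.

    ``frame_times``: recovery times (s) for T1 mode, TSLs (ms) for
    T1rho mode.  ``t1_recovery=False`` disables the readout T1 factor
    in T1rho mode (pure mono-exponential decay).
    """
    mask = phantom.mask
    m0 = phantom.maps["m0"]
    N = phantom.matrix
    if N != protocol.matrix:
        raise ValueError("phantom/protocol matrix mismatch")
    frames = np.zeros((len(frame_times), N, N, N), dtype=complex)
    if protocol.mode == "t1":
        t1 = phantom.maps["t1"]
        with np.errstate(divide="ignore", invalid="ignore"):
            r1eff = np.where(mask, 1.0 / np.where(mask, t1, 1.0)
                             - np.log(np.cos(np.deg2rad(protocol.flip_angle)))
                             / protocol.spoke_time, 0.0)
            t1eff = np.where(mask, 1.0 / np.where(r1eff > 0, r1eff, 1.0), 0.0)
            steady = np.where(mask, m0 * t1eff / np.where(mask, t1, 1.0), 0.0)
        for j, t in enumerate(frame_times):
            sig = steady * (1.0 - sat_efficiency *
                            np.exp(-t / np.where(mask, t1eff, 1.0)))
            frames[j] = np.where(mask, sig, 0.0)
    elif protocol.mode == "t1rho":
        t1rho = phantom.maps["t1rho"]
        if t1_recovery:
            t_read = protocol.prep_period * protocol.spoke_time
            t1 = phantom.maps["t1"]
            x = np.where(mask, t_read / np.where(mask, t1, 1.0), 1.0)
            f = np.where(mask, (1.0 - np.exp(-x)) / x, 1.0)
        else:
            f = np.ones_like(m0)
        for j, tsl in enumerate(frame_times):
            e_rho = np.exp(-tsl / np.where(mask, t1rho, 1.0))
            frames[j] = np.where(mask, m0 * (1.0 - (1.0 - e_rho) * f), 0.0)
    else:
        raise ValueError(f"unsupported mode {protocol.mode!r}")
    return ImageSeries(frames=frames, frame_times=np.asarray(frame_times, float),
                       mode=protocol.mode, protocol=protocol)


def sample_kspace(series: ImageSeries, spokes: SpokeSet, noise_sigma: float = 0.0,
                  seed: int = 0, engine: str = "gridding",
                  nufft: KaiserBesselGrid | None = None) -> RadialKSpace:
    """Sample the non-uniform Fourier transform of each frame's image
    along its spokes; add complex Gaussian noise of std ``noise_sigma``.

    ``engine='dft'`` uses exact direct summation (tiny grids only).
    Deterministic per seed.
    """
    if np.any(~np.isfinite(series.frames)):
        raise ValueError("NaN/inf in image series")
    if spokes.frame_label.max() >= series.n_frames:
        raise ValueError("spoke frame labels exceed series frames")
    protocol = series.protocol
    S = protocol.samples_per_spoke
    N = series.matrix
    samples = np.zeros((len(spokes), S), dtype=complex)
    if engine == "gridding":
        g = nufft or KaiserBesselGrid(N)
    elif engine != "dft":
        raise ValueError(f"unknown NUFFT engine {engine!r}")
    for f in range(series.n_frames):
        idx = spokes.frame_indices(f)
        if idx.size == 0:
            continue
        coords = spoke_sample_coords(spokes.directions[idx], S)
        if engine == "dft":
            vals = dft_forward(series.frames[f], coords)
        else:
            vals = g.forward(series.frames[f], g.plan(coords))
        samples[idx] = vals.reshape(idx.size, S)
    if noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                           spawn_key=(1,)))
        noise = rng.normal(0.0, noise_sigma, samples.shape) \
            + 1j * rng.normal(0.0, noise_sigma, samples.shape)
        samples = samples + noise
    return RadialKSpace(samples=samples, spokes=spokes, protocol=protocol,
                        noise_sigma=noise_sigma, seed=seed)


def snr_estimate(m0: float, noise_sigma: float, samples_per_spoke: int) -> float:
    """Report SNR as m0 / (noise_sigma * sqrt(samples_per_spoke))."""
    return np.inf if noise_sigma == 0 else \
        m0 / (noise_sigma * np.sqrt(samples_per_spoke))


def noise_sigma_for_snr(snr: float, m0: float, samples_per_spoke: int) -> float:
    """Inverse of :func:`snr_estimate`."""
    return 0.0 if np.isinf(snr) else m0 / (snr * np.sqrt(samples_per_spoke))
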