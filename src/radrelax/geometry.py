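"""Center-out 3D radial trajectory geometry and acquisition ordering.

The acquisition walks through spokes (center-out radial readouts) in a
3D golden-means spiral order, so that any contiguous prefix of spokes
covers the sphere quasi-uniformly — the property that makes
retrospective (prefix) under-sampling meaningful.  Saturation-recovery
(look-locker) acquisitions are binned into frames by position within
the curve; spin-lock acquisitions carry one TSL per frame.

Conventions: spoke directions are unit 3-vectors; k-space radius is
normalized to [0, 0.5) cycles/voxel; image grids use 0-based centered
voxel indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

# 3D golden means (the two quadratic irrationals driving the spiral
# ordering); any prefix of the sequence is low-discrepancy on the sphere.
_GOLDEN_MEAN_1 = 0.4656105955992359
_GOLDEN_MEAN_2 = 0.6823278038280193


@dataclass
class SequenceProtocol:
    """Timing and preparation description of one acquisition.

    mode 't1': a saturation pulse every ``spokes_per_curve`` spokes, the
    recovery sampled continuously and binned into ``n_frames`` images.
    mode 't1rho': preparation blocks with spin-lock duration
    ``tsl_list[frame]`` (ms) repeated every ``prep_period`` spokes.
    """

    mode: str = "t1"
    spoke_time: float = 3e-3          # tau, seconds per spoke
    flip_angle: float = 2.0           # degrees (2 phantom / 4 heart, 3 T1rho)
    fov: float = 50.0                 # mm, isotropic
    matrix: int = 32                  # voxels per side
    spokes_total: int = 65536
    spokes_per_curve: int = 1024      # T1 mode: spokes between saturations
    n_frames: int = 32
    tsl_list: tuple = ()              # ms, T1rho mode
    prep_period: int = 16             # spokes between prep blocks (T1rho)
    samples_per_spoke: int = 0        # 0 -> matrix/2 x 2 oversampling

    def __post_init__(self):
        if self.mode not in ("t1", "t1rho"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.samples_per_spoke == 0:
            self.samples_per_spoke = self.matrix  # matrix/2 * 2x oversampling
        if self.mode == "t1":
            if self.spokes_total % self.spokes_per_curve:
                raise ValueError(
                    f"spokes_total={self.spokes_total} not divisible by "
                    f"spokes_per_curve={self.spokes_per_curve}")
            if self.spokes_per_curve % self.n_frames:
                raise ValueError(
                    f"spokes_per_curve={self.spokes_per_curve} not divisible "
                    f"by n_frames={self.n_frames}")
        else:
            tsl = np.asarray(self.tsl_list, dtype=float)
            if tsl.size < 2 or tsl[0] != 0 or np.any(np.diff(tsl) <= 0):
                raise ValueError("tsl_list must start at 0 and be strictly increasing")
            self.tsl_list = tuple(float(v) for v in tsl)
            self.n_frames = len(self.tsl_list)

    @property
    def voxel_size_mm(self) -> float:
        return self.fov / self.matrix

    def to_dict(self) -> dict:
        return asdict(self)


def t1_protocol(matrix=32, spokes_total=65536, spokes_per_curve=1024,
                n_frames=32, flip_angle=2.0, **kw) -> SequenceProtocol:
    """Saturation-recovery look-locker protocol (defaults: tau=3 ms,
    saturation every 1024 spokes, first 65536 spokes -> 64 curves
    binned into 32 frames of 2048 spokes)."""
    return SequenceProtocol(mode="t1", matrix=matrix, spokes_total=spokes_total,
                            spokes_per_curve=spokes_per_curve, n_frames=n_frames,
                            flip_angle=flip_angle, **kw)


def t1rho_protocol(matrix=32, spokes_per_frame=4096, flip_angle=3.0,
                   tsl_list=(0, 4, 8, 12, 16, 20, 24, 28), prep_period=16,
                   **kw) -> SequenceProtocol:
    """Spin-lock prepared protocol: 8 TSL frames 0..28 ms, preparation
    repeated every 16 spokes."""
    n = len(tsl_list)
    return SequenceProtocol(mode="t1rho", matrix=matrix,
                            spokes_total=spokes_per_frame * n,
                            tsl_list=tuple(tsl_list), prep_period=prep_period,
                            flip_angle=flip_angle, n_frames=n, **kw)


@dataclass
class SpokeSet:
    """Spoke directions + acquisition order + frame labels + time tags.

    ``time_tag`` per spoke is seconds since the last saturation (T1
    mode) or the TSL in ms (T1rho mode).  ``frame_times`` holds the
    per-frame effective time (mean of member spokes).
    """

    directions: np.ndarray            # (n, 3) unit vectors
    order: np.ndarray                 # (n,) acquisition index
    frame_label: np.ndarray           # (n,) int
    time_tag: np.ndarray              # (n,) float
    n_frames: int
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self):
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("spoke directions must be unit vectors")
        if np.any(self.frame_label < 0) or np.any(self.frame_label >= self.n_frames):
            raise ValueError("frame labels out of range")
        if np.any(self.time_tag < 0):
            raise ValueError("time tags must be non-negative")
        if self.frame_times is None:
            self.frame_times = np.array([
                self.time_tag[self.frame_label == f].mean()
                for f in range(self.n_frames)])

    def __len__(self):
        return self.directions.shape[0]

    def frame_indices(self, f: int) -> np.ndarray:
        return np.nonzero(self.frame_label == f)[0]

    def frame_counts(self) -> np.ndarray:
        return np.bincount(self.frame_label, minlength=self.n_frames)

    def to_hdf5(self, group: h5py.Group) -> None:
        group.create_dataset("directions", data=self.directions)
        group.create_dataset("order", data=self.order)
        group.create_dataset("frame_label", data=self.frame_label)
        group.create_dataset("time_tag", data=self.time_tag)
        group.attrs["n_frames"] = self.n_frames

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "SpokeSet":
        return cls(directions=group["directions"][:], order=group["order"][:],
                   frame_label=group["frame_label"][:],
                   time_tag=group["time_tag"][:],
                   n_frames=int(group.attrs["n_frames"]))


def make_spoke_directions(n: int, scheme: str = "golden-angle-spiral",
                          seed: int = 0) -> np.ndarray:
    """Unit spoke directions, approximately uniform on the sphere.

    'golden-angle-spiral': 3D golden-means ordering — every contiguous
    prefix is quasi-uniform, which retrospective under-sampling relies
    on.  'archimedean': a single Archimedean spiral over the full
    sphere for exactly ``n`` spokes (uniform only as a whole).  The seed
    offsets the golden-means sequence start; output is deterministic in
    (n, scheme, seed).
    """
    if n <= 0:
        raise ValueError("need n >= 1 spokes")
    i = np.arange(n, dtype=float)
    if scheme == "golden-angle-spiral":
        i = i + (seed % 2**16) * 1.0
        z = 1.0 - 2.0 * np.mod(i * _GOLDEN_MEAN_1, 1.0)
        phi = 2.0 * np.pi * np.mod(i * _GOLDEN_MEAN_2, 1.0)
    elif scheme == "archimedean":
        z = 1.0 - (2.0 * i + 1.0) / n
        phi = np.mod(np.sqrt(np.pi * n) * np.arcsin(z), 2.0 * np.pi)
    else:
        raise ValueError(f"unknown spoke ordering scheme {scheme!r}")
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    d = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d


def bin_looklocker_frames(protocol: SequenceProtocol, spokes_used: int | None = None,
                          scheme: str = "golden-angle-spiral", seed: int = 0) -> SpokeSet:
    """Assign look-locker spokes to recovery frames.

    Spokes are grouped by position within the saturation-recovery curve:
    frame f collects within-curve positions
    ``[f*m, (f+1)*m)`` with ``m = spokes_per_curve / n_frames``, pooled
    across all curves.  With the default protocol (65536 spokes, 1024
    per curve, 32 frames) this yields 64 curves and 2048 spokes/frame.
    Each spoke's time tag is its mid-readout time since saturation; the
    frame time is the mean over member spokes.
    """
    if protocol.mode != "t1":
        raise ValueError("bin_looklocker_frames requires a T1-mode protocol")
    used = protocol.spokes_total if spokes_used is None else int(spokes_used)
    if used % protocol.spokes_per_curve:
        raise ValueError(
            f"spokes_used={used} is not a whole number of curves of "
            f"{protocol.spokes_per_curve} spokes")
    m, rem = divmod(protocol.spokes_per_curve, protocol.n_frames)
    if rem:
        raise ValueError(
            f"spokes_per_curve={protocol.spokes_per_curve} not divisible by "
            f"n_frames={protocol.n_frames}")
    directions = make_spoke_directions(used, scheme, seed)
    order = np.arange(used)
    pos_in_curve = order % protocol.spokes_per_curve
    frame_label = (pos_in_curve // m).astype(np.int64)
    time_tag = (pos_in_curve + 0.5) * protocol.spoke_time
    return SpokeSet(directions=directions, order=order, frame_label=frame_label,
                    time_tag=time_tag, n_frames=protocol.n_frames)


def make_t1rho_spokes(protocol: SequenceProtocol, spokes_per_frame: int | None = None,
                      scheme: str = "golden-angle-spiral", seed: int = 0) -> SpokeSet:
    """Spoke set for the spin-lock acquisition: one block of spokes per
    TSL frame, each frame's spokes drawn from the continuing golden-means
    sequence; time tag = frame TSL (ms)."""
    if protocol.mode != "t1rho":
        raise ValueError("make_t1rho_spokes requires a T1rho-mode protocol")
    spf = spokes_per_frame or protocol.spokes_total // protocol.n_frames
    n = spf * protocol.n_frames
    directions = make_spoke_directions(n, scheme, seed)
    order = np.arange(n)
    frame_label = (order // spf).astype(np.int64)
    time_tag = np.asarray(protocol.tsl_list, dtype=float)[frame_label]
    return SpokeSet(directions=directions, order=order, frame_label=frame_label,
                    time_tag=time_tag, n_frames=protocol.n_frames,
                    frame_times=np.asarray(protocol.tsl_list, dtype=float))


def undersample_t1rho(full: SpokeSet, keep: int, strategy: str = "prefix") -> SpokeSet:
    """Retain ``keep`` spokes per frame (retrospective under-sampling).

    'prefix' keeps the first ``keep`` acquired spokes of every frame
    (quasi-uniform under golden-means ordering); 'uniform-stride' keeps
    every (count//keep)-th spoke.  The achieved acceleration factor is
    logged.
    """
    import logging
    counts = full.frame_counts()
    if keep > counts.min():
        raise ValueError(f"keep={keep} exceeds available spokes/frame "
                         f"(min {counts.min()})")
    sel = []
    for f in range(full.n_frames):
        idx = full.frame_indices(f)
        idx = idx[np.argsort(full.order[idx])]
        if strategy == "prefix":
            sel.append(idx[:keep])
        elif strategy == "uniform-stride":
            stride = len(idx) // keep
            sel.append(idx[::stride][:keep])
        else:
            raise ValueError(f"unknown under-sampling strategy {strategy!r}")
    sel = np.concatenate(sel)
    accel = counts.sum() / sel.size
    logging.getLogger("radrelax").info(
        "retrospective under-sampling: kept %d of %d spokes (acceleration %.1fx)",
        sel.size, counts.sum(), accel)
    return SpokeSet(directions=full.directions[sel], order=full.order[sel],
                    frame_label=full.frame_label[sel], time_tag=full.time_tag[sel],
                    n_frames=full.n_frames, frame_times=full.frame_times)
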