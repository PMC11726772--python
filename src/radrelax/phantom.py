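"""Digital ground-truth phantoms for the relaxometry pipeline.

Two phantoms are provided:

* an MnCl2 dilution-series tube phantom — four cylinders whose
  relaxation rates are exactly linear in concentration,
  ``R = baseline_rate + r * c`` (r = relaxivity), so the downstream
  relaxivity fit has a known answer;
* a heart-like phantom — a left-ventricle-wall annulus with a septal
  bar, an anterior-wall fibrotic lesion and a septal inflammation
  region, carrying literature-typical relaxation values for control,
  remote, inflamed and fibrotic myocardium of the subacute-infarct
  mouse heart.

Ground-truth maps are exactly piecewise constant (per-compartment
variance 0); optional Gaussian jitter with per-tissue spread emulates
biological heterogeneity for ROI-statistics work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .signal_models import RelaxationParameters

#: Reference tissue relaxation values, mean and spread, for the four
#: myocardial compartments of the subacute-infarct mouse heart (3D
#: acquisition; T1 in s, T1rho/T2 in ms).  The inflammation T1 and the
#: fibrosis T2 are synthetic choices (not separately characterized in
#: the ex vivo literature values the others come from): inflammation T1
#: is placed between remote and fibrosis, fibrosis T2 near oedema.
TISSUE_TABLE_3D = {
    "control": {"t1": (0.68, 0.042), "t1rho": (30.0, 2.6), "t2": (31.0, 0.05)},
    "remote": {"t1": (1.4, 0.21), "t1rho": (31.0, 3.2), "t2": (31.0, 0.82)},
    "inflammation": {"t1": (1.65, 0.26), "t1rho": (50.0, 5.7), "t2": (61.0, 8.4)},
    "fibrosis": {"t1": (1.9, 0.31), "t1rho": (84.0, 12.0), "t2": (45.0, 6.0)},
}

#: 2D spin-lock reference means/spreads (ms) for the same compartments,
#: used for worked examples and group-comparison simulations.
TISSUE_TABLE_2D_T1RHO = {
    "control": (63.0, 0.05),
    "remote": (74.0, 5.2),
    "inflammation": (110.0, 4.5),
    "fibrosis": (153.0, 18.0),
}

#: 2D T2 reference means/spreads (ms); "inflammation" is the oedema ROI.
TISSUE_TABLE_2D_T2 = {
    "control": (31.0, 0.05),
    "remote": (31.0, 0.82),
    "inflammation": (61.0, 8.4),
}

COMPARTMENTS = ("control", "remote", "inflammation", "fibrosis")


@dataclass
class RelaxivityModel:
    """Linear rate model R(c) = baseline_rate + r * c (rates in 1/s)."""

    r: float
    baseline_rate: float

    def __post_init__(self):
        if self.r < 0:
            raise ValueError("relaxivity r must be >= 0")
        if not self.baseline_rate > 0:
            raise ValueError("baseline rate must be > 0")

    def time_constant(self, c: float) -> float:
        rate = self.baseline_rate + self.r * c
        if rate <= 0:
            raise ValueError(f"non-positive relaxation rate at c={c}")
        return 1.0 / rate


@dataclass
class PhantomDefinition:
    """Voxelized ground truth: label map + per-parameter maps.

    Maps: t1 (s), t1rho (ms), t2 (ms), m0 (a.u.); label 0 is
    zero-signal background.  Compartments are painted in definition
    order with later-wins overlap resolution.
    """

    matrix: int
    voxel_size_mm: float
    labels: dict            # name -> integer label
    label_map: np.ndarray   # (N, N, N) int
    maps: dict              # param name -> (N, N, N) float array
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.label_map > 0

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.label_map == self.labels[name]

    def jittered(self, seed: int, spreads: dict) -> "PhantomDefinition":
        """Per-voxel Gaussian jitter of parameter maps.

        ``spreads`` maps parameter name -> {compartment -> std}.  Values
        are clipped to stay positive.  Deterministic per seed.
        """
        rng = np.random.default_rng(seed)
        maps = {k: v.copy() for k, v in self.maps.items()}
        for param, per_tissue in spreads.items():
            for name, sd in per_tissue.items():
                m = self.compartment_mask(name)
                vals = maps[param][m] + rng.normal(0.0, sd, m.sum())
                maps[param][m] = np.clip(vals, 1e-6, None)
        return PhantomDefinition(self.matrix, self.voxel_size_mm, self.labels,
                                 self.label_map, maps, dict(self.meta))

    def to_nifti(self, path_prefix: str) -> list:
        """Write parameter maps (float NIfTI) and label map (int NIfTI)."""
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        written = []
        for name, arr in self.maps.items():
            img = nib.Nifti1Image(arr.astype(np.float32), affine)
            img.header["descrip"] = {"t1": b"T1 map [s]", "t1rho": b"T1rho map [ms]",
                                     "t2": b"T2 map [ms]"}.get(name, b"a.u.")
            p = f"{path_prefix}_{name}.nii"
            nib.save(img, p)
            written.append(p)
        p = f"{path_prefix}_labels.nii"
        nib.save(nib.Nifti1Image(self.label_map.astype(np.int16), affine), p)
        written.append(p)
        return written


def _grid(matrix):
    c = (matrix - 1) / 2.0
    ax = np.arange(matrix) - c
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _paint(label_map, maps, mask, label, params: RelaxationParameters):
    label_map[mask] = label
    maps["t1"][mask] = params.t1
    maps["t1rho"][mask] = params.t1rho
    maps["t2"][mask] = params.t2
    maps["m0"][mask] = params.m0


def _empty_maps(matrix):
    shape = (matrix,) * 3
    return (np.zeros(shape, dtype=np.int16),
            {k: np.zeros(shape) for k in ("t1", "t1rho", "t2", "m0")})


def build_mncl2_phantom(concentrations=(100.0, 300.0, 500.0, 900.0),
                        relaxivity_t1: RelaxivityModel | None = None,
                        relaxivity_t1rho: RelaxivityModel | None = None,
                        matrix: int = 32, voxel_size_mm: float = 1.0,
                        concentration_unit: str = "uM-scale") -> PhantomDefinition:
    """Four-tube MnCl2 dilution phantom.

    Concentrations are taken as numeric values with an explicit unit
    string (the dilution series is quoted as 0.01–0.09 mM in one place
    and 0.1–0.9 mM in another in the source measurements; the default
    relaxivities are only unit-consistent with a µM-scale axis, so the
    axis is left explicitly unit-tagged rather than guessed).

    Default relaxivities reproduce spin-lock tube values near
    420/320/280/230 ms over the default series.  T2 tubes follow the T1rho
    model scaled; m0 = 1 inside tubes.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size < 1 or np.any(conc <= 0) or np.unique(conc).size != conc.size:
        raise ValueError("concentrations must be positive and distinct")
    if relaxivity_t1 is None:
        relaxivity_t1 = RelaxivityModel(r=0.00024, baseline_rate=1.0 / 2.45)
    if relaxivity_t1rho is None:
        relaxivity_t1rho = RelaxivityModel(r=0.0025, baseline_rate=1.0 / 0.462)

    label_map, maps = _empty_maps(matrix)
    X, Y, Z = _grid(matrix)
    R = matrix / 2.0
    tube_r = 0.16 * matrix
    centers = [(-0.45 * R, -0.45 * R), (0.45 * R, -0.45 * R),
               (-0.45 * R, 0.45 * R), (0.45 * R, 0.45 * R)]
    labels = {}
    for i, c in enumerate(conc):
        cx, cy = centers[i % 4]
        mask = ((X - cx) ** 2 + (Y - cy) ** 2 <= tube_r ** 2) & (np.abs(Z) <= 0.35 * matrix)
        t1 = relaxivity_t1.time_constant(c)                 # s
        t1rho = 1e3 * relaxivity_t1rho.time_constant(c)     # ms
        params = RelaxationParameters(t1=t1, t1rho=t1rho, t2=0.5 * t1rho, m0=1.0)
        _paint(label_map, maps, mask, i + 1, params)
        labels[f"tube{i + 1}"] = i + 1
    return PhantomDefinition(matrix, voxel_size_mm, labels, label_map, maps,
                             meta={"concentrations": conc.tolist(),
                                   "concentration_unit": concentration_unit,
                                   "relaxivity_t1": vars(relaxivity_t1),
                                   "relaxivity_t1rho": vars(relaxivity_t1rho)})


def default_heart_tissue_table() -> dict:
    """RelaxationParameters per compartment from the 3D reference means."""
    table = {}
    for name, v in TISSUE_TABLE_3D.items():
        table[name] = RelaxationParameters(t1=v["t1"][0], t1rho=v["t1rho"][0],
                                           t2=v["t2"][0], m0=1.0)
    return table


def build_heart_phantom(matrix: int = 32, voxel_size_mm: float = 0.78,
                        tissue_table: dict | None = None) -> PhantomDefinition:
    """Heart-like phantom: LV-wall annulus + septal bar + lesions.

    The geometry is stylized (the thin annulus and small lesions stress
    block-wise low-rank blurring): an annular "LV wall" of remote
    tissue, a septal bar carrying inflammation, a fibrotic lesion in
    the anterior wall, and a separate small control cylinder.  The
    tissue table must cover control/remote/inflammation/fibrosis.
    """
    table = tissue_table or default_heart_tissue_table()
    missing = [c for c in COMPARTMENTS if c not in table]
    if missing:
        raise ValueError(f"tissue table missing compartments: {missing}")
    label_map, maps = _empty_maps(matrix)
    X, Y, Z = _grid(matrix)
    R = matrix / 2.0
    rad = np.hypot(X, Y)
    zmask = np.abs(Z) <= 0.38 * matrix

    annulus = (rad >= 0.32 * R) & (rad <= 0.62 * R) & zmask          # LV wall
    septum = (np.abs(X) <= 0.14 * R) & (np.abs(Y) <= 0.62 * R) & \
        (rad < 0.62 * R) & zmask                                     # septal bar
    lesion = annulus & (Y > 0.3 * R) & (np.abs(X) < 0.5 * R)         # anterior wall
    control = ((X - 0.78 * R) ** 2 + Y ** 2 <= (0.16 * R) ** 2) & zmask

    labels = {"control": 1, "remote": 2, "inflammation": 3, "fibrosis": 4}
    _paint(label_map, maps, control, labels["control"], table["control"])
    _paint(label_map, maps, annulus, labels["remote"], table["remote"])
    _paint(label_map, maps, septum, labels["inflammation"], table["inflammation"])
    _paint(label_map, maps, lesion, labels["fibrosis"], table["fibrosis"])
    return PhantomDefinition(matrix, voxel_size_mm, labels, label_map, maps,
                             meta={"kind": "heart"})


def heart_jitter_spreads() -> dict:
    """Per-compartment parameter spreads from the 3D reference table."""
    return {
        "t1": {n: TISSUE_TABLE_3D[n]["t1"][1] for n in COMPARTMENTS},
        "t1rho": {n: TISSUE_TABLE_3D[n]["t1rho"][1] for n in COMPARTMENTS},
        "t2": {n: TISSUE_TABLE_3D[n]["t2"][1] for n in COMPARTMENTS},
    }
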