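"""ROI statistics, the relative relaxation time difference (RRTD),
phantom relaxivity fits, and group comparisons.

RRTD between a damaged and a remote region of a relaxation map is

    RRTD = (mean(T_damage) - mean(T_remote)) / mean(T_remote),

a dimensionless contrast measure (> -1 for positive-valued maps, 0 for
identical regions, scale-invariant).  Relaxivity is the slope of the
relaxation rate R = 1/T against contrast-agent concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import RelaxationMap

logger = logging.getLogger("radrelax")


@dataclass
class RoiSet:
    """Named voxel-index sets over one grid (labels unique)."""

    labels: dict          # name -> integer label
    label_map: np.ndarray

    def __post_init__(self):
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("ROI labels must be unique")

    def mask(self, name: str) -> np.ndarray:
        return self.label_map == self.labels[name]

    @classmethod
    def from_phantom(cls, phantom) -> "RoiSet":
        return cls(labels=dict(phantom.labels), label_map=phantom.label_map)


@dataclass
class RRTDReport:
    contrast: str
    comparison: tuple
    value: float

    def rounded(self, sig: int = 2) -> float:
        """Value to ``sig`` significant figures (table style)."""
        if self.value == 0 or not np.isfinite(self.value):
            return self.value
        exp = int(np.floor(np.log10(abs(self.value))))
        return round(self.value, sig - 1 - exp)


@dataclass
class RelaxivityFit:
    slope: float          # relaxivity r, rate per concentration unit
    intercept: float      # baseline rate, 1/s
    r_squared: float

    def __post_init__(self):
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


def roi_stats(relax_map: RelaxationMap, rois: RoiSet) -> pd.DataFrame:
    """Per-label mean/std/n over finite voxels; NaN rows for empty ROIs."""
    if rois.label_map.shape != relax_map.values.shape:
        raise ValueError("ROI grid does not match map grid")
    rows = []
    for name in rois.labels:
        v = relax_map.values[rois.mask(name)]
        finite = v[np.isfinite(v)]
        excluded = v.size - finite.size
        if finite.size == 0:
            logger.warning("ROI %s empty after NaN exclusion", name)
            rows.append((name, np.nan, np.nan, 0, excluded))
        else:
            rows.append((name, float(finite.mean()),
                         float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
                         int(finite.size), excluded))
    return pd.DataFrame(rows, columns=["label", "mean", "std", "n", "n_excluded"])


def rrtd(mean_damage: float, mean_remote: float, contrast: str = "",
         comparison: tuple = ("damage", "remote")) -> RRTDReport:
    """Relative relaxation time difference between two ROI means."""
    if not mean_remote > 0:
        raise ValueError("remote mean must be > 0")
    value = (mean_damage - mean_remote) / mean_remote
    return RRTDReport(contrast=contrast, comparison=comparison, value=float(value))


def rrtd_table(stats_by_contrast: dict, comparisons) -> pd.DataFrame:
    """RRTD for several (damage, remote) pairs across contrasts.

    ``stats_by_contrast``: contrast name -> {label: mean}; rows carry
    full precision plus the 2-significant-figure table value.
    """
    rows = []
    for contrast, means in stats_by_contrast.items():
        for a, b in comparisons:
            if a in means and b in means and np.isfinite(means[a]) \
                    and np.isfinite(means[b]):
                rep = rrtd(means[a], means[b], contrast, (a, b))
                rows.append((contrast, a, b, rep.value, rep.rounded()))
    return pd.DataFrame(rows, columns=["contrast", "region_a", "region_b",
                                       "rrtd", "rrtd_2sf"])


def relaxivity_fit(concentrations, time_constants_s) -> RelaxivityFit:
    """OLS fit of relaxation rate 1/T (1/s) vs concentration.

    The slope is the relaxivity r; time constants in seconds.
    """
    c = np.asarray(concentrations, dtype=float)
    T = np.asarray(time_constants_s, dtype=float)
    if c.size < 2 or c.size != T.size:
        raise ValueError("need >= 2 matched (concentration, T) points")
    if np.unique(c).size < 2:
        raise ValueError("degenerate concentrations")
    if np.any(T <= 0):
        raise ValueError("time constants must be positive")
    res = stats.linregress(c, 1.0 / T)
    return RelaxivityFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def group_compare(values_a, values_b, n_comparisons: int = 1,
                  equal_var: bool = True):
    """Two-sample t-test with Bonferroni correction.

    Returns ``(t, p_adjusted)`` with p multiplied by ``n_comparisons``
    and capped at 1.  Unpaired equal-variance by default (``equal_var``
    switches to Welch).  Identical zero-variance groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(min(1.0, p * n_comparisons))
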