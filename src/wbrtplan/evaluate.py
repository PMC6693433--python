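"""Plan evaluation: DVHs, dosimetric endpoints and the paired statistical
comparison protocol (one-sided Wilcoxon signed-rank, Bonferroni-corrected
family of eight endpoints).

Conventions, stated once so voxel counts are bit-stable: VX thresholds use a
closed lower bound (dose >= X), voxel volumes are voxel_size^3 with no
partial-volume interpolation, zero paired differences are dropped (classical
Wilcoxon convention) and ties receive mid-ranks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

#: the eight endpoints of the comparison family, with the one-sided
#: alternative "the auto-plan is worse": 'less' for coverage metrics
#: (auto < clinical), 'greater' for dose/hot-spot metrics (auto > clinical)
ENDPOINTS = (
    ("target_v100_pct", "less"),
    ("target_v105_pct", "greater"),
    ("v105_cc", "greater"),
    ("lung_v10gy_pct", "greater"),
    ("lung_v20gy_pct", "greater"),
    ("lung_v95_pct", "greater"),
    ("heart_mean_pct", "greater"),
    ("plan_max_pct", "greater"),
)


@dataclass
class PlanMetrics:
    target_v90_pct: float
    target_v95_pct: float
    target_v100_pct: float
    target_v105_pct: float
    v105_cc: float            # absolute hot-spot volume over the whole grid
    lung_v10gy_pct: float
    lung_v20gy_pct: float
    lung_v95_pct: float
    heart_mean_pct: float     # mean heart dose as % of prescription
    plan_max_pct: float       # maximum voxel dose as % of prescription

    def __post_init__(self):
        nested = (self.target_v90_pct >= self.target_v95_pct
                  >= self.target_v100_pct >= self.target_v105_pct)
        if not nested:
            raise ValueError("V-metrics must be nested (V90>=V95>=V100>=V105)")

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def dvh(dose_grid, mask: np.ndarray, bin_width: float = 10.0) -> pd.DataFrame:
    """Cumulative DVH: columns (dose_cgy, volume_pct); monotone
    non-increasing, 100% at zero dose."""
    dose = dose_grid.dose if hasattr(dose_grid, "dose") else np.asarray(dose_grid)
    if not mask.any():
        raise ValueError("empty structure mask")
    vals = dose[mask]
    edges = np.arange(0.0, vals.max() + 2 * bin_width, bin_width)
    volume = [100.0 * np.mean(vals >= d) for d in edges]
    return pd.DataFrame({"dose_cgy": edges, "volume_pct": volume})


def plan_metrics(dose_grid, phantom, rx: float) -> PlanMetrics:
    """The Table-1-style endpoint set for one plan (prescription in cGy)."""
    if rx <= 0:
        raise ValueError("prescription must be positive")
    for name in ("breast_target", "ipsilateral_lung", "heart"):
        if name not in phantom.masks:
            raise ValueError(f"missing structure mask {name!r}")
    dose = dose_grid.dose
    target = dose[phantom.masks["breast_target"]]
    lung_mask = phantom.masks["ipsilateral_lung"]
    lung = dose[lung_mask] if lung_mask.any() else np.zeros(1)
    heart_mask = phantom.masks["heart"]
    heart = dose[heart_mask] if heart_mask.any() else np.zeros(1)

    def vpct(vals, frac):
        return 100.0 * float(np.mean(vals >= frac * rx))

    voxel_cc = (phantom.voxel_size / 10.0) ** 3
    return PlanMetrics(
        target_v90_pct=vpct(target, 0.90),
        target_v95_pct=vpct(target, 0.95),
        target_v100_pct=vpct(target, 1.00),
        target_v105_pct=vpct(target, 1.05),
        v105_cc=float((dose >= 1.05 * rx).sum()) * voxel_cc,
        lung_v10gy_pct=100.0 * float(np.mean(lung >= 1000.0)),
        lung_v20gy_pct=100.0 * float(np.mean(lung >= 2000.0)),
        lung_v95_pct=vpct(lung, 0.95),
        heart_mean_pct=100.0 * float(heart.mean()) / rx,
        plan_max_pct=100.0 * float(dose.max()) / rx,
    )


# --------------------------------------------------------------------------
# one-sided Wilcoxon signed-rank test
# --------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _wplus_distribution(double_ranks: tuple[int, ...]) -> np.ndarray:
    """Exact null distribution of 2*W+ by polynomial convolution over sign
    assignments.  Ranks are passed doubled so mid-ranks stay integral."""
    n_max = sum(double_ranks)
    counts = np.zeros(n_max + 1)
    counts[0] = 1.0
    for r in double_ranks:
        counts[r:] += counts[:n_max + 1 - r].copy()
    return counts / counts.sum()


def wilcoxon_signed_rank_one_sided(a, b, alternative: str = "greater"
                                   ) -> tuple[float, float]:
    """Exact (n <= 25) or tie-corrected normal one-sided signed-rank test.

    Tests H1: the paired differences a - b tend to be positive
    (``alternative='greater'``) or negative (``'less'``).  Zeros are dropped;
    ties get mid-ranks.  Returns (W+, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; degenerate test",
                      stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 25:
        dist = _wplus_distribution(
            tuple(sorted(int(round(2 * r)) for r in ranks)))
        w2 = int(round(2 * w_plus))
        if alternative == "greater":
            p = float(dist[w2:].sum())
        else:
            p = float(dist[:w2 + 1].sum())
    else:
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(float((ranks ** 2).sum()) / 4.0)  # mid-ranks absorb ties
        z = (w_plus - mean) / sd
        p = float(stats.norm.sf(z) if alternative == "greater"
                  else stats.norm.cdf(z))
    return w_plus, min(p, 1.0)


# --------------------------------------------------------------------------
# cohort comparison
# --------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    table: pd.DataFrame           # one row per endpoint
    alpha: float
    m: int

    @property
    def adjusted_threshold(self) -> float:
        return self.alpha / self.m

    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def compare_cohorts(metrics_auto, metrics_clinical, alpha: float = 0.05,
                    m: int = len(ENDPOINTS)) -> ComparisonReport:
    """Paired endpoint-wise comparison of auto vs clinical plan cohorts.

    ``metrics_*`` are equal-length, same-order lists of :class:`PlanMetrics`.
    The family-wise level ``alpha`` is Bonferroni-split over the ``m``
    endpoints (0.05/8 = 0.00625, conventionally printed as 0.006).
    """
    if len(metrics_auto) != len(metrics_clinical):
        raise ValueError("cohorts must be paired (equal length, same order)")
    rows = {}
    thresh = alpha / m
    for name, alternative in ENDPOINTS:
        va = np.array([mm.as_dict()[name] for mm in metrics_auto])
        vc = np.array([mm.as_dict()[name] for mm in metrics_clinical])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = wilcoxon_signed_rank_one_sided(va, vc, alternative)
        rows[name] = {
            "auto_mean": va.mean(), "auto_sd": va.std(ddof=1) if len(va) > 1 else 0.0,
            "clinical_mean": vc.mean(),
            "clinical_sd": vc.std(ddof=1) if len(vc) > 1 else 0.0,
            "alternative": alternative, "W": w, "p": p,
            "significant": p < thresh,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return ComparisonReport(table=table, alpha=alpha, m=m)
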