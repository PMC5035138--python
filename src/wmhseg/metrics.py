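"""Overlap, cluster-level and volumetric agreement metrics.

Overlap between an automated mask A and a manual mask M is summarised by
the Dice similarity index SI = 2|A∩M| / (|A|+|M|), voxel-level false
positive/negative ratios, cluster-level FPR/FNR, and the detection and
outline error rates:

- DER: volume of clusters present in only one of the two masks, divided
  by the mean total volume (|A|+|M|)/2;
- OER: non-overlapping volume inside matched cluster groups, divided by
  the same mean total volume.

These definitions satisfy DER + OER = 2(1 − SI) identically. Volumetric
agreement across subjects uses the intraclass correlation coefficient
(two-way model, absolute agreement, single measures), lesion volume as a
percentage of intracranial volume (WMHr, log-transformed for skew), and
Spearman rank correlations against visual ratings. Scan-rescan
reproducibility is summarised by per-pair percentage error and
Bland-Altman limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .volumes import BinaryMask, Volume

__all__ = [
    "ClusterSet",
    "OverlapReport",
    "VolumetricReport",
    "connected_components",
    "overlap_metrics",
    "icc_absolute_agreement",
    "wmh_ratio",
    "log_wmhr",
    "spearman_rho",
    "reproducibility_stats",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterSet:
    """Connected components of a binary mask."""

    label_map: np.ndarray
    sizes: np.ndarray            # per-label voxel counts, label i -> sizes[i-1]
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


@dataclass
class OverlapReport:
    si: float
    voxel_fpr: float
    voxel_fnr: float
    cluster_fpr: float
    cluster_fnr: float
    der: float
    oer: float
    mean_total_area_voxels: float
    mean_total_area_mm3: float
    tp_voxels: int
    fp_voxels: int
    fn_voxels: int
    n_auto_clusters: int
    n_manual_clusters: int
    fp_clusters: int
    fn_clusters: int

    def as_dict(self) -> Dict[str, float]:
        return dict(self.__dict__)


@dataclass
class VolumetricReport:
    icc: float
    spearman_rho: Dict[str, float] = field(default_factory=dict)
    wmhr: Optional[np.ndarray] = None
    log_wmhr: Optional[np.ndarray] = None


def connected_components(mask: BinaryMask, connectivity: int = 26) -> ClusterSet:
    """Label connected components at 6/18/26 (3-D) connectivity."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    lab, n = ndimage.label(mask.data.astype(bool), structure=_STRUCTURES[connectivity])
    sizes = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    return ClusterSet(label_map=lab, sizes=sizes, connectivity=connectivity)


def overlap_metrics(
    auto: BinaryMask, manual: BinaryMask, connectivity: int = 26
) -> OverlapReport:
    """All voxel- and cluster-level overlap metrics of one mask pair.

    Cluster semantics: an automated cluster touching the manual mask by at
    least one voxel is a true-positive cluster, otherwise false positive;
    a manual cluster touching no automated voxel is false negative. DER
    pools the volume of FP and FN clusters; OER pools, over groups of
    mutually overlapping TP clusters, the non-overlapping volume
    (|auto part| + |manual part| − 2·|overlap|). Both are divided by the
    mean total volume of the two masks. The empty-vs-empty comparison is
    defined as perfect agreement (SI = 1, all error rates 0); 0/0 ratios
    elsewhere are reported as 0.
    """
    if auto.shape != manual.shape:
        raise ValueError("masks must share a grid")
    a = auto.data.astype(bool)
    m = manual.data.astype(bool)
    n_a, n_m = int(a.sum()), int(m.sum())
    tp = int((a & m).sum())
    fp, fn = n_a - tp, n_m - tp
    mta_vox = (n_a + n_m) / 2.0
    mta_mm3 = mta_vox * auto.voxel_volume_mm3
    if n_a == 0 and n_m == 0:
        return OverlapReport(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                             0, 0, 0, 0, 0, 0, 0)
    si = 2.0 * tp / (n_a + n_m)
    voxel_fpr = fp / n_a if n_a else 0.0
    voxel_fnr = fn / n_m if n_m else 0.0

    ca = connected_components(auto, connectivity)
    cm = connected_components(manual, connectivity)
    # cluster overlap table: which auto label touches which manual label
    both = a & m
    auto_hit = np.zeros(ca.n_clusters + 1, dtype=bool)
    man_hit = np.zeros(cm.n_clusters + 1, dtype=bool)
    auto_hit[np.unique(ca.label_map[both])] = True
    man_hit[np.unique(cm.label_map[both])] = True
    fp_clusters = int((~auto_hit[1:]).sum())
    fn_clusters = int((~man_hit[1:]).sum())
    cluster_fpr = fp_clusters / ca.n_clusters if ca.n_clusters else 0.0
    cluster_fnr = fn_clusters / cm.n_clusters if cm.n_clusters else 0.0

    detection_error = int(ca.sizes[~auto_hit[1:]].sum() + cm.sizes[~man_hit[1:]].sum())
    # outline error over matched clusters: total volume of TP clusters on
    # both sides minus twice their mutual overlap (union-graph grouping is
    # implicit: every TP-cluster voxel is counted once on its own side)
    tp_auto_vol = int(ca.sizes[auto_hit[1:]].sum())
    tp_man_vol = int(cm.sizes[man_hit[1:]].sum())
    outline_error = tp_auto_vol + tp_man_vol - 2 * tp
    der = detection_error / mta_vox
    oer = outline_error / mta_vox
    return OverlapReport(
        si=si, voxel_fpr=voxel_fpr, voxel_fnr=voxel_fnr,
        cluster_fpr=cluster_fpr, cluster_fnr=cluster_fnr,
        der=der, oer=oer,
        mean_total_area_voxels=mta_vox, mean_total_area_mm3=mta_mm3,
        tp_voxels=tp, fp_voxels=fp, fn_voxels=fn,
        n_auto_clusters=ca.n_clusters, n_manual_clusters=cm.n_clusters,
        fp_clusters=fp_clusters, fn_clusters=fn_clusters,
    )


def icc_absolute_agreement(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Single-measure, absolute-agreement, two-way model ICC for 2 raters.

    Computed from the two-way ANOVA decomposition:
    ICC = (MSR − MSE) / (MSR + MSE + (2/n)(MSC − MSE)), where MSR, MSC and
    MSE are the rows (subjects), columns (raters) and error mean squares.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValueError("two equal-length 1-D measurement vectors required")
    n = len(v1)
    if n < 3:
        raise ValueError("at least 3 paired measurements are required")
    data = np.column_stack([v1, v2])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise ValueError("ICC undefined: zero between-subject variance")
    return float((msr - mse) / denom)


def wmh_ratio(lesion_volume_mm3: float, icv_mm3: float) -> float:
    """Lesion volume as a percentage of intracranial volume."""
    if icv_mm3 <= 0:
        raise ValueError("intracranial volume must be positive")
    return 100.0 * lesion_volume_mm3 / icv_mm3


def log_wmhr(wmhr: float, epsilon: float = 0.0) -> float:
    """Natural log of (WMHr + epsilon); epsilon keeps lesion-free subjects finite."""
    if wmhr < 0:
        raise ValueError("WMHr cannot be negative")
    return float(np.log(wmhr + epsilon))


def cohort_log_wmhr(wmhr: Sequence[float]) -> np.ndarray:
    """log WMHr with epsilon = half the smallest nonzero cohort value."""
    wmhr = np.asarray(wmhr, dtype=float)
    nonzero = wmhr[wmhr > 0]
    eps = nonzero.min() / 2 if len(nonzero) else 1.0
    return np.array([log_wmhr(w, eps if w == 0 else 0.0) for w in wmhr])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("two equal-length vectors of length >= 3 required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def reproducibility_stats(v1: Sequence[float], v2: Sequence[float]) -> Dict[str, float]:
    """Scan-rescan agreement summary for paired volume estimates.

    Returns per-pair percentage error (100·|v1−v2| / pair mean) summarised
    as mean ± sd, Bland-Altman mean difference and 95% limits of agreement
    (mean ± 1.96 sd of the differences), plus the Spearman correlation and
    absolute-agreement ICC of the pairs. Pairs with zero mean are excluded
    from the percentage error with a warning.
    """
    import warnings

    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("paired vectors required")
    means = (v1 + v2) / 2.0
    ok = means != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} pair(s) with zero mean excluded "
                      "from percentage error")
    pe = 100.0 * np.abs(v1[ok] - v2[ok]) / means[ok]
    diff = v1 - v2
    sd_diff = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
    return {
        "percentage_error_mean": float(pe.mean()) if len(pe) else float("nan"),
        "percentage_error_sd": float(np.std(pe, ddof=1)) if len(pe) > 1 else 0.0,
        "bland_altman_mean_diff": float(diff.mean()),
        "bland_altman_lower": float(diff.mean() - 1.96 * sd_diff),
        "bland_altman_upper": float(diff.mean() + 1.96 * sd_diff),
        "spearman_rho": spearman_rho(v1, v2),
        "icc": icc_absolute_agreement(v1, v2),
    }
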