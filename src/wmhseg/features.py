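"""Per-voxel feature construction.

Each in-brain voxel is described by a feature vector holding, in order:
the variance-scaled intensity of every modality, optional local patch
means (one column per modality per kernel size D), and optional MNI
coordinates that are variance-normalised and multiplied by the spatial
weight ``sw``. A higher ``sw`` makes the nearest-neighbour search
increasingly local in anatomical space; ``sw = 0`` drops the coordinate
columns entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter

from .volumes import BinaryMask, SubjectRecord, Volume, voxel_to_mni

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "variance_normalize",
    "patch_average",
    "spatial_features",
    "build_feature_matrix",
]


@dataclass
class FeatureSpec:
    """Which features to extract.

    Parameters
    ----------
    modality_names : ordered list of modality names (FLAIR first).
    patch_sizes : kernel side lengths D in voxels (each >= 2); empty for none.
    patch_dim : 2 for in-plane (axial) kernels, 3 for cubic kernels.
    spatial_weight : sw >= 0; 0 disables spatial features, 1 leaves the
        variance-normalised MNI coordinates unscaled.
    center : subtract the in-mask mean before variance scaling (off by
        default: plain variance scaling divides by the standard deviation
        only).
    """

    modality_names: Sequence[str] = ("flair",)
    patch_sizes: Sequence[int] = ()
    patch_dim: int = 3
    spatial_weight: float = 1.0
    center: bool = False

    def __post_init__(self) -> None:
        if any(D < 2 for D in self.patch_sizes):
            raise ValueError("every patch size D must be >= 2")
        if self.patch_dim not in (2, 3):
            raise ValueError("patch_dim must be 2 or 3")
        if self.spatial_weight < 0:
            raise ValueError("spatial_weight must be >= 0")

    @property
    def use_spatial(self) -> bool:
        return self.spatial_weight > 0

    def feature_names(self) -> List[str]:
        names = [f"int_{m}" for m in self.modality_names]
        for D in self.patch_sizes:
            for m in self.modality_names:
                names.append(f"patch{D}_{self.patch_dim}d_{m}")
        if self.use_spatial:
            names += ["mni_x", "mni_y", "mni_z"]
        return names


@dataclass
class FeatureMatrix:
    """Feature rows with voxel back-pointers and optional labels."""

    rows: np.ndarray                      # (n_voxels, n_features)
    voxel_index: np.ndarray               # (n_voxels, 3) int
    feature_names: List[str]
    labels: Optional[np.ndarray] = None   # (n_voxels,) in {0, 1}; 1 = WMH
    normalization_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.feature_names):
            raise ValueError("row width must equal number of feature names")
        if len(self.voxel_index) != len(self.rows):
            raise ValueError("one voxel index per row required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.rows):
                raise ValueError("labels must cover every row")

    def __len__(self) -> int:
        return len(self.rows)

    def take(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(
            rows=self.rows[idx],
            voxel_index=self.voxel_index[idx],
            feature_names=list(self.feature_names),
            labels=None if self.labels is None else self.labels[idx],
            normalization_stats=dict(self.normalization_stats),
        )


def _sample_sd(values: np.ndarray) -> float:
    # sample (n-1) standard deviation; the in-mask variance after scaling
    # is then exactly 1 under the same convention
    return float(np.std(values, ddof=1))


def variance_normalize(v: Volume, brain: BinaryMask, center: bool = False) -> Volume:
    """Scale in-mask intensities to unit variance.

    Divides by the in-mask standard deviation (optionally subtracting the
    in-mask mean first when ``center``); out-of-mask voxels are set to 0.
    A constant in-mask image is degenerate and raises ``ValueError``.
    """
    m = brain.data.astype(bool)
    if m.sum() < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    vals = v.data[m].astype(np.float64)
    sd = _sample_sd(vals)
    if sd <= 0:
        raise ValueError("degenerate image: zero in-mask variance")
    out = np.zeros(v.shape, dtype=np.float64)
    out[m] = (vals - np.mean(vals)) / sd if center else vals / sd
    return v.with_data(out)


def patch_average(v: Volume, brain: BinaryMask, D: int, dim: int = 3) -> Volume:
    """Local mean intensity over a D-sided kernel, restricted to the brain.

    Each in-mask voxel receives the mean of the in-mask voxels inside the
    D^dim kernel centred on it; voxels outside the kernel or outside the
    brain never contribute (the standard edge rule at the brain boundary).
    2-D kernels average within the axial (i, j) plane. For even D the
    kernel spans floor((D-1)/2) voxels before and ceil((D-1)/2) after the
    centre on each axis.
    """
    if D < 2:
        raise ValueError("patch size D must be >= 2")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    m = brain.data.astype(np.float64)
    size = (D, D, D) if dim == 3 else (D, D, 1)
    # anchor even kernels floor((D-1)/2) voxels before / ceil((D-1)/2)
    # after the centre: scipy's default puts the extra voxel before, so
    # shift the window by padding one trailing zero plane per even axis
    shift = tuple(1 if s % 2 == 0 and s > 1 else 0 for s in size)

    def _filt(arr):
        if any(shift):
            arr = np.pad(arr, [(0, sh) for sh in shift], mode="constant")
        out = uniform_filter(arr, size=size, mode="constant")
        if any(shift):
            out = out[tuple(slice(sh, None) for sh in shift)]
        return out

    num = _filt(v.data.astype(np.float64) * m)
    den = _filt(m)
    out = np.zeros(v.shape, dtype=np.float64)
    inside = m.astype(bool)
    out[inside] = num[inside] / den[inside]
    return v.with_data(out)


def spatial_features(subject: SubjectRecord, sw: float) -> Optional[np.ndarray]:
    """sw-scaled, variance-normalised MNI coordinates of in-brain voxels.

    Returns an (n_in_mask, 3) array in the scan order of the brain mask,
    or ``None`` when ``sw == 0`` (coordinates ignored). Each axis is
    divided by its in-mask standard deviation, then multiplied by ``sw``,
    so at sw=1 every coordinate column has unit in-mask variance.
    """
    if sw < 0:
        raise ValueError("sw must be >= 0")
    if sw == 0:
        return None
    ijk = np.argwhere(subject.brain_mask.data > 0)
    mni = np.atleast_2d(voxel_to_mni(ijk, subject))
    sd = mni.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("degenerate spatial axis: zero coordinate variance")
    return mni / sd * sw


def build_feature_matrix(subject: SubjectRecord, spec: FeatureSpec) -> FeatureMatrix:
    """One feature row per in-brain voxel, per the feature specification.

    Column order: modality intensities, then patch means (per D, per
    modality), then spatial coordinates. All intensity-derived columns are
    variance-scaled using the subject's own brain mask; the scale factors
    are recorded in ``normalization_stats``.
    """
    for name in spec.modality_names:
        if name not in subject.modalities:
            raise ValueError(
                f"subject {subject.subject_id!r} lacks modality {name!r}"
            )
    brain = subject.brain_mask
    inside = brain.data.astype(bool)
    ijk = np.argwhere(inside)
    n = len(ijk)
    cols, stats = [], {}
    if n > 0:
        for name in spec.modality_names:
            vol = subject.modalities[name]
            vals = vol.data[inside].astype(np.float64)
            sd = _sample_sd(vals)
            if sd <= 0:
                raise ValueError(f"degenerate modality {name!r}: zero variance")
            stats[f"int_{name}"] = sd
            col = (vals - np.mean(vals)) / sd if spec.center else vals / sd
            cols.append(col)
        for D in spec.patch_sizes:
            for name in spec.modality_names:
                pa = patch_average(subject.modalities[name], brain, D, spec.patch_dim)
                vals = pa.data[inside]
                sd = _sample_sd(vals)
                if sd <= 0:
                    raise ValueError(
                        f"degenerate patch column D={D} for modality {name!r}"
                    )
                stats[f"patch{D}_{spec.patch_dim}d_{name}"] = sd
                col = (vals - np.mean(vals)) / sd if spec.center else vals / sd
                cols.append(col)
        coords = spatial_features(subject, spec.spatial_weight)
        if coords is not None:
            for ax, axis_name in enumerate(("mni_x", "mni_y", "mni_z")):
                stats[axis_name] = spec.spatial_weight
                cols.append(coords[:, ax])
        rows = np.column_stack(cols)
    else:
        rows = np.empty((0, len(spec.feature_names())))
    return FeatureMatrix(
        rows=rows,
        voxel_index=ijk,
        feature_names=spec.feature_names(),
        normalization_stats=stats,
    )
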