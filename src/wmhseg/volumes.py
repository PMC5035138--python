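"""Volumes, masks and subject records.

All images for one subject live on a single voxel grid (the subject's
reference space); world coordinates follow the NIfTI affine convention
(0-based voxel indices, millimetres). Transforms between spaces are
FLIRT-style 4x4 affines stored as plain-text matrices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform

__all__ = [
    "Volume",
    "BinaryMask",
    "SubjectRecord",
    "read_volume",
    "write_volume",
    "read_affine_matrix",
    "write_affine_matrix",
    "resample_to_reference",
    "voxel_to_mni",
    "read_master_file",
    "MASK_RESAMPLING_THRESHOLD",
]

#: Interpolated-mask binarisation threshold applied after resampling a
#: binary mask with trilinear interpolation (strictly greater-than).
MASK_RESAMPLING_THRESHOLD = 0.25


@dataclass
class Volume:
    """A 3-D scalar image with its voxel geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar grid.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention).
    space_tag : str
        Free-text identifier of the reference space.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel dimensions must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def same_grid(self, other: "Volume", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))


@dataclass
class BinaryMask(Volume):
    """A Volume whose values are restricted to {0, 1}."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(np.unique(self.data), (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.data = self.data.astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


@dataclass
class SubjectRecord:
    """One subject's co-registered images and annotations.

    ``modalities`` is an ordered mapping name -> Volume with FLAIR first.
    All volumes share one grid shape and affine.
    """

    subject_id: str
    modalities: dict
    brain_mask: BinaryMask
    manual_mask: Optional[BinaryMask] = None
    to_mni_affine: Optional[np.ndarray] = None
    atlas_labels: Optional[Volume] = None
    icv_mm3: Optional[float] = None
    load_score: Optional[float] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality (FLAIR) is required")
        ref = next(iter(self.modalities.values()))
        for name, vol in self.modalities.items():
            if not vol.same_grid(ref):
                raise ValueError(f"modality {name!r} is not on the reference grid")
        if not self.brain_mask.same_grid(ref):
            raise ValueError("brain mask is not on the reference grid")
        if self.manual_mask is not None and not self.manual_mask.same_grid(ref):
            raise ValueError("manual mask is not on the reference grid")
        if self.to_mni_affine is not None:
            self.to_mni_affine = np.asarray(self.to_mni_affine, dtype=float)
            if self.to_mni_affine.shape != (4, 4):
                raise ValueError("to_mni_affine must be 4x4")
        if self.load_score is None and self.manual_mask is not None:
            self.load_score = self.manual_mask.volume_mm3()

    @property
    def reference(self) -> Volume:
        return next(iter(self.modalities.values()))

    @property
    def flair(self) -> Volume:
        return next(iter(self.modalities.values()))


def read_volume(path: str, as_mask: bool = False) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume` (or :class:`BinaryMask`).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for a
    non-3-D image.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    cls = BinaryMask if as_mask else Volume
    return cls(data=np.asarray(data, dtype=np.uint8 if as_mask else np.float32),
               affine=img.affine, space_tag=os.path.basename(path))


def write_volume(v: Volume, path: str) -> None:
    """Write a Volume as NIfTI-1: masks as uint8, intensities as float32."""
    if isinstance(v, BinaryMask):
        data = v.data.astype(np.uint8)
    else:
        data = v.data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, v.affine), path)


def read_affine_matrix(path: str) -> np.ndarray:
    """Read a FLIRT-style plain-text 4x4 affine matrix."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def write_affine_matrix(mat: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(mat, dtype=float), fmt="%.10g")


def resample_to_reference(
    v: Volume,
    target: Volume,
    transform: Optional[np.ndarray] = None,
    is_mask: bool = False,
    mask_threshold: float = MASK_RESAMPLING_THRESHOLD,
) -> Volume:
    """Resample ``v`` onto ``target``'s grid with trilinear interpolation.

    ``transform`` maps world coordinates of ``v``'s space to world
    coordinates of ``target``'s space (identity if omitted). Out-of-field
    voxels are filled with 0. If ``is_mask``, the interpolated field is
    binarised with a strict ``> mask_threshold`` test, reproducing the
    standard handling of interpolated manual masks after registration.
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform)) < 1e-12:
        raise ValueError("singular transform")
    # voxel(target) -> world(target) -> world(v) -> voxel(v)
    vox2vox = np.linalg.inv(v.affine) @ np.linalg.inv(transform) @ target.affine
    out = affine_transform(
        v.data.astype(np.float64),
        matrix=vox2vox[:3, :3],
        offset=vox2vox[:3, 3],
        output_shape=target.shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    if is_mask:
        return BinaryMask(
            data=(out > mask_threshold).astype(np.uint8),
            affine=target.affine,
            space_tag=target.space_tag,
        )
    return Volume(data=out.astype(np.float32), affine=target.affine,
                  space_tag=target.space_tag)


def voxel_to_mni(ijk, subject: SubjectRecord) -> np.ndarray:
    """Map voxel indices to MNI mm via subject affine then subject->MNI affine.

    ``ijk`` may be a single (i,j,k) triple or an (n, 3) array; returns mm
    coordinates with matching shape.
    """
    if subject.to_mni_affine is None:
        raise ValueError(
            f"subject {subject.subject_id!r} has no subject->MNI affine; "
            "spatial features are unavailable"
        )
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    hom = np.c_[ijk, np.ones(len(ijk))]
    full = subject.to_mni_affine @ subject.reference.affine
    out = (hom @ full.T)[:, :3]
    return out[0] if out.shape[0] == 1 and np.asarray(ijk).ndim == 1 else out


def read_master_file(path: str) -> pd.DataFrame:
    """Read a cohort master file (tab-separated, one row per subject).

    Expected columns: ``subject_id``, one column per modality path (e.g.
    ``flair``, ``t1``), ``brain_mask``, and optional ``manual_mask``,
    ``to_mni_affine``, ``atlas_labels``, ``load_score``, ``icv_mm3``.
    """
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "flair" not in df.columns:
        raise ValueError("master file needs 'subject_id' and 'flair' columns")
    return df


def load_subject(row: pd.Series, base_dir: str = ".") -> SubjectRecord:
    """Instantiate a SubjectRecord from one master-file row."""

    def _p(rel):
        return rel if os.path.isabs(rel) else os.path.join(base_dir, rel)

    known = {"subject_id", "brain_mask", "manual_mask", "to_mni_affine",
             "atlas_labels", "load_score", "icv_mm3"}
    modalities = {}
    for col in row.index:
        if col in known or pd.isna(row[col]):
            continue
        modalities[col] = read_volume(_p(str(row[col])))
    if "flair" in modalities:  # FLAIR always first
        modalities = {"flair": modalities.pop("flair"), **modalities}
    kwargs = {}
    if "manual_mask" in row.index and not pd.isna(row["manual_mask"]):
        kwargs["manual_mask"] = read_volume(_p(str(row["manual_mask"])), as_mask=True)
    if "to_mni_affine" in row.index and not pd.isna(row["to_mni_affine"]):
        kwargs["to_mni_affine"] = read_affine_matrix(_p(str(row["to_mni_affine"])))
    if "atlas_labels" in row.index and not pd.isna(row["atlas_labels"]):
        kwargs["atlas_labels"] = read_volume(_p(str(row["atlas_labels"])))
    for scalar in ("load_score", "icv_mm3"):
        if scalar in row.index and not pd.isna(row[scalar]):
            kwargs[scalar] = float(row[scalar])
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        modalities=modalities,
        brain_mask=read_volume(_p(str(row["brain_mask"])), as_mask=True),
        **kwargs,
    )
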