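"""Training-point and training-subject selection.

The classifier is trained on labelled voxels drawn from manually
segmented subjects. Three count modes control class balance:

- ``FE`` (fixed + equal): up to ``n_wmh`` lesion voxels per subject
  (capped by the manual mask) and the same number of non-lesion voxels;
- ``AE`` (all + equal): every manual lesion voxel, and an equal number of
  non-lesion voxels;
- ``FU`` (fixed + unbalanced): up to ``n_wmh`` lesion and up to
  ``n_nonwmh`` non-lesion voxels.

Non-lesion voxels can be drawn from anywhere outside the manual mask
(``any``), away from the lesion border (``no_border``) or preferentially
from the border shell (``surround``). Subjects can be restricted to the
highest or lowest lesion loads. When segmenting a subject that is itself
part of the training cohort, its rows are excluded (leave-one-out).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure

from .features import FeatureMatrix, FeatureSpec, build_feature_matrix
from .volumes import BinaryMask, SubjectRecord

__all__ = [
    "TrainingConfig",
    "TrainingSet",
    "select_training_subjects",
    "lesion_border",
    "select_training_points",
    "assemble_training_set",
]

logger = logging.getLogger(__name__)

#: class codes used in label arrays
NONWMH, WMH = 0, 1


@dataclass
class TrainingConfig:
    """Options controlling training-point selection."""

    mode: str = "FE"                      # FE | AE | FU
    n_wmh: int = 2000
    n_nonwmh: int = 10000                 # FU only
    location: str = "any"                 # any | no_border | surround
    border_width: int = 1
    subject_selection: str = "any_load"   # any_load | high_load | low_load
    n_subjects: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("FE", "AE", "FU"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.location not in ("any", "no_border", "surround"):
            raise ValueError(f"unknown location option {self.location!r}")
        if self.subject_selection not in ("any_load", "high_load", "low_load"):
            raise ValueError(f"unknown subject_selection {self.subject_selection!r}")
        if self.n_wmh < 1:
            raise ValueError("n_wmh must be >= 1")
        if self.mode == "FU" and self.n_nonwmh < 1:
            raise ValueError("n_nonwmh must be >= 1 in FU mode")
        if self.border_width < 1:
            raise ValueError("border_width must be >= 1")


@dataclass
class TrainingSet:
    """Labelled feature rows pooled over training subjects."""

    features: FeatureMatrix               # labels present
    provenance: np.ndarray                # per-row subject_id

    def __post_init__(self) -> None:
        if self.features.labels is None:
            raise ValueError("training features must be labelled")
        if len(self.provenance) != len(self.features):
            raise ValueError("one provenance entry per row required")
        labels = self.features.labels
        if not ((labels == WMH).any() and (labels == NONWMH).any()):
            raise ValueError("training set must contain both classes")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def subject_ids(self) -> Set[str]:
        return set(np.unique(self.provenance))


def select_training_subjects(
    cohort: Sequence[SubjectRecord], selection: str, n: Optional[int]
) -> List[SubjectRecord]:
    """Pick training subjects, optionally by lesion load.

    ``high_load``/``low_load`` take the ``n`` subjects with the largest or
    smallest ``load_score`` (visual rating or manual-mask volume), with a
    deterministic tie-break on subject id; ``any_load`` takes the first
    ``n`` in cohort order. ``n`` greater than the cohort size is clamped
    with a warning.
    """
    sel = {"any": "any_load", "high": "high_load", "low": "low_load"}.get(
        selection, selection
    )
    if n is None:
        n = len(cohort)
    if n < 1:
        raise ValueError("number of training subjects must be >= 1")
    if n > len(cohort):
        warnings.warn(
            f"requested {n} training subjects but cohort has {len(cohort)}; clamping"
        )
        n = len(cohort)
    for s in cohort:
        if s.manual_mask is None:
            raise ValueError(f"subject {s.subject_id!r} has no manual mask")
    if sel == "any_load":
        return list(cohort[:n])
    missing = [s.subject_id for s in cohort if s.load_score is None]
    if missing:
        raise ValueError(f"subjects lack a load score: {missing}")
    reverse = sel == "high_load"
    ranked = sorted(
        cohort,
        key=lambda s: (-s.load_score if reverse else s.load_score, s.subject_id),
    )
    return ranked[:n]


def lesion_border(mask: BinaryMask, width: int = 1) -> BinaryMask:
    """The non-lesion shell of the given width around lesions.

    Computed as ``dilate(mask, width) & ~mask`` with a 26-connected
    structuring element applied ``width`` times.
    """
    struct = generate_binary_structure(3, 3)  # 26-connected
    core = mask.data.astype(bool)
    dilated = binary_dilation(core, structure=struct, iterations=width) if core.any() else core
    return BinaryMask(
        data=(dilated & ~core).astype(np.uint8),
        affine=mask.affine,
        space_tag=mask.space_tag,
    )


def select_training_points(
    subject: SubjectRecord, cfg: TrainingConfig, rng_seed: int
):
    """Sample labelled voxel indices for one subject.

    Returns ``(wmh_ijk, nonwmh_ijk)`` as integer index arrays, or ``None``
    if the subject has an empty manual mask (skipped with a warning).
    Sampling is uniform without replacement and reproducible from
    ``rng_seed``.
    """
    if subject.manual_mask is None:
        raise ValueError(f"subject {subject.subject_id!r} has no manual mask")
    rng = np.random.default_rng(rng_seed)
    brain = subject.brain_mask.data.astype(bool)
    if not brain.any():
        raise ValueError("empty brain mask")
    lesion = subject.manual_mask.data.astype(bool) & brain
    if not lesion.any():
        warnings.warn(
            f"subject {subject.subject_id!r} has an empty manual mask; skipped"
        )
        return None
    wmh_pool = np.argwhere(lesion)
    if cfg.mode == "AE":
        wmh_idx = np.arange(len(wmh_pool))
    else:
        take = min(cfg.n_wmh, len(wmh_pool))
        wmh_idx = rng.choice(len(wmh_pool), size=take, replace=False)
    wmh_ijk = wmh_pool[np.sort(wmh_idx)]

    n_non = len(wmh_ijk) if cfg.mode in ("FE", "AE") else cfg.n_nonwmh
    outside = brain & ~lesion
    if not outside.any():
        raise ValueError("empty non-WMH pool")
    border = lesion_border(subject.manual_mask, cfg.border_width).data.astype(bool) & brain
    if cfg.location == "no_border":
        pool = outside & ~border
        if not pool.any():
            raise ValueError("no_border option leaves an empty non-WMH pool")
        nonwmh_ijk = _sample(np.argwhere(pool), min(n_non, int(pool.sum())), rng)
    elif cfg.location == "surround":
        shell = np.argwhere(border & outside)
        rest = np.argwhere(outside & ~border)
        n_shell = min(n_non, len(shell))
        picked = [_sample(shell, n_shell, rng)]
        short = n_non - n_shell
        if short > 0:
            if len(rest) == 0 and short > 0:
                short = 0
            else:
                logger.warning(
                    "surround border smaller than requested (%d < %d); "
                    "filling from the general pool", n_shell, n_non
                )
                picked.append(_sample(rest, min(short, len(rest)), rng))
        nonwmh_ijk = np.concatenate(picked, axis=0)
    else:  # any
        pool = np.argwhere(outside)
        nonwmh_ijk = _sample(pool, min(n_non, len(pool)), rng)
    return wmh_ijk, nonwmh_ijk


def _sample(pool: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return pool[:0]
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool[np.sort(idx)]


def subject_training_rows(
    subject: SubjectRecord, cfg: TrainingConfig, spec: FeatureSpec
):
    """One subject's labelled training rows, or ``None`` if it has no lesions.

    Features are normalised from the subject's own brain mask; the
    sampling seed derives deterministically from ``cfg.seed`` and the
    subject id, so a subject's contribution is invariant to which other
    subjects are in the cohort.
    """
    sel = select_training_points(subject, cfg, _subject_seed(cfg.seed, subject.subject_id))
    if sel is None:
        return None
    wmh_ijk, non_ijk = sel
    fm = build_feature_matrix(subject, spec)
    order = np.empty(subject.brain_mask.data.size, dtype=np.intp)
    order[np.ravel_multi_index(fm.voxel_index.T, subject.brain_mask.shape)] = (
        np.arange(len(fm))
    )
    rows, ijks, labels = [], [], []
    for ijk, lab in ((wmh_ijk, WMH), (non_ijk, NONWMH)):
        if len(ijk) == 0:
            continue
        ridx = order[np.ravel_multi_index(ijk.T, subject.brain_mask.shape)]
        rows.append(fm.rows[ridx])
        ijks.append(ijk)
        labels.append(np.full(len(ijk), lab, dtype=np.int8))
    return (
        np.concatenate(rows, axis=0),
        np.concatenate(ijks, axis=0),
        np.concatenate(labels),
    )


def pool_training_rows(
    contributions: dict, feature_names: Sequence[str],
    exclude: Optional[Iterable[str]] = None,
) -> TrainingSet:
    """Concatenate cached per-subject contributions, honouring exclusions."""
    exclude = set(exclude or ())
    rows, ijks, labels, prov = [], [], [], []
    for sid, contrib in contributions.items():
        if sid in exclude or contrib is None:
            continue
        r, v, l = contrib
        rows.append(r)
        ijks.append(v)
        labels.append(l)
        prov.append(np.full(len(r), sid, dtype=object))
    if not rows:
        raise ValueError("no subject contributed training points")
    fm = FeatureMatrix(
        rows=np.concatenate(rows, axis=0),
        voxel_index=np.concatenate(ijks, axis=0),
        feature_names=list(feature_names),
        labels=np.concatenate(labels),
    )
    return TrainingSet(features=fm, provenance=np.concatenate(prov))


def assemble_training_set(
    subjects: Sequence[SubjectRecord],
    cfg: TrainingConfig,
    spec: FeatureSpec,
    exclude: Optional[Iterable[str]] = None,
) -> TrainingSet:
    """Pool selected training points' feature rows over subjects.

    Rows from subjects in ``exclude`` never appear (leave-one-out).
    Features are normalised per subject, each from its own brain mask.
    Per-subject sampling seeds are derived deterministically from
    ``cfg.seed`` and the subject id, so the same cohort and config always
    yield the same training set regardless of exclusions.
    """
    exclude = set(exclude or ())
    kept = [s for s in subjects if s.subject_id not in exclude]
    if not kept:
        raise ValueError("all subjects excluded from the training set")
    contributions = {s.subject_id: subject_training_rows(s, cfg, spec) for s in kept}
    return pool_training_rows(contributions, spec.feature_names())


def _subject_seed(base_seed: int, subject_id: str) -> int:
    h = np.uint32(2166136261)
    for ch in subject_id.encode():
        h = np.uint32((int(h) ^ ch) * 16777619 & 0xFFFFFFFF)
    return int((np.uint32(base_seed * 2654435761 & 0xFFFFFFFF) ^ h) & 0x7FFFFFFF)
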