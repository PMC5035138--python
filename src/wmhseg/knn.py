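"""k-NN voxel classification and probability thresholding.

The classifier assigns each query voxel the fraction of lesion-class
rows among its k nearest training rows (Euclidean distance in the
normalised feature space), so the output probability is quantised to
multiples of 1/k. A binary lesion mask is obtained by thresholding the
probability map, by default at 0.9 with k = 40.

Two estimators are provided: :class:`KNNVoxelClassifier`, a
scikit-learn-compatible classifier on plain feature matrices, and
:class:`LesionSegmenter`, which operates on :class:`SubjectRecord`
cohorts end to end (feature extraction, training-point selection,
leave-one-out handling, thresholding and exclusion masking).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exclusion import ExclusionMask, apply_exclusion, build_exclusion_mask
from .features import FeatureMatrix, FeatureSpec, build_feature_matrix
from .training import (
    TrainingConfig,
    TrainingSet,
    pool_training_rows,
    subject_training_rows,
)
from .volumes import BinaryMask, SubjectRecord, Volume

__all__ = [
    "KNNVoxelClassifier",
    "LesionSegmenter",
    "knn_probability",
    "threshold_probability",
    "brute_force_knn_probability",
]


def brute_force_knn_probability(
    X_train: np.ndarray, y_train: np.ndarray, X_query: np.ndarray, k: int
) -> np.ndarray:
    """Exhaustive O(n m) reference: full distance sort per query row.

    Ties at the k-th distance are broken by training-row insertion index
    (stable lexicographic sort on (distance, index)). Serves as the exact
    oracle for the accelerated search.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_query = np.asarray(X_query, dtype=np.float64)
    y_train = np.asarray(y_train)
    out = np.empty(len(X_query))
    idx = np.arange(len(X_train))
    for q, row in enumerate(X_query):
        d = np.sqrt(((X_train - row) ** 2).sum(axis=1))
        nearest = idx[np.lexsort((idx, d))][:k]
        out[q] = np.mean(y_train[nearest] == 1)
    return out


class KNNVoxelClassifier(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour voxel classifier with 1/k-quantised probabilities.

    Parameters
    ----------
    k : int, default 40
        Number of neighbours voting per query voxel.
    metric : str, default "euclidean"
        Distance in feature space (only Euclidean is supported).

    Attributes
    ----------
    X_ : ndarray of shape (n_train, n_features)
        Stored training rows, in insertion order.
    y_ : ndarray of shape (n_train,)
        Training labels in {0, 1}; 1 is the lesion class.
    classes_ : ndarray
        Sorted unique labels, always [0, 1].
    nn_ : fitted sklearn NearestNeighbors index.

    Notes
    -----
    Exact ties at the k-th neighbour distance are resolved by training-row
    insertion index, so the accelerated KD-tree path returns bit-identical
    probabilities to the exhaustive distance sort.
    """

    def __init__(self, k: int = 40, metric: str = "euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > len(X):
            raise ValueError(f"k={self.k} exceeds {len(X)} training rows")
        self.classes_ = np.unique(y)
        if not np.array_equal(self.classes_, [0, 1]):
            raise ValueError("training labels must contain both classes 0 and 1")
        self.X_ = np.asarray(X, dtype=np.float64)
        self.y_ = np.asarray(y)
        self.n_features_in_ = self.X_.shape[1]
        self.nn_ = NearestNeighbors(metric="euclidean").fit(self.X_)
        return self

    def predict_proba(self, X):
        """Class-membership probabilities, columns ordered [non-lesion, lesion]."""
        p = self.lesion_fraction(X)
        return np.column_stack([1.0 - p, p])

    def lesion_fraction(self, X) -> np.ndarray:
        """Fraction of the k nearest training rows in the lesion class."""
        check_is_fitted(self, "X_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query feature width differs from training")
        k = self.k
        n_train = len(self.X_)
        # query one extra neighbour to detect ties straddling the k-th rank
        kq = min(k + 1, n_train)
        dist, ind = self.nn_.kneighbors(X, n_neighbors=kq)
        p = (self.y_[ind[:, :k]] == 1).mean(axis=1)
        if kq > k:
            # rows whose k-th and (k+1)-th distances (near-)coincide are
            # re-resolved exhaustively with the insertion-index tie-break
            gap = dist[:, k] - dist[:, k - 1]
            ambiguous = gap <= 1e-9 * np.maximum(1.0, dist[:, k])
            if ambiguous.any():
                p[ambiguous] = brute_force_knn_probability(
                    self.X_, self.y_, X[ambiguous], k
                )
        return p

    def predict(self, X):
        return (self.lesion_fraction(X) >= 0.5).astype(int)


def knn_probability(
    query: FeatureMatrix,
    train: TrainingSet,
    k: int = 40,
    grid_shape: Optional[tuple] = None,
    affine: Optional[np.ndarray] = None,
    space_tag: str = "subject",
) -> Volume:
    """Classify query voxels and write probabilities back to the voxel grid.

    Out-of-mask voxels hold 0; in-mask voxels hold the lesion-class
    fraction among the k nearest training rows.
    """
    if query.feature_names != train.features.feature_names:
        raise ValueError(
            "feature-name mismatch between query and training set: "
            f"{query.feature_names} vs {train.features.feature_names}"
        )
    clf = KNNVoxelClassifier(k=k).fit(train.features.rows, train.features.labels)
    p = clf.lesion_fraction(query.rows) if len(query) else np.empty(0)
    if grid_shape is None or affine is None:
        raise ValueError("grid_shape and affine are required to map back to voxels")
    vol = np.zeros(grid_shape, dtype=np.float64)
    vol[tuple(query.voxel_index.T)] = p
    return Volume(data=vol, affine=affine, space_tag=space_tag)


def threshold_probability(
    p: Volume, thr: float = 0.9, inclusive: bool = True
) -> BinaryMask:
    """Binarise a lesion probability map.

    A voxel is lesion iff its probability is >= ``thr`` (inclusive by
    default, which keeps thr = 1.0 attainable; set ``inclusive=False``
    for a strict > test). Raising the threshold trades false positives
    for false negatives.
    """
    if not 0 <= thr <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    data = p.data >= thr if inclusive else p.data > thr
    return BinaryMask(data=data.astype(np.uint8), affine=p.affine,
                      space_tag=p.space_tag)


class LesionSegmenter(BaseEstimator):
    """End-to-end supervised lesion segmentation for subject cohorts.

    Fitting selects training subjects and voxels per the training config,
    extracts features and stores the pooled labelled rows. Prediction
    builds the query subject's feature matrix, classifies every in-brain
    voxel, thresholds the probability map and optionally applies a
    CSF-based exclusion mask. When the query subject belongs to the
    training cohort its rows are left out automatically.

    Parameters
    ----------
    k : neighbours voting per voxel (default 40).
    threshold : probability cut-off for the binary mask (default 0.9).
    modalities : modality names used as intensity features.
    spatial_weight : sw multiplier for MNI coordinate features.
    patch_sizes, patch_dim : local-averaging kernel sizes and dimension.
    mode, n_wmh, n_nonwmh, location, border_width, subject_selection,
    n_subjects, seed : training-set options, see
        :class:`~wmhseg.training.TrainingConfig`.
    apply_exclusion_mask : remove non-WM false positives using the
        subject's CSF segmentation and atlas labels.
    """

    def __init__(
        self,
        k: int = 40,
        threshold: float = 0.9,
        modalities: Sequence[str] = ("flair",),
        spatial_weight: float = 1.0,
        patch_sizes: Sequence[int] = (),
        patch_dim: int = 3,
        mode: str = "FU",
        n_wmh: int = 2000,
        n_nonwmh: int = 10000,
        location: str = "no_border",
        border_width: int = 1,
        subject_selection: str = "any_load",
        n_subjects: Optional[int] = None,
        seed: int = 0,
        apply_exclusion_mask: bool = True,
    ):
        self.k = k
        self.threshold = threshold
        self.modalities = modalities
        self.spatial_weight = spatial_weight
        self.patch_sizes = patch_sizes
        self.patch_dim = patch_dim
        self.mode = mode
        self.n_wmh = n_wmh
        self.n_nonwmh = n_nonwmh
        self.location = location
        self.border_width = border_width
        self.subject_selection = subject_selection
        self.n_subjects = n_subjects
        self.seed = seed
        self.apply_exclusion_mask = apply_exclusion_mask

    def _feature_spec(self) -> FeatureSpec:
        return FeatureSpec(
            modality_names=tuple(self.modalities),
            patch_sizes=tuple(self.patch_sizes),
            patch_dim=self.patch_dim,
            spatial_weight=self.spatial_weight,
        )

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            mode=self.mode,
            n_wmh=self.n_wmh,
            n_nonwmh=self.n_nonwmh,
            location=self.location,
            border_width=self.border_width,
            subject_selection=self.subject_selection,
            n_subjects=self.n_subjects,
            seed=self.seed,
        )

    def fit(self, subjects: Sequence[SubjectRecord], y=None):
        """Store the training cohort (subject and point selection applied)."""
        from .training import select_training_subjects

        if not subjects:
            raise ValueError("at least one training subject is required")
        sel = {"any_load": "any_load", "high_load": "high_load",
               "low_load": "low_load"}[self.subject_selection]
        self.training_subjects_ = select_training_subjects(
            list(subjects), sel, self.n_subjects
        )
        self.training_ids_ = [s.subject_id for s in self.training_subjects_]
        self.feature_spec_ = self._feature_spec()
        self.training_config_ = self._training_config()
        # per-subject rows cached once; leave-one-out pools all but one
        self.contributions_ = {
            s.subject_id: subject_training_rows(
                s, self.training_config_, self.feature_spec_
            )
            for s in self.training_subjects_
        }
        return self

    def _training_set(self, exclude: Sequence[str]) -> TrainingSet:
        return pool_training_rows(
            self.contributions_, self.feature_spec_.feature_names(), exclude
        )

    def predict_proba_map(self, subject: SubjectRecord) -> Volume:
        """Lesion probability map for one subject (leave-one-out aware)."""
        check_is_fitted(self, "training_subjects_")
        exclude = [subject.subject_id] if subject.subject_id in self.training_ids_ else []
        train = self._training_set(exclude)
        query = build_feature_matrix(subject, self.feature_spec_)
        return knn_probability(
            query, train, k=self.k,
            grid_shape=subject.brain_mask.shape,
            affine=subject.brain_mask.affine,
            space_tag=subject.reference.space_tag,
        )

    def predict_mask(
        self, subject: SubjectRecord,
        exclusion: Optional[ExclusionMask] = None,
    ) -> BinaryMask:
        """Thresholded binary lesion mask, with optional exclusion masking."""
        prob = self.predict_proba_map(subject)
        mask = threshold_probability(prob, self.threshold)
        if self.apply_exclusion_mask:
            if exclusion is None:
                exclusion = build_exclusion_mask(subject)
            mask = apply_exclusion(mask, exclusion)
        return mask

    # sklearn-style alias: predict on a single subject returns the mask
    predict = predict_mask
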