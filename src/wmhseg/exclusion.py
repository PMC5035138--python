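"""CSF-based exclusion masking.

FLAIR images routinely show non-lesion hyperintensities in cortical grey
matter and flow artefacts around the ventricles. Rather than relying on
a full grey/white segmentation (which lesions themselves corrupt), the
exclusion mask is built from CSF only: a two-class intensity split
yields the CSF map, ventricular CSF is removed (plus a protective
margin, so periventricular lesions survive), and the remaining cortical
CSF is dilated to cover the cortical grey-matter ribbon. Atlas-defined
subcortical structures (thalamus, basal ganglia, entorhinal cortex,
optionally cerebellum) are added as further components. Candidate lesion
voxels falling inside the union are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure
from sklearn.mixture import GaussianMixture

from .volumes import BinaryMask, SubjectRecord, Volume

__all__ = [
    "ExclusionMask",
    "two_class_segment",
    "extract_cortical_csf",
    "build_exclusion_mask",
    "apply_exclusion",
    "DEFAULT_STRUCTURE_LABELS",
]

#: atlas integer labels used by the phantom generator and expected by
#: default for real atlases supplied as (label, name) tables
DEFAULT_STRUCTURE_LABELS = {
    "ventricles": 1,
    "thalamus": 2,
    "basal_ganglia": 3,
    "entorhinal": 4,
}

_STRUCT26 = generate_binary_structure(3, 3)


@dataclass
class ExclusionMask(BinaryMask):
    """Binary exclusion region with per-component provenance."""

    components: Dict[str, np.ndarray] = field(default_factory=dict)

    def component_union(self) -> np.ndarray:
        u = np.zeros(self.shape, dtype=bool)
        for comp in self.components.values():
            u |= comp.astype(bool)
        return u


def two_class_segment(
    img: Volume, brain: BinaryMask, low_class: bool = True, seed: int = 0
) -> BinaryMask:
    """Two-class Gaussian-mixture split of in-mask intensities.

    Fits a 2-component 1-D Gaussian mixture to the in-brain intensities
    and returns the maximum-posterior voxel set of the component with the
    lower mean (``low_class=True``; on FLAIR this is CSF) or the higher
    mean (for inverted-contrast images). The components share one (tied)
    variance and are initialised at the 5th and 60th intensity
    percentiles: the split then stays a coarse dark-vs-bright partition
    and cannot collapse onto a narrow tissue mode when bright lesions add
    a third intensity peak.
    """
    m = brain.data.astype(bool)
    vals = img.data[m].astype(np.float64).reshape(-1, 1)
    if len(vals) < 2 or float(np.std(vals)) == 0:
        raise ValueError("cannot split a constant image into two classes")
    lo, hi = np.percentile(vals, [5, 60])
    if lo == hi:
        lo, hi = float(vals.min()), float(vals.max())
    gmm = GaussianMixture(
        n_components=2, covariance_type="tied", means_init=[[lo], [hi]],
        random_state=seed,
    ).fit(vals)
    means = gmm.means_.ravel()
    if not np.isfinite(means).all() or abs(means[0] - means[1]) < 1e-9 * (
        abs(means).max() + 1e-12
    ):
        raise ValueError(
            f"degenerate two-class fit: component means {means} collapsed"
        )
    target = int(np.argmin(means)) if low_class else int(np.argmax(means))
    post = gmm.predict(vals)
    out = np.zeros(img.shape, dtype=np.uint8)
    out[m] = (post == target).astype(np.uint8)
    return BinaryMask(data=out, affine=img.affine, space_tag=img.space_tag)


def extract_cortical_csf(
    csf: BinaryMask, ventricle_mask: BinaryMask, periventricular_margin: int = 2
) -> BinaryMask:
    """Remove ventricular CSF (plus a protective margin) from a CSF map.

    The margin keeps periventricular lesion voxels out of the eventual
    exclusion mask. 26-connected dilation, one iteration per voxel of
    margin.
    """
    if csf.shape != ventricle_mask.shape:
        raise ValueError("CSF and ventricle masks must share a grid")
    vent = ventricle_mask.data.astype(bool)
    if periventricular_margin > 0 and vent.any():
        vent = binary_dilation(vent, structure=_STRUCT26,
                               iterations=periventricular_margin)
    out = csf.data.astype(bool) & ~vent
    return BinaryMask(data=out.astype(np.uint8), affine=csf.affine,
                      space_tag=csf.space_tag)


def build_exclusion_mask(
    subject: SubjectRecord,
    dilation_radius: int = 2,
    structure_labels: Optional[Sequence[int]] = None,
    periventricular_margin: int = 2,
    csf_mask: Optional[BinaryMask] = None,
    seed: int = 0,
) -> ExclusionMask:
    """Union of dilated cortical CSF and atlas-defined structures.

    ``structure_labels`` defaults to thalamus, basal ganglia and
    entorhinal cortex under the default label table; ventricle voxels are
    taken from the atlas label 'ventricles'. Pass ``csf_mask`` to reuse a
    precomputed CSF segmentation instead of the internal two-class split
    of FLAIR.
    """
    ref = subject.reference
    if subject.atlas_labels is None:
        raise ValueError(
            "atlas labels are required to build the exclusion mask "
            "(ventricles and subcortical structures)"
        )
    labels = subject.atlas_labels.data.astype(int)
    if structure_labels is None:
        structure_labels = [
            DEFAULT_STRUCTURE_LABELS["thalamus"],
            DEFAULT_STRUCTURE_LABELS["basal_ganglia"],
            DEFAULT_STRUCTURE_LABELS["entorhinal"],
        ]
    if csf_mask is None:
        csf_mask = two_class_segment(subject.flair, subject.brain_mask,
                                     low_class=True, seed=seed)
    vent = BinaryMask(
        data=(labels == DEFAULT_STRUCTURE_LABELS["ventricles"]).astype(np.uint8),
        affine=ref.affine, space_tag=ref.space_tag,
    )
    cortical = extract_cortical_csf(csf_mask, vent, periventricular_margin)
    comp: Dict[str, np.ndarray] = {}
    cort = cortical.data.astype(bool)
    if dilation_radius > 0 and cort.any():
        cort = binary_dilation(cort, structure=_STRUCT26,
                               iterations=dilation_radius)
    comp["cortical_csf_dilated"] = cort
    if len(structure_labels) > 0:
        comp["subcortical_atlas"] = np.isin(labels, list(structure_labels))
    union = np.zeros(ref.shape, dtype=bool)
    for c in comp.values():
        union |= c
    return ExclusionMask(
        data=union.astype(np.uint8), affine=ref.affine,
        space_tag=ref.space_tag, components=comp,
    )


def apply_exclusion(lesions: BinaryMask, excl: BinaryMask) -> BinaryMask:
    """Remove excluded voxels from a candidate lesion mask."""
    if lesions.shape != excl.shape:
        raise ValueError("lesion and exclusion masks must share a grid")
    out = lesions.data.astype(bool) & ~excl.data.astype(bool)
    return BinaryMask(data=out.astype(np.uint8), affine=lesions.affine,
                      space_tag=lesions.space_tag)
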