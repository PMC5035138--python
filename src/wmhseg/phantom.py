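"""Synthetic multimodal head phantoms with known lesion ground truth.

The phantom is a layered head template on a regular grid: an ellipsoidal
brain whose outermost shell is cortical CSF, then a cortical grey-matter
ribbon, a white-matter core, lateral-ventricle CSF spaces and
subcortical nuclei (thalamus, basal ganglia) plus small entorhinal
regions. Lesions are sums of random Gaussian blobs thresholded at
half-maximum and clipped to white matter, with a controllable total load
(fraction of WM volume) and a controllable share seeded adjacent to the
ventricles (periventricular) versus deep WM. Rendering produces a
FLAIR-like contrast (CSF dark, lesions bright) and a pseudo-T1 (lesions
slightly hypointense), with partial-volume smoothing and additive
Gaussian noise. Optionally, cortical bright spots and a
fourth-ventricle-like flow artefact are planted to exercise exclusion
masking.

The phantom's standard space is its own grid (identity subject-to-MNI
affine), so spatial features work without a real template. Gaussian
(rather than Rician) noise is an accepted simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import (
    binary_dilation,
    binary_erosion,
    distance_transform_edt,
    gaussian_filter,
    generate_binary_structure,
)

from .exclusion import DEFAULT_STRUCTURE_LABELS
from .volumes import BinaryMask, SubjectRecord, Volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]

_STRUCT26 = generate_binary_structure(3, 3)

# rendered tissue means (arbitrary units); FLAIR ordering is
# lesion > WM > GM > CSF by construction
FLAIR_MEANS = {"csf": 25.0, "gm": 70.0, "wm": 100.0}
T1_MEANS = {"csf": 30.0, "gm": 70.0, "wm": 100.0, "lesion": 80.0}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    lesion_load_target is the fraction of WM volume occupied by lesions
    (0 to 0.2); noise_sigma is the additive Gaussian noise sd as a
    fraction of the WM mean; pv_smooth_fwhm (mm) models partial volume.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_load_target: float = 0.02
    n_lesions: Tuple[int, int] = (4, 12)
    periventricular_fraction: float = 0.5
    lesion_intensity_boost: float = 1.5
    noise_sigma: float = 0.08
    pv_smooth_fwhm: float = 1.5
    plant_cortical_artifacts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lesion_load_target <= 0.2:
            raise ValueError("lesion_load_target must lie in [0, 0.2]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.grid_shape) < 32:
            raise ValueError("grid must be at least 32^3 to contain the head template")
        if not 0 <= self.periventricular_fraction <= 1:
            raise ValueError("periventricular_fraction must lie in [0, 1]")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _head_template(shape):
    """Tissue masks of the layered head template."""
    nx, ny, nz = shape
    c = np.array(shape) / 2.0
    brain = _ellipsoid(shape, c, (0.42 * nx, 0.46 * ny, 0.40 * nz))
    inner1 = binary_erosion(brain, _STRUCT26, iterations=1)
    inner3 = binary_erosion(brain, _STRUCT26, iterations=3)
    csf_rim = brain & ~inner1
    gm = inner1 & ~inner3
    core = inner3

    # lateral ventricles: two elongated ellipsoids flanking the midline
    vent = np.zeros(shape, dtype=bool)
    for sx in (-1, 1):
        vent |= _ellipsoid(
            shape,
            (c[0] + sx * 0.08 * nx, c[1], c[2] + 0.02 * nz),
            (0.045 * nx, 0.22 * ny, 0.06 * nz),
        )
    vent &= core

    thal = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    ento = np.zeros(shape, dtype=bool)
    for sx in (-1, 1):
        thal |= _ellipsoid(
            shape,
            (c[0] + sx * 0.17 * nx, c[1] - 0.06 * ny, c[2]),
            (0.06 * nx, 0.07 * ny, 0.06 * nz),
        )
        bg |= _ellipsoid(
            shape,
            (c[0] + sx * 0.20 * nx, c[1] + 0.10 * ny, c[2]),
            (0.06 * nx, 0.08 * ny, 0.06 * nz),
        )
        ento |= _ellipsoid(
            shape,
            (c[0] + sx * 0.24 * nx, c[1] + 0.06 * ny, c[2] - 0.24 * nz),
            (0.05 * nx, 0.05 * ny, 0.04 * nz),
        )
    thal = thal & core & ~vent
    bg = bg & core & ~vent & ~thal
    ento = ento & core & ~vent
    wm = core & ~vent & ~thal & ~bg & ~ento
    return {
        "brain": brain, "csf_rim": csf_rim, "gm": gm, "ventricles": vent,
        "thalamus": thal, "basal_ganglia": bg, "entorhinal": ento, "wm": wm,
    }


def _grow_lesions(tissues, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Accumulate half-max-thresholded Gaussian blobs in WM up to the load."""
    wm = tissues["wm"]
    target = int(round(spec.lesion_load_target * wm.sum()))
    lesions = np.zeros(spec.grid_shape, dtype=bool)
    if target == 0:
        return lesions
    if target > wm.sum():
        raise ValueError("lesion load target exceeds the white-matter volume")
    # candidate seed pools
    perivent_shell = (
        binary_dilation(tissues["ventricles"], _STRUCT26, iterations=2) & wm
    )
    dist_gm = distance_transform_edt(~(tissues["gm"] | tissues["csf_rim"]))
    deep = wm & (dist_gm >= 3) & ~perivent_shell
    pv_pool = np.argwhere(perivent_shell)
    deep_pool = np.argwhere(deep if deep.any() else wm)
    n_min, n_max = spec.n_lesions
    n_seeds = int(rng.integers(n_min, n_max + 1))
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    placed = 0
    attempts = 0
    while lesions.sum() < target and attempts < 200:
        attempts += 1
        use_pv = (rng.random() < spec.periventricular_fraction) and len(pv_pool) > 0
        pool = pv_pool if use_pv else deep_pool
        centre = pool[rng.integers(len(pool))]
        remaining = target - int(lesions.sum())
        n_left = max(1, n_seeds - placed)
        want = max(2, remaining // n_left)
        # half-max threshold of an isotropic Gaussian -> sphere of radius
        # sigma*sqrt(2 ln 2); pick sigma to roughly match the wanted volume
        r = (3.0 * want / (4.0 * np.pi)) ** (1.0 / 3.0)
        sigma = max(0.7, r / np.sqrt(2 * np.log(2))) * rng.uniform(0.8, 1.25)
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, centre))
        blob = (d2 <= 2 * np.log(2) * sigma ** 2) & wm
        new = blob & ~lesions
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if int(lesions.sum()) + n_new > target:
            # trim the farthest new voxels so the load lands on target
            keep = target - int(lesions.sum())
            idx = np.argwhere(new)
            d = ((idx - centre) ** 2).sum(axis=1)
            sel = idx[np.argsort(d, kind="stable")[:keep]]
            new = np.zeros_like(new)
            new[tuple(sel.T)] = True
        lesions |= new
        placed += 1
    return lesions


def _render(tissues, lesions, spec, rng, artifacts):
    flair = np.zeros(spec.grid_shape, dtype=np.float64)
    t1 = np.zeros(spec.grid_shape, dtype=np.float64)
    csf = tissues["csf_rim"] | tissues["ventricles"]
    gm_like = tissues["gm"] | tissues["entorhinal"]
    nuclei = tissues["thalamus"] | tissues["basal_ganglia"]
    flair[csf] = FLAIR_MEANS["csf"]
    flair[gm_like] = FLAIR_MEANS["gm"]
    flair[nuclei] = 0.5 * (FLAIR_MEANS["gm"] + FLAIR_MEANS["wm"])
    flair[tissues["wm"]] = FLAIR_MEANS["wm"]
    lesion_mean = spec.lesion_intensity_boost * FLAIR_MEANS["wm"]
    flair[lesions] = lesion_mean
    t1[csf] = T1_MEANS["csf"]
    t1[gm_like] = T1_MEANS["gm"]
    t1[nuclei] = 0.5 * (T1_MEANS["gm"] + T1_MEANS["wm"])
    t1[tissues["wm"]] = T1_MEANS["wm"]
    t1[lesions] = T1_MEANS["lesion"]
    for mask in artifacts.values():
        flair[mask] = lesion_mean
    sigma_vox = (spec.pv_smooth_fwhm / 2.3548) / np.asarray(spec.voxel_size)
    if np.any(sigma_vox > 0):
        flair = gaussian_filter(flair, sigma=sigma_vox)
        t1 = gaussian_filter(t1, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        sd = spec.noise_sigma * FLAIR_MEANS["wm"]
        flair = flair + rng.normal(0.0, sd, size=flair.shape)
        t1 = t1 + rng.normal(0.0, sd, size=t1.shape)
    return flair, t1


def _plant_artifacts(tissues, spec, rng):
    """Cortical bright spots and a flow artefact near the ventricle tip."""
    artifacts = {}
    if not spec.plant_cortical_artifacts:
        return artifacts
    shell = tissues["gm"] | tissues["csf_rim"]
    pool = np.argwhere(shell)
    cortical = np.zeros(spec.grid_shape, dtype=bool)
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    for _ in range(4):
        centre = pool[rng.integers(len(pool))]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
        cortical |= (d2 <= 2.5) & shell
    artifacts["cortical"] = cortical
    # flow artefact: bright CSF at the inferior tip of the ventricles
    vent = tissues["ventricles"]
    if vent.any():
        zmin = np.argwhere(vent)[:, 2].min()
        flow = vent & (np.arange(spec.grid_shape[2])[None, None, :] <= zmin + 1)
        artifacts["flow"] = flow
    return artifacts


def generate_phantom(
    spec: PhantomSpec, noise_seed: Optional[int] = None, subject_id: str = "phantom"
) -> SubjectRecord:
    """Build one synthetic subject with ground truth.

    The structural draw (lesion geometry, artefact placement) is driven by
    ``spec.seed``; additive noise uses ``noise_seed`` when given, so the
    same anatomy can be re-rendered as an independent noise realisation
    (scan-rescan style). Returns a SubjectRecord whose ``manual_mask`` is
    the true lesion mask and whose ``ground_truth`` dict holds the tissue
    masks and planted-artefact masks.
    """
    struct_rng = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng(
        spec.seed + 777 if noise_seed is None else noise_seed
    )
    tissues = _head_template(spec.grid_shape)
    lesions = _grow_lesions(tissues, spec, struct_rng)
    artifacts = _plant_artifacts(tissues, spec, struct_rng)
    flair_data, t1_data = _render(tissues, lesions, spec, noise_rng, artifacts)

    affine = np.diag(list(spec.voxel_size) + [1.0])
    vol = lambda d: Volume(data=d.astype(np.float32), affine=affine,
                           space_tag="phantom")
    brain = BinaryMask(data=tissues["brain"].astype(np.uint8), affine=affine,
                       space_tag="phantom")
    atlas = np.zeros(spec.grid_shape, dtype=np.int16)
    atlas[tissues["ventricles"]] = DEFAULT_STRUCTURE_LABELS["ventricles"]
    atlas[tissues["thalamus"]] = DEFAULT_STRUCTURE_LABELS["thalamus"]
    atlas[tissues["basal_ganglia"]] = DEFAULT_STRUCTURE_LABELS["basal_ganglia"]
    atlas[tissues["entorhinal"]] = DEFAULT_STRUCTURE_LABELS["entorhinal"]
    voxel_mm3 = float(np.prod(spec.voxel_size))
    manual = BinaryMask(data=lesions.astype(np.uint8), affine=affine,
                        space_tag="phantom")
    perivent = (
        binary_dilation(tissues["ventricles"], _STRUCT26, iterations=2) & lesions
    )
    gt = {
        "spec": spec,
        "tissues": tissues,
        "true_lesions": manual,
        "periventricular_lesions": perivent,
        "artifacts": artifacts,
        "lesion_volume_mm3": float(lesions.sum()) * voxel_mm3,
        "wm_volume_mm3": float(tissues["wm"].sum()) * voxel_mm3,
    }
    return SubjectRecord(
        subject_id=subject_id,
        modalities={"flair": vol(flair_data), "t1": vol(t1_data)},
        brain_mask=brain,
        manual_mask=manual,
        to_mni_affine=np.eye(4),
        atlas_labels=Volume(data=atlas, affine=affine, space_tag="phantom"),
        icv_mm3=float(tissues["brain"].sum()) * voxel_mm3,
        load_score=float(lesions.sum()) * voxel_mm3,
        ground_truth=gt,
    )


def generate_cohort(
    n: int,
    load_distribution: str = "mixed",
    base_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
) -> List[SubjectRecord]:
    """n phantoms with lesion loads drawn from a named distribution.

    ``low``: uniform 0.1-0.5% of WM; ``high``: uniform 2-8%; ``mixed``:
    log-uniform across 0.1-8%. Per-subject seeds derive deterministically
    from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if load_distribution not in ("low", "high", "mixed"):
        raise ValueError(f"unknown load distribution {load_distribution!r}")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if load_distribution == "low":
            load = rng.uniform(0.001, 0.005)
        elif load_distribution == "high":
            load = rng.uniform(0.02, 0.08)
        else:
            load = float(np.exp(rng.uniform(np.log(0.001), np.log(0.08))))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, lesion_load_target=load, seed=sub_seed)
        out.append(generate_phantom(spec, subject_id=f"phantom_{i:03d}"))
    return out
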