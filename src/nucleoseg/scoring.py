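"""Nucleolar segment scoring within segmented nuclei.

The median-filtered holes image acts as a compartment template: inside every
nucleus, candidate segments are connected components above a per-nucleus
threshold of the template, and a candidate is accepted when

* its area (2D, µm²) or volume (3D, µm³) lies inside configured bounds, and
* its mean hole response exceeds the mean response in a surrounding
  intranuclear annulus ("local background") by a configured floor.

The floor can be given in absolute response units or — the default — as a
fraction of the median source intensity inside the nucleus, which makes
scoring invariant to global linear intensity rescaling (including the
rescale applied when two negative-marker images are summed).

Accepted segments are relabelled contiguously, each tied to its parent
nucleus.  :func:`evaluate_segmentation` quantifies agreement with ground
truth by greedy IoU matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import ValidationError
from .filters import ChannelImage, HolesImage

__all__ = [
    "ScoringConstraints",
    "NucleusLabels",
    "SegmentLabels",
    "SegmentationMetrics",
    "segment_nuclei",
    "score_nucleoli",
    "score_nucleoli_3d",
    "evaluate_segmentation",
]


@dataclass(frozen=True)
class ScoringConstraints:
    """Acceptance rules for candidate nucleolar segments.

    ``min_area``/``max_area`` are µm² in 2D and µm³ in 3D.  With
    ``intensity_mode="relative"`` the required response excess over the local
    annulus is ``min_intensity_above_background × median(source | nucleus)``;
    with ``"absolute"`` it is in raw response units.
    """

    min_area: float = 0.5
    max_area: float = 80.0
    min_intensity_above_background: float = 0.25
    intensity_mode: str = "relative"  # relative | absolute
    background_annulus_width: float = 1.0  # µm
    connectivity: int = 2  # scipy order: 2 = 8-neighbour (2D) / full (3D)
    threshold_mode: str = "otsu"  # otsu | fixed
    fixed_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValidationError("need 0 < min_area < max_area")
        if self.min_intensity_above_background < 0:
            raise ValidationError("intensity floor must be ≥ 0")
        if self.intensity_mode not in ("relative", "absolute"):
            raise ValidationError("intensity_mode must be 'relative' or 'absolute'")
        if self.background_annulus_width <= 0:
            raise ValidationError("annulus width must be positive (µm)")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValidationError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed threshold mode needs fixed_threshold")


@dataclass
class NucleusLabels:
    """Labelled nuclei plus the set of labels touching the field border."""

    labels: np.ndarray
    border_labels: FrozenSet[int] = frozenset()

    @property
    def ids(self) -> List[int]:
        return [int(i) for i in np.unique(self.labels) if i > 0]


@dataclass
class SegmentLabels:
    """Accepted nucleolar segments: contiguous positive labels, 0 = background."""

    labels: np.ndarray
    parent_of: Dict[int, int]
    provenance: str = ""
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    border_nuclei: FrozenSet[int] = frozenset()

    @property
    def n_segments(self) -> int:
        return len(self.parent_of)


def segment_nuclei(
    dapi: ChannelImage,
    min_nucleus_area: float = 15.0,
    threshold: Optional[float] = None,
) -> NucleusLabels:
    """Threshold the nuclear stain into labelled nuclei.

    Global Otsu by default, or a user-supplied fixed ``threshold`` (the
    ImageJ-style mask workflow).  Thresholded foreground is hole-filled,
    objects below ``min_nucleus_area`` (µm² or µm³) are removed, and labels
    touching the field border are flagged (not deleted) so that partial
    nuclei can be excluded from per-cell statistics downstream.
    """
    img = dapi.pixels
    if threshold is None:
        if img.min() == img.max():
            return NucleusLabels(labels=np.zeros(img.shape, dtype=np.int32))
        threshold = threshold_otsu(img)
        fg = img > threshold
    else:
        fg = img > threshold
    if not fg.any():
        return NucleusLabels(labels=np.zeros(img.shape, dtype=np.int32))
    fg = ndimage.binary_fill_holes(fg)
    structure = ndimage.generate_binary_structure(img.ndim, img.ndim)
    labels, n = ndimage.label(fg, structure=structure)
    if n == 0:
        return NucleusLabels(labels=labels.astype(np.int32))
    unit = _pixel_unit(dapi.pixel_size, dapi.z_spacing, img.ndim)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes * unit >= min_nucleus_area)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]
    border = set()
    for ax in range(labels.ndim):
        for sl in (0, -1):
            border.update(int(v) for v in np.unique(labels.take(sl, axis=ax)) if v > 0)
    return NucleusLabels(labels=labels, border_labels=frozenset(border))


def _pixel_unit(pixel_size: float, z_spacing: Optional[float], ndim: int) -> float:
    """Physical size of one pixel/voxel: µm² in 2D, µm³ in 3D."""
    unit = pixel_size**2
    if ndim == 3:
        unit *= z_spacing
    return unit


def _annulus_footprint(width_um: float, pixel_size: float, z_spacing: Optional[float], ndim: int) -> np.ndarray:
    n_xy = max(1, int(round(width_um / pixel_size)))
    if ndim == 2:
        y, x = np.ogrid[-n_xy : n_xy + 1, -n_xy : n_xy + 1]
        return (x * x + y * y) * pixel_size**2 <= width_um**2 + 1e-9
    n_z = max(0, int(width_um // z_spacing))
    z, y, x = np.ogrid[-n_z : n_z + 1, -n_xy : n_xy + 1, -n_xy : n_xy + 1]
    d2 = (z * z_spacing) ** 2 + (y * y + x * x) * pixel_size**2
    return d2 <= width_um**2 + 1e-9


def score_nucleoli(
    median_img: HolesImage,
    nuclei: NucleusLabels,
    constraints: ScoringConstraints = ScoringConstraints(),
) -> SegmentLabels:
    """Accept nucleolar segments from a median-filtered holes image.

    Per nucleus: threshold the template (intranuclear Otsu, or the fixed
    threshold), take connected components, and keep each candidate iff its
    area/volume is within bounds and its mean response exceeds the mean of a
    surrounding intranuclear annulus (excluding all candidates) by the
    configured floor.  Returns contiguously relabelled accepted segments.
    """
    resp = np.asarray(median_img.response, dtype=np.float64)
    labels_img = nuclei.labels
    if resp.shape != labels_img.shape:
        raise ValidationError(
            f"holes image {resp.shape} vs nucleus mask {labels_img.shape}"
        )
    out = np.zeros(resp.shape, dtype=np.int32)
    parent_of: Dict[int, int] = {}
    rows = []
    next_label = 1
    ndim = resp.ndim
    structure = ndimage.generate_binary_structure(ndim, constraints.connectivity if ndim == 2 else ndim)
    unit = _pixel_unit(median_img.pixel_size, median_img.z_spacing, ndim)
    ann_fp = _annulus_footprint(
        constraints.background_annulus_width,
        median_img.pixel_size,
        median_img.z_spacing,
        ndim,
    )
    source = median_img.source

    for nuc_id in (int(i) for i in np.unique(labels_img) if i > 0):
        in_nucleus = labels_img == nuc_id
        vals = resp[in_nucleus]
        if constraints.threshold_mode == "fixed":
            thr = float(constraints.fixed_threshold)
        else:
            if np.ptp(vals) == 0:
                continue
            thr = float(threshold_otsu(vals, nbins=256))
        cand_mask = in_nucleus & (resp > thr)
        if not cand_mask.any():
            continue
        cand_labels, n_cand = ndimage.label(cand_mask, structure=structure)

        if constraints.intensity_mode == "relative":
            if source is None:
                raise ValidationError(
                    "relative intensity mode requires the holes image to carry its source"
                )
            floor = constraints.min_intensity_above_background * float(
                np.median(np.asarray(source, dtype=np.float64)[in_nucleus])
            )
        else:
            floor = constraints.min_intensity_above_background

        for cid in range(1, n_cand + 1):
            cmask = cand_labels == cid
            area = int(cmask.sum()) * unit
            if not (constraints.min_area <= area <= constraints.max_area):
                continue
            ring = ndimage.binary_dilation(cmask, structure=ann_fp)
            ring &= in_nucleus & ~cand_mask
            cand_mean = float(resp[cmask].mean())
            ring_mean = float(resp[ring].mean()) if ring.any() else 0.0
            if cand_mean - ring_mean < floor:
                continue
            out[cmask] = next_label
            parent_of[next_label] = nuc_id
            rows.append(
                {
                    "segment": next_label,
                    "nucleus": nuc_id,
                    "n_pixels": int(cmask.sum()),
                    "area": area,
                    "mean_response": cand_mean,
                    "annulus_mean": ring_mean,
                    "excess": cand_mean - ring_mean,
                    "floor": floor,
                }
            )
            next_label += 1

    stats = pd.DataFrame(
        rows,
        columns=[
            "segment",
            "nucleus",
            "n_pixels",
            "area",
            "mean_response",
            "annulus_mean",
            "excess",
            "floor",
        ],
    )
    return SegmentLabels(
        labels=out,
        parent_of=parent_of,
        provenance=f"{median_img.polarity_used} holes, r={median_img.structuring_radius} µm",
        stats=stats,
        border_nuclei=nuclei.border_labels,
    )


def score_nucleoli_3d(
    stack_holes: HolesImage,
    nuclei_3d: NucleusLabels,
    constraints: ScoringConstraints,
) -> SegmentLabels:
    """Volumetric segment scoring on a z-stack.

    Identical acceptance logic to :func:`score_nucleoli` with volumes in µm³
    and anisotropy-aware (z-spacing scaled) annulus footprints; a
    single-slice stack reduces exactly to the 2D result on that slice.
    """
    if stack_holes.response.ndim != 3:
        raise ValidationError("score_nucleoli_3d expects a 3D holes image")
    if stack_holes.z_spacing is None or stack_holes.z_spacing <= 0:
        raise ValidationError("3D scoring requires z-spacing metadata")
    return score_nucleoli(stack_holes, nuclei_3d, constraints)


@dataclass
class SegmentationMetrics:
    """Greedy one-to-one IoU matching of predicted vs true segments."""

    recall: float
    precision: float
    mean_matched_iou: float
    n_true: int
    n_pred: int
    matches: List[Tuple[int, int, float]]  # (true label, pred label, IoU)
    missed: List[int]  # unmatched true labels
    missed_by_nucleus: Dict[int, List[int]]
    precision_undefined: bool = False


def evaluate_segmentation(
    pred: SegmentLabels,
    truth,
    iou_threshold: float = 0.5,
) -> SegmentationMetrics:
    """Match predicted segments to ground-truth nucleoli by descending IoU.

    ``truth`` is a :class:`~nucleoseg.scene.GroundTruth` (or anything with
    ``nucleolus_labels`` and ``parent_of``).  Matching is greedy one-to-one,
    larger IoU first (ties broken by lower predicted label); a pair counts
    only if its IoU reaches ``iou_threshold``.
    """
    t = np.asarray(truth.nucleolus_labels)
    p = np.asarray(pred.labels)
    if t.shape != p.shape:
        raise ValidationError("prediction and truth shapes differ")
    true_ids = [int(i) for i in np.unique(t) if i > 0]
    pred_ids = [int(i) for i in np.unique(p) if i > 0]
    n_true, n_pred = len(true_ids), len(pred_ids)
    if n_true == 0 and n_pred == 0:
        return SegmentationMetrics(0.0, 0.0, 0.0, 0, 0, [], [], {}, True)

    both = (t > 0) & (p > 0)
    pair_counts: Dict[Tuple[int, int], int] = {}
    if both.any():
        pairs = np.stack([t[both], p[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        pair_counts = {(int(a), int(b)): int(c) for (a, b), c in zip(uniq, counts)}
    t_sizes = {int(i): int((t == i).sum()) for i in true_ids}
    p_sizes = {int(i): int((p == i).sum()) for i in pred_ids}

    cand = []
    for (ti, pi), inter in pair_counts.items():
        union = t_sizes[ti] + p_sizes[pi] - inter
        iou = inter / union
        if iou >= iou_threshold:
            cand.append((iou, ti, pi))
    cand.sort(key=lambda x: (-x[0], x[2], x[1]))

    used_t, used_p = set(), set()
    matches: List[Tuple[int, int, float]] = []
    for iou, ti, pi in cand:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        matches.append((ti, pi, iou))

    missed = [ti for ti in true_ids if ti not in used_t]
    missed_by_nucleus: Dict[int, List[int]] = {}
    parent = getattr(truth, "parent_of", {})
    for ti in missed:
        missed_by_nucleus.setdefault(int(parent.get(ti, 0)), []).append(ti)

    recall = len(matches) / n_true if n_true else 0.0
    precision = len(matches) / n_pred if n_pred else 0.0
    mean_iou = float(np.mean([m[2] for m in matches])) if matches else 0.0
    return SegmentationMetrics(
        recall=recall,
        precision=precision,
        mean_matched_iou=mean_iou,
        n_true=n_true,
        n_pred=n_pred,
        matches=matches,
        missed=missed,
        missed_by_nucleus=missed_by_nucleus,
        precision_undefined=(n_pred == 0),
    )
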