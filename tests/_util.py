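"""Shared test helpers: brute-force morphology oracles and pipeline shortcuts.

The oracles are deliberately naive (per-pixel loops over an explicit
neighbour list with symmetric boundary padding) so they stay independent of
the scipy-based implementation they check.
"""

from __future__ import annotations

import numpy as np

from nucleoseg import (
    ScoringConstraints,
    default_structuring_radius,
    evaluate_segmentation,
    score_nucleoli,
    segment_nuclei,
)
from nucleoseg.pipeline import demarcate

STRUCT_RADIUS = default_structuring_radius(1.5)  # µm, default panel geometry


def disk_footprint(r_px: int) -> np.ndarray:
    y, x = np.ogrid[-r_px : r_px + 1, -r_px : r_px + 1]
    return x * x + y * y <= r_px * r_px


def _local_reduce(img: np.ndarray, fp: np.ndarray, fn) -> np.ndarray:
    ry, rx = fp.shape[0] // 2, fp.shape[1] // 2
    pad = np.pad(img, ((ry, ry), (rx, rx)), mode="symmetric")
    offsets = [(dy - ry, dx - rx) for dy, dx in np.argwhere(fp)]
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = fn(pad[i + ry + dy, j + rx + dx] for dy, dx in offsets)
    return out


def brute_opening(img: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Erosion then dilation, each per-pixel with symmetric padding."""
    return _local_reduce(_local_reduce(img, fp, min), fp, max)


def brute_closing(img: np.ndarray, fp: np.ndarray) -> np.ndarray:
    return _local_reduce(_local_reduce(img, fp, max), fp, min)


def score_scene(images, mode, markers, radius_um=STRUCT_RADIUS, constraints=None):
    """DAPI → nuclei, marker(s) → template, template → accepted segments."""
    nuclei = segment_nuclei(images["dapi"])
    template = demarcate(images, mode, list(markers), radius_um)
    return score_nucleoli(template, nuclei, constraints or ScoringConstraints())


def recall_of(images, truth, mode, markers, radius_um=STRUCT_RADIUS):
    seg = score_scene(images, mode, markers, radius_um)
    return evaluate_segmentation(seg, truth).recall
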