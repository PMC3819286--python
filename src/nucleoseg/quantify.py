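"""Per-nucleolus intensity measurement, QC, normalization and statistics.

Once nucleolar segments exist, every channel of interest is measured on the
*original* (unfiltered) images: one row per segment with its area/volume,
per-channel mean pixel intensity (intensity per area) and integrated
intensity.  Automated QC then removes segments a microscopist would have
discarded by eye: segments of border-truncated nuclei, implausibly small or
large segments, low-contrast segments, and nuclei with an implausible number
of segments.

Treatment effects are expressed relative to a control condition: within each
replicate (independent experiment) and channel, every nucleolar mean is
divided by that replicate's control mean-of-nucleolar-means, so the control
averages to 1 per replicate by construction.  Replicate means are the
statistical units; conditions are compared to control with a two-sided
two-sample t-test on replicate means (Welch by default) and annotated with
the conventional stars (* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .exceptions import PairingError, ValidationError
from .filters import ChannelImage
from .scoring import SegmentLabels

__all__ = [
    "measure_segments",
    "measure_function_channel",
    "qc_filter",
    "normalize_to_control",
    "summarize_and_test",
    "stars",
]


def stars(p: float) -> str:
    """Significance annotation: '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def measure_segments(
    labels: SegmentLabels,
    channels: Mapping[str, ChannelImage],
    scene_id: str = "scene",
    replicate: int = 0,
    condition: str = "control",
) -> pd.DataFrame:
    """One row per segment with per-channel mean and integrated intensity.

    Means are computed over exactly the segment's pixels of the original
    channel images (never of holes images); integrated intensity is the
    float64 pixel sum, so ``mean × n_pixels == integrated`` exactly.
    """
    lab = labels.labels
    ids = sorted(labels.parent_of)
    for name, ch in channels.items():
        if ch.pixels.shape != lab.shape:
            raise ValidationError(
                f"channel {name!r} shape {ch.pixels.shape} != labels {lab.shape}"
            )
    any_ch = next(iter(channels.values())) if channels else None
    if any_ch is not None:
        unit = any_ch.pixel_size**2
        if any_ch.pixels.ndim == 3:
            unit *= any_ch.z_spacing
    else:
        unit = 1.0

    if not ids:
        cols = ["scene_id", "replicate", "condition", "nucleus", "nucleolus",
                "n_pixels", "area_um2"]
        for name in channels:
            cols += [f"mean_{name}", f"integrated_{name}"]
        return pd.DataFrame(columns=cols + ["qc_flags"])

    idx = np.asarray(ids)
    npix = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, idx).astype(np.int64)
    rows = pd.DataFrame(
        {
            "scene_id": scene_id,
            "replicate": replicate,
            "condition": condition,
            "nucleus": [labels.parent_of[i] for i in ids],
            "nucleolus": ids,
            "n_pixels": npix,
            "area_um2": npix * unit,
        }
    )
    for name, ch in channels.items():
        total = ndimage.sum_labels(ch.pixels.astype(np.float64), lab, idx)
        rows[f"mean_{name}"] = total / npix
        rows[f"integrated_{name}"] = total
    rows["qc_flags"] = ""
    return rows


def measure_function_channel(
    labels: SegmentLabels,
    function_channel: ChannelImage,
    table: pd.DataFrame,
    name: str = "eu",
) -> pd.DataFrame:
    """Measure a functional readout (e.g. nascent-RNA labelling) on existing segments.

    Applies the same per-segment machinery to the functional channel and
    joins the resulting ``mean_<name>``/``integrated_<name>`` columns onto
    ``table`` by (scene_id, nucleolus).  Downstream normalization and
    statistics are shared with the marker channels.
    """
    extra = measure_segments(labels, {name: function_channel})
    extra = extra[["nucleolus", f"mean_{name}", f"integrated_{name}"]]
    scene_ids = table["scene_id"].unique()
    if len(scene_ids) != 1:
        raise ValidationError(
            "measure_function_channel joins one scene at a time; "
            f"table contains {len(scene_ids)} scene ids"
        )
    out = table.drop(columns=[f"mean_{name}", f"integrated_{name}"], errors="ignore")
    return out.merge(extra, on="nucleolus", how="left")


@dataclass
class QCReport:
    kept: pd.DataFrame
    excluded: pd.DataFrame  # original rows plus a 'reason' column


def qc_filter(
    table: pd.DataFrame,
    labels: SegmentLabels,
    area_bounds: Optional[Tuple[float, float]] = None,
    min_contrast_excess: Optional[float] = None,
    max_segments_per_nucleus: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Automated stand-in for visual elimination of misidentified nucleoli.

    Drops rows whose parent nucleus touches the field border, whose area is
    outside ``area_bounds``, whose scoring contrast excess fell below
    ``min_contrast_excess`` (in units of the scoring floor; requires the
    segment stats recorded at scoring time), or that belong to a nucleus
    with more than ``max_segments_per_nucleus`` segments.  Returns
    ``(kept, excluded)``; kept rows are never modified, only removed.
    """
    reasons: List[Tuple[int, str]] = []
    t = table

    border = labels.border_nuclei
    for i, row in t.iterrows():
        if row["nucleus"] in border:
            reasons.append((i, "border"))
    if area_bounds is not None:
        lo, hi = area_bounds
        for i, row in t.iterrows():
            if not (lo <= row["area_um2"] <= hi):
                reasons.append((i, "area"))
    if min_contrast_excess is not None and len(labels.stats):
        weak = set(
            labels.stats.loc[
                labels.stats.excess < min_contrast_excess * labels.stats.floor,
                "segment",
            ]
        )
        for i, row in t.iterrows():
            if row["nucleolus"] in weak:
                reasons.append((i, "contrast"))
    counts = t.groupby("nucleus")["nucleolus"].count()
    crowded = set(counts[counts > max_segments_per_nucleus].index)
    for i, row in t.iterrows():
        if row["nucleus"] in crowded:
            reasons.append((i, "count"))

    if not reasons:
        return t, t.iloc[0:0].assign(reason=pd.Series(dtype=str))
    reason_map: Dict[int, str] = {}
    for i, r in reasons:
        reason_map.setdefault(i, r)
    drop_idx = list(reason_map)
    excluded = t.loc[drop_idx].copy()
    excluded["reason"] = [reason_map[i] for i in drop_idx]
    kept = t.drop(index=drop_idx)
    return kept, excluded


def _channel_cols(table: pd.DataFrame, channels: Optional[Sequence[str]]) -> List[str]:
    if channels is not None:
        return [f"mean_{c}" for c in channels]
    return [c for c in table.columns if c.startswith("mean_")]


def normalize_to_control(
    table: pd.DataFrame,
    control_condition: str = "control",
    channels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Divide nucleolar means by the matched control replicate's average.

    Within each replicate and channel, every nucleolar mean (all conditions)
    is divided by that replicate's control mean-of-nucleolar-means, adding
    ``norm_<channel>`` columns.  Raises :class:`PairingError` if any
    replicate present in the table lacks control rows.
    """
    cols = _channel_cols(table, channels)
    if not cols:
        raise ValidationError("no mean_<channel> columns to normalize")
    is_ctrl = table["condition"] == control_condition
    reps = sorted(table["replicate"].unique())
    missing = [r for r in reps if not (is_ctrl & (table["replicate"] == r)).any()]
    if missing:
        raise PairingError(
            f"no {control_condition!r} rows for replicate(s) {missing}; "
            "every replicate needs its own control"
        )
    out = table.copy()
    for col in cols:
        denom = (
            table.loc[is_ctrl].groupby("replicate")[col].mean()
        )
        out["norm_" + col.removeprefix("mean_")] = (
            table[col] / table["replicate"].map(denom)
        )
    return out


@dataclass
class ComparisonResult:
    """Replicate-level summary and test for one condition/channel pair."""

    condition: str
    channel: str
    normalized_mean: float
    sem: float
    n_replicates: int
    n_nucleoli: int
    n_cells: int
    t_statistic: float
    p_value: float
    annotation: str
    warning: str = ""


def summarize_and_test(
    table: pd.DataFrame,
    control_condition: str = "control",
    channels: Optional[Sequence[str]] = None,
    equal_var: bool = False,
    unit: str = "replicate",
) -> pd.DataFrame:
    """Average replicate means per condition and test against control.

    ``table`` must carry ``norm_<channel>`` columns (see
    :func:`normalize_to_control`).  The statistical unit is the replicate
    mean by default (``unit="replicate"``), avoiding pseudoreplication of
    nucleoli; ``unit="nucleolus"`` treats individual nucleoli as units
    instead.  The test is a two-sided two-sample t-test (Welch unless
    ``equal_var``), annotated ``*`` for p < 0.05 and ``**`` for p < 0.01.
    Control rows report mean and SEM but no test.  Conditions with fewer
    than two units are flagged and their test skipped.
    """
    norm_cols = [
        "norm_" + c.removeprefix("mean_") for c in _channel_cols(table, channels)
    ]
    for c in norm_cols:
        if c not in table.columns:
            raise ValidationError(f"missing column {c!r}; run normalize_to_control first")

    rows = []
    conditions = list(dict.fromkeys(table["condition"]))
    for col in norm_cols:
        ch = col.removeprefix("norm_")
        if unit == "replicate":
            units = table.groupby(["condition", "replicate"])[col].mean().reset_index()
            value_of = lambda cond: units.loc[units.condition == cond, col].to_numpy()
        else:
            value_of = lambda cond: table.loc[table.condition == cond, col].to_numpy()
        ctrl_vals = value_of(control_condition)
        for cond in conditions:
            vals = value_of(cond)
            sub = table[table.condition == cond]
            n_nucleoli = len(sub)
            n_cells = sub.groupby(["scene_id", "nucleus"]).ngroups
            warning = ""
            if len(vals) < 2:
                mean, sem = float(np.mean(vals)), float("nan")
                t, p = float("nan"), float("nan")
                warning = "fewer than 2 units: SEM undefined, test skipped"
            else:
                mean = float(np.mean(vals))
                sem = float(stats.sem(vals))
                if cond == control_condition:
                    t, p = float("nan"), float("nan")
                elif np.ptp(vals) == 0 and np.ptp(ctrl_vals) == 0 and np.mean(vals) == np.mean(ctrl_vals):
                    # identical constant samples: no difference by construction
                    t, p = 0.0, 1.0
                else:
                    with warnings.catch_warnings():
                        # near-identical replicate means trip scipy's
                        # catastrophic-cancellation warning; the result is a
                        # legitimate "no difference"
                        warnings.simplefilter("ignore", RuntimeWarning)
                        t, p = stats.ttest_ind(vals, ctrl_vals, equal_var=equal_var)
                    t, p = float(t), float(p)
            rows.append(
                ComparisonResult(
                    condition=cond,
                    channel=ch,
                    normalized_mean=mean,
                    sem=sem,
                    n_replicates=int(len(vals)) if unit == "replicate" else int(sub["replicate"].nunique()),
                    n_nucleoli=n_nucleoli,
                    n_cells=int(n_cells),
                    t_statistic=t,
                    p_value=p,
                    annotation="" if cond == control_condition else stars(p),
                    warning=warning,
                ).__dict__
            )
    return pd.DataFrame(rows)
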