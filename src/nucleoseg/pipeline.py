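"""End-to-end orchestration: simulate → holes → segment → measure → compare.

A :class:`PipelineConfig` (typically loaded from YAML) fixes the scene
description, the demarcation strategy (which marker(s), light/dark/add), the
filter and scoring parameters, the replicate layout and the seeds.  Given the
same config the pipeline is fully deterministic, down to byte-identical CSV
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import io as nio
from .exceptions import PairingError, ValidationError
from .filters import (
    ChannelImage,
    add_images,
    default_structuring_radius,
    detect_dark_holes,
    detect_light_holes,
    median_denoise,
)
from .quantify import measure_segments, normalize_to_control, qc_filter, summarize_and_test
from .scene import FUNCTION, MARKER, NUCLEAR_STAIN, SceneSpec, apply_condition, render_scene
from .scoring import ScoringConstraints, SegmentLabels, segment_nuclei, score_nucleoli

log = logging.getLogger("nucleoseg")

__all__ = ["PipelineConfig", "run_pipeline", "demarcate", "process_scene"]


@dataclass
class PipelineConfig:
    """Everything needed for a reproducible synthetic experiment."""

    scene: SceneSpec = field(default_factory=SceneSpec)
    conditions: Tuple[str, ...] = ("control", "DRB")
    control_condition: str = "control"
    n_replicates: int = 3
    fields_per_replicate: int = 2
    base_seed: int = 0
    demarcation_mode: str = "dark"  # light | dark | add
    demarcation_markers: Tuple[str, ...] = ("cas",)
    measure_channels: Optional[Tuple[str, ...]] = None  # default: markers + function
    structuring_radius_um: Optional[float] = None  # default 1.25× max nucleolus radius
    median_radius: int = 1
    constraints: ScoringConstraints = field(default_factory=ScoringConstraints)
    qc_max_segments_per_nucleus: int = 10
    qc_min_contrast_excess: Optional[float] = None

    def __post_init__(self) -> None:
        roles = [c.role for c in self.scene.channels]
        if roles.count(NUCLEAR_STAIN) != 1:
            raise ValidationError("config needs exactly one nuclear_stain channel")
        if roles.count(MARKER) < 1:
            raise ValidationError("config needs at least one marker channel")
        if self.control_condition not in self.conditions:
            raise PairingError(
                f"control condition {self.control_condition!r} is not among "
                f"conditions {self.conditions}"
            )
        if self.demarcation_mode not in ("light", "dark", "add"):
            raise ValidationError("demarcation_mode must be light, dark or add")
        n_markers = 2 if self.demarcation_mode == "add" else 1
        if len(self.demarcation_markers) != n_markers:
            raise ValidationError(
                f"demarcation mode {self.demarcation_mode!r} needs exactly "
                f"{n_markers} marker(s)"
            )
        names = {c.name for c in self.scene.channels}
        for m in self.demarcation_markers:
            if m not in names:
                raise ValidationError(f"unknown demarcation marker {m!r}")
        if self.n_replicates < 1 or self.fields_per_replicate < 1:
            raise ValidationError("replicate layout counts must be ≥ 1")

    @property
    def stain_channel(self) -> str:
        return next(c.name for c in self.scene.channels if c.role == NUCLEAR_STAIN)

    def measured(self) -> Tuple[str, ...]:
        if self.measure_channels is not None:
            return self.measure_channels
        return tuple(c.name for c in self.scene.channels if c.role in (MARKER, FUNCTION))

    def radius_um(self) -> float:
        if self.structuring_radius_um is not None:
            return self.structuring_radius_um
        return default_structuring_radius(self.scene.nucleolus_radius_range[1])

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "scene" in d:
            d["scene"] = nio.spec_from_yaml(yaml.safe_dump(d["scene"]))
        if "constraints" in d:
            d["constraints"] = ScoringConstraints(**d["constraints"])
        for key in ("conditions", "demarcation_markers", "measure_channels"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["scene"] = yaml.safe_load(nio.spec_to_yaml(self.scene))
        d["constraints"] = dataclasses.asdict(self.constraints)
        for key in ("conditions", "demarcation_markers", "measure_channels"):
            if d.get(key) is not None:
                d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)


def demarcate(
    images: Dict[str, ChannelImage],
    mode: str,
    markers: Sequence[str],
    structuring_radius_um: float,
    median_radius: int = 1,
):
    """Produce the median-filtered compartment template for one scene."""
    if mode == "light":
        holes = detect_light_holes(images[markers[0]], structuring_radius_um)
    elif mode == "dark":
        holes = detect_dark_holes(images[markers[0]], structuring_radius_um)
    elif mode == "add":
        combined = add_images(images[markers[0]], images[markers[1]])
        holes = detect_dark_holes(combined, structuring_radius_um)
    else:
        raise ValidationError(f"unknown demarcation mode {mode!r}")
    return median_denoise(holes, median_radius)


def process_scene(
    images: Dict[str, ChannelImage],
    config: PipelineConfig,
    scene_id: str,
    replicate: int,
    condition: str,
) -> Tuple[pd.DataFrame, pd.DataFrame, SegmentLabels]:
    """Segment one scene and measure its channels; returns (kept, excluded, labels)."""
    nuclei = segment_nuclei(images[config.stain_channel])
    template = demarcate(
        images,
        config.demarcation_mode,
        config.demarcation_markers,
        config.radius_um(),
        config.median_radius,
    )
    segments = score_nucleoli(template, nuclei, config.constraints)
    table = measure_segments(
        segments,
        {name: images[name] for name in config.measured()},
        scene_id=scene_id,
        replicate=replicate,
        condition=condition,
    )
    kept, excluded = qc_filter(
        table,
        segments,
        max_segments_per_nucleus=config.qc_max_segments_per_nucleus,
        min_contrast_excess=config.qc_min_contrast_excess,
    )
    return kept, excluded, segments


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, Path]:
    """Run the full synthetic experiment and write all artifacts.

    Writes ``measurements.csv`` (per-nucleolus, post-QC), ``exclusions.csv``
    (QC log), ``comparison.csv`` (per condition/channel normalized mean, SEM,
    t, p, stars), ``config.yaml`` and ``run_log.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    kept_all: List[pd.DataFrame] = []
    excl_all: List[pd.DataFrame] = []
    seeds: Dict[str, int] = {}
    counts: Dict[str, int] = {}

    for ci, cond in enumerate(config.conditions):
        spec_c = apply_condition(config.scene.replace(condition="control"), cond)
        for rep in range(config.n_replicates):
            for fld in range(config.fields_per_replicate):
                seed = (
                    int(config.base_seed)
                    + 7919 * fld
                    + 104729 * rep
                    + 1299709 * ci
                ) % (2**31)
                scene_id = f"{cond}-r{rep}-f{fld}"
                seeds[scene_id] = seed
                try:
                    images, truth = render_scene(spec_c.replace(seed=seed))
                except Exception as exc:
                    raise RuntimeError(f"stage 'simulate' failed for {scene_id}: {exc}") from exc
                try:
                    kept, excluded, segments = process_scene(
                        images, config, scene_id, rep, cond
                    )
                except Exception as exc:
                    raise RuntimeError(f"stage 'segment/measure' failed for {scene_id}: {exc}") from exc
                counts[scene_id] = segments.n_segments
                kept_all.append(kept)
                excl_all.append(excluded)
                log.info("%s: %d segments (%d rows kept)", scene_id, segments.n_segments, len(kept))

    measurements = pd.concat(kept_all, ignore_index=True)
    exclusions = pd.concat(excl_all, ignore_index=True)
    try:
        normalized = normalize_to_control(measurements, config.control_condition)
        comparison = summarize_and_test(normalized, config.control_condition)
    except Exception as exc:
        raise RuntimeError(f"stage 'statistics' failed: {exc}") from exc

    paths = {
        "measurements": out / "measurements.csv",
        "exclusions": out / "exclusions.csv",
        "comparison": out / "comparison.csv",
        "config": out / "config.yaml",
        "run_log": out / "run_log.yaml",
    }
    normalized.to_csv(paths["measurements"], index=False)
    exclusions.to_csv(paths["exclusions"], index=False)
    comparison.to_csv(paths["comparison"], index=False)
    paths["config"].write_text(config.to_yaml())
    run_log = {
        "seeds": seeds,
        "segments_per_scene": counts,
        "n_rows_kept": int(len(measurements)),
        "n_rows_excluded": int(len(exclusions)),
        "elapsed_s": round(time.time() - t0, 2),
    }
    paths["run_log"].write_text(yaml.safe_dump(run_log, sort_keys=True))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return paths
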