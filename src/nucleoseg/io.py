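"""TIFF/OME-TIFF input-output, scene serialization, and config loading.

Canonical containers: one OME-TIFF per scene with channels as planes and
physical pixel sizes in the OME metadata; ground-truth label masks as 16-bit
TIFF; planted means as CSV; scene specs and pipeline configs as YAML.
Pixel indices are 0-based row-major; physical units are always µm.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ValidationError
from .filters import ChannelImage
from .scene import ChannelDef, GroundTruth, SceneSpec

__all__ = [
    "read_image",
    "write_image",
    "write_scene",
    "read_scene",
    "write_labels",
    "read_labels",
    "spec_to_yaml",
    "spec_from_yaml",
]

_SUPPORTED_DTYPES = ("uint8", "uint16", "int16", "int32")


def write_image(path, img: ChannelImage) -> Path:
    """Write one channel as OME-TIFF with physical-size metadata."""
    path = Path(path)
    meta = {
        "axes": "ZYX" if img.is_3d else "YX",
        "PhysicalSizeX": img.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": img.pixel_size,
        "PhysicalSizeYUnit": "µm",
    }
    if img.is_3d:
        meta["PhysicalSizeZ"] = img.z_spacing
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, img.pixels, ome=True, metadata=meta)
    return path


def _ome_pixel_sizes(tf: tifffile.TiffFile) -> Tuple[Optional[float], Optional[float]]:
    xml = tf.ome_metadata
    if not xml:
        return None, None
    def grab(attr):
        m = re.search(rf'{attr}="([0-9.eE+-]+)"', xml)
        return float(m.group(1)) if m else None
    return grab("PhysicalSizeX"), grab("PhysicalSizeZ")


def read_image(
    path,
    pixel_size: Optional[float] = None,
    z_spacing: Optional[float] = None,
    polarity: str = "unknown",
    name: str = "",
) -> ChannelImage:
    """Read a 2D image or z-stack into a :class:`ChannelImage`.

    Pixel size and z-spacing come from OME metadata when present; explicit
    arguments override.  Only single-channel integer TIFFs are supported —
    RGB or float inputs are rejected with an explicit error.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_px, meta_z = _ome_pixel_sizes(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValidationError(f"cannot read {path} as TIFF: {exc}") from exc
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.dtype == np.uint8:
        raise ValidationError(
            f"{path} looks like an RGB(A) image; expected single-channel grayscale"
        )
    if data.ndim not in (2, 3):
        raise ValidationError(f"{path}: expected 2D or 3D data, got shape {data.shape}")
    if str(data.dtype) not in _SUPPORTED_DTYPES:
        raise ValidationError(
            f"{path}: unsupported dtype {data.dtype}; expected one of {_SUPPORTED_DTYPES}"
        )
    px = pixel_size if pixel_size is not None else meta_px
    if px is None:
        raise ValidationError(
            f"{path}: no pixel size in metadata and no override given"
        )
    zs = z_spacing if z_spacing is not None else meta_z
    if data.ndim == 3 and zs is None:
        raise ValidationError(f"{path}: 3D stack without z-spacing metadata or override")
    return ChannelImage(
        pixels=data,
        pixel_size=float(px),
        z_spacing=float(zs) if data.ndim == 3 else None,
        polarity=polarity,
        name=name or path.stem,
    )


def write_labels(path, labels: np.ndarray) -> Path:
    """Write an integer label mask as 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("more than 65535 labels do not fit a 16-bit mask")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_scene(
    out_dir,
    images: Mapping[str, ChannelImage],
    truth: Optional[GroundTruth] = None,
    spec: Optional[SceneSpec] = None,
    stem: str = "scene",
) -> Path:
    """Write a rendered scene: multichannel OME-TIFF, label masks, sidecar CSV, YAML spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = list(images)
    first = images[names[0]]
    stack = np.stack([images[n].pixels for n in names])
    axes = "CZYX" if first.is_3d else "CYX"
    meta = {
        "axes": axes,
        "Channel": {"Name": names},
        "PhysicalSizeX": first.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": first.pixel_size,
        "PhysicalSizeYUnit": "µm",
    }
    if first.is_3d:
        meta["PhysicalSizeZ"] = first.z_spacing
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(out / f"{stem}.ome.tif", stack, ome=True, metadata=meta)
    if truth is not None:
        write_labels(out / f"{stem}_nuclei.tif", truth.nucleus_labels)
        write_labels(out / f"{stem}_nucleoli.tif", truth.nucleolus_labels)
        truth.planted_mean.to_csv(out / f"{stem}_planted.csv", index=False)
    if spec is not None:
        (out / f"{stem}_spec.yaml").write_text(spec_to_yaml(spec))
    return out / f"{stem}.ome.tif"


def read_scene(path, spec: Optional[SceneSpec] = None) -> Dict[str, ChannelImage]:
    """Read a multichannel OME-TIFF written by :func:`write_scene`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        xml = tf.ome_metadata or ""
        px, zs = _ome_pixel_sizes(tf)
    names = re.findall(r'Channel[^>]*Name="([^"]+)"', xml)
    if data.ndim == 2:
        data = data[None]
    if not names:
        names = [f"ch{i}" for i in range(data.shape[0])]
    polarity = {}
    if spec is not None:
        polarity = {c.name: c.polarity for c in spec.channels}
    out = {}
    for i, n in enumerate(names):
        out[n] = ChannelImage(
            pixels=data[i],
            pixel_size=px if px is not None else (spec.pixel_size if spec else 1.0),
            z_spacing=(zs if zs is not None else (spec.z_spacing if spec else None))
            if data[i].ndim == 3
            else None,
            polarity=polarity.get(n, "unknown"),
            name=n,
        )
    return out


def spec_to_yaml(spec: SceneSpec) -> str:
    d = dataclasses.asdict(spec)
    d["channels"] = [dataclasses.asdict(c) for c in spec.channels]
    d["field_shape"] = list(spec.field_shape)
    d["nucleus_radius_range"] = list(spec.nucleus_radius_range)
    d["nucleoli_per_nucleus_range"] = list(spec.nucleoli_per_nucleus_range)
    d["nucleolus_radius_range"] = list(spec.nucleolus_radius_range)
    d["fragmentation"] = list(spec.fragmentation) if spec.fragmentation else None
    d["nucleolar_level_scale"] = {k: v for k, v in spec.nucleolar_level_scale}
    return yaml.safe_dump(d, sort_keys=True)


def spec_from_yaml(text: str) -> SceneSpec:
    d = yaml.safe_load(text)
    d["channels"] = tuple(ChannelDef(**c) for c in d.get("channels", []))
    for key in ("field_shape", "nucleus_radius_range", "nucleolus_radius_range",
                "nucleoli_per_nucleus_range"):
        if key in d:
            d[key] = tuple(d[key])
    if d.get("fragmentation"):
        d["fragmentation"] = tuple(d["fragmentation"])
    d["nucleolar_level_scale"] = tuple(sorted((d.get("nucleolar_level_scale") or {}).items()))
    return SceneSpec(**d)
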