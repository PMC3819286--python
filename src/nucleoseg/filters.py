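"""Hole-detection image operators.

Nucleoli are demarcated from a single marker channel by one of two residue
filters.  For a marker *enriched* in nucleoli (e.g. nucleolin) the compartment
appears as bright blobs on the dimmer nucleoplasm and is isolated with the
"light holes" filter, a white top-hat: ``source - opening(source)``.  For a
*negative* marker excluded from nucleoli (e.g. CAS, HuR) the compartment
appears as dark holes and is isolated with the "dark holes" filter, a black
top-hat: ``closing(source) - source``.  Either residue ("holes image") is then
median-filtered before segment scoring.

Two negative-marker images can be combined pixel-wise with :func:`add_images`
to deepen nucleolar holes that either marker alone demarcates poorly.

All neighbourhood operators use reflection padding at the image border and a
disk (2D) or an anisotropy-aware ellipsoid (3D) structuring element whose
radius is given in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

__all__ = [
    "ChannelImage",
    "HolesImage",
    "detect_light_holes",
    "detect_dark_holes",
    "median_denoise",
    "add_images",
    "default_structuring_radius",
]

#: polarity tags for marker channels
ENRICHED = "enriched"
EXCLUDED = "excluded"
UNKNOWN = "unknown"

_POLARITIES = (ENRICHED, EXCLUDED, UNKNOWN)


@dataclass
class ChannelImage:
    """A single-marker 2D image or 3D stack with physical pixel metadata.

    Parameters
    ----------
    pixels:
        2D ``(y, x)`` or 3D ``(z, y, x)`` integer array.
    pixel_size:
        Lateral sampling in µm/pixel (x and y are assumed isotropic).
    z_spacing:
        Axial slice spacing in µm; required for 3D stacks.
    polarity:
        ``"enriched"`` (marker concentrated in nucleoli), ``"excluded"``
        (negative marker) or ``"unknown"``.
    """

    pixels: np.ndarray
    pixel_size: float
    z_spacing: Optional[float] = None
    polarity: str = UNKNOWN
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(
                f"expected a 2D image or 3D stack, got ndim={self.pixels.ndim}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError(
                f"expected an integer dtype (8/16-bit camera data), got {self.pixels.dtype}"
            )
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive (µm/pixel)")
        if self.pixels.ndim == 3:
            if self.z_spacing is None or self.z_spacing <= 0:
                raise ValidationError("3D stacks require a positive z_spacing (µm)")
        if self.polarity not in _POLARITIES:
            raise ValidationError(f"polarity must be one of {_POLARITIES}")

    @property
    def is_3d(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def dtype_max(self) -> int:
        return int(np.iinfo(self.pixels.dtype).max)

    def inverted(self) -> "ChannelImage":
        """dtype-max minus value; swaps light and dark holes."""
        inv = (self.dtype_max - self.pixels.astype(np.int64)).astype(self.pixels.dtype)
        pol = {ENRICHED: EXCLUDED, EXCLUDED: ENRICHED}.get(self.polarity, UNKNOWN)
        return replace(self, pixels=inv, polarity=pol)


@dataclass
class HolesImage:
    """Residue of a light/dark hole filter, same geometry as its source.

    ``response`` is non-negative everywhere and zero where the source is
    locally flat at the structuring scale.  The original source pixels are
    retained so that downstream scoring can express intensity floors relative
    to the local (per-nucleus) staining level, which keeps scoring invariant
    to the linear rescaling applied by :func:`add_images`.
    """

    response: np.ndarray
    polarity_used: str  # "light" | "dark"
    structuring_radius: float  # µm
    pixel_size: float
    z_spacing: Optional[float] = None
    source: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def is_3d(self) -> bool:
        return self.response.ndim == 3


def default_structuring_radius(max_nucleolus_radius: float) -> float:
    """Default structuring radius: 1.25× the largest expected nucleolus radius.

    The top-hat residue only captures blobs strictly smaller than the
    structuring element, so the element must comfortably cover a nucleolus.
    """
    return 1.25 * float(max_nucleolus_radius)


def _footprint(radius_um: float, pixel_size: float, z_spacing: Optional[float], ndim: int) -> np.ndarray:
    """Disk (2D) or ellipsoid (3D, anisotropy-aware) footprint for a µm radius."""
    r_xy = radius_um / pixel_size
    if r_xy < 1.0:
        raise ValidationError(
            f"structuring radius {radius_um} µm is smaller than one pixel "
            f"({pixel_size} µm)"
        )
    n_xy = int(np.floor(r_xy))
    if ndim == 2:
        y, x = np.ogrid[-n_xy : n_xy + 1, -n_xy : n_xy + 1]
        return (x * x + y * y) * pixel_size**2 <= radius_um**2 + 1e-9
    n_z = int(np.floor(radius_um / z_spacing))
    z, y, x = np.ogrid[-n_z : n_z + 1, -n_xy : n_xy + 1, -n_xy : n_xy + 1]
    d2 = (z * z_spacing) ** 2 + (y**2 + x**2) * pixel_size**2
    return d2 <= radius_um**2 + 1e-9


def _check_radius(img: ChannelImage, structuring_radius: float) -> np.ndarray:
    if structuring_radius <= 0:
        raise ValidationError("structuring radius must be positive (µm)")
    fp = _footprint(structuring_radius, img.pixel_size, img.z_spacing, img.pixels.ndim)
    if any(f > s for f, s in zip(fp.shape[-2:], img.pixels.shape[-2:])):
        raise ValidationError(
            f"structuring radius {structuring_radius} µm exceeds the image extent"
        )
    return fp


def detect_light_holes(img: ChannelImage, structuring_radius: float) -> HolesImage:
    """White top-hat: ``source - grayscale opening``.

    Bright blobs smaller than the structuring element (nucleoli of an
    enriched marker) yield a positive response; the flat nucleoplasm and any
    structure larger than the element yield zero.
    """
    fp = _check_radius(img, structuring_radius)
    src = img.pixels.astype(np.int64)
    opened = ndimage.grey_opening(src, footprint=fp, mode="reflect")
    return HolesImage(
        response=src - opened,
        polarity_used="light",
        structuring_radius=float(structuring_radius),
        pixel_size=img.pixel_size,
        z_spacing=img.z_spacing,
        source=img.pixels,
    )


def detect_dark_holes(img: ChannelImage, structuring_radius: float) -> HolesImage:
    """Black top-hat: ``grayscale closing - source``.

    Dark blobs smaller than the structuring element (nucleoli of a negative
    marker) yield a positive response.  Identical to applying
    :func:`detect_light_holes` to the dtype-inverted image.
    """
    fp = _check_radius(img, structuring_radius)
    src = img.pixels.astype(np.int64)
    closed = ndimage.grey_closing(src, footprint=fp, mode="reflect")
    return HolesImage(
        response=closed - src,
        polarity_used="dark",
        structuring_radius=float(structuring_radius),
        pixel_size=img.pixel_size,
        z_spacing=img.z_spacing,
        source=img.pixels,
    )


def median_denoise(holes: HolesImage, radius: int = 1) -> HolesImage:
    """Median filter of the holes image over a (2·radius+1)^ndim neighbourhood.

    Removes the isolated pixel-scale residue that the top-hat produces from
    shot noise while preserving blob boundaries; the default 3×3 window is
    adequate for confocal noise levels.
    """
    if int(radius) != radius or radius < 1:
        raise ValidationError("median radius must be a positive integer (pixels)")
    size = 2 * int(radius) + 1
    filt = ndimage.median_filter(holes.response, size=size, mode="reflect")
    return replace(holes, response=filt)


def add_images(a: ChannelImage, b: ChannelImage) -> ChannelImage:
    """Pixel-wise sum of two negative-marker images, rescaled to the dtype range.

    The sum is accumulated at widened precision and mapped linearly onto
    ``[0, dtype_max]`` (min → 0, max → dtype_max), so nothing saturates.
    Summing two markers that are each excluded from nucleoli deepens the
    relative intensity deficit of nucleoli that either marker alone
    demarcates weakly, which is what makes the combined image a better
    dark-hole substrate.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValidationError(
            f"shape mismatch: {a.pixels.shape} vs {b.pixels.shape}"
        )
    if not np.isclose(a.pixel_size, b.pixel_size) or (
        a.z_spacing is not None
        and b.z_spacing is not None
        and not np.isclose(a.z_spacing, b.z_spacing)
    ):
        raise ValidationError("pixel-size mismatch between images to add")
    for img in (a, b):
        if img.polarity != EXCLUDED:
            raise ValidationError(
                "add_images combines negative (excluded) markers; "
                f"got polarity {img.polarity!r} for {img.name or 'an input'}"
            )
    total = a.pixels.astype(np.int64) + b.pixels.astype(np.int64)
    lo, hi = int(total.min()), int(total.max())
    out_max = a.dtype_max
    if hi == lo:
        scaled = np.zeros_like(total)
    else:
        scaled = np.rint((total - lo) * (out_max / (hi - lo))).astype(np.int64)
    return ChannelImage(
        pixels=scaled.astype(a.pixels.dtype),
        pixel_size=a.pixel_size,
        z_spacing=a.z_spacing,
        polarity=EXCLUDED,
        name=f"{a.name}+{b.name}" if (a.name or b.name) else "",
    )
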