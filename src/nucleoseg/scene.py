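"""Synthetic multi-channel fluorescence scenes with per-pixel ground truth.

The generator renders fields of elliptical nuclei, each containing a small
number of disk/spherical nucleoli, across a configurable set of marker
channels: a DAPI-like nuclear stain, a positive nucleolar marker enriched in
nucleoli (nucleolin-like), negative markers excluded from nucleoli (CAS- and
HuR-like) and an optional functional channel reporting nascent-RNA labelling
(EU-like).  Five named experimental conditions re-parameterize the channels to
emulate the qualitative phenotypes of stress and transcription-inhibitor
treatments:

``control``
    untouched geometry and contrasts.
``heat``
    severe heat shock: the negative markers relocate into nucleoli, so their
    nucleolar exclusion contrast collapses toward zero while the positive
    marker keeps demarcating nucleoli.
``DEM``
    oxidative stress: a mild global dimming; marker contrasts retained.
``actinomycinD``
    Pol I inhibition: the positive marker relocates and nucleoli now appear
    as *dark* holes in its channel (contrast sign flips to depleted); the
    functional channel collapses.
``DRB``
    kinase-inhibitor treatment: nucleoli fragment into smaller remnants, the
    positive marker loses all contrast, the negative markers are attenuated
    and each independently fails to demarcate ("misses") a random subset of
    nucleoli — the scenario in which combining two negative markers pays off.

Condition parameters live in the editable :data:`CONDITION_PARAMS` table; the
values are encodings of qualitative observations, not measured quantities.

Rendering is fully deterministic given the spec (including its seed):
intensities are planted in floating point, Gaussian noise (optionally
signal-scaled) is added, and the result is clipped and quantized to the
declared integer dtype.  Ground truth records label masks, the
nucleolus→nucleus parent map, the noise-free planted mean of every nucleolus
in every channel, and the planted per-marker miss sets.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import PlacementError, ValidationError
from .filters import ENRICHED, EXCLUDED, UNKNOWN, ChannelImage

__all__ = [
    "ChannelDef",
    "SceneSpec",
    "GroundTruth",
    "Scene",
    "CONDITIONS",
    "CONDITION_PARAMS",
    "default_channels",
    "contrast_factor",
    "apply_condition",
    "render_scene",
    "render_replicates",
]

NUCLEAR_STAIN = "nuclear_stain"
MARKER = "marker"
FUNCTION = "function"

CONDITIONS = ("control", "heat", "DEM", "actinomycinD", "DRB")

#: Editable encodings of the condition phenotypes (qualitative → numeric).
#: ``excluded_contrast_scale`` multiplies the (negative) contrast of excluded
#: markers; ``enriched_contrast_to`` overwrites the ratio of enriched markers
#: (1.0 = indistinguishable from nucleoplasm); ``invert_enriched`` flips an
#: enriched ratio c>1 into the depleted contrast 1/c − 1; ``level_scale``
#: dims every channel globally; ``function_level_scale`` multiplies the
#: functional channel's nucleolar level (transcription readout);
#: ``fragmentation`` is (remnants per nucleolus, remnant-radius shrink);
#: ``miss_prob`` is the per-nucleolus, per-negative-marker probability of a
#: planted demarcation failure (contrast replaced by ``miss_contrast``).
CONDITION_PARAMS: Dict[str, Dict[str, object]] = {
    "control": {},
    "heat": {"excluded_contrast_scale": 0.2},
    "DEM": {"level_scale": 0.9, "function_level_scale": 0.7},
    "actinomycinD": {"invert_enriched": True, "function_level_scale": 0.2},
    "DRB": {
        "enriched_contrast_to": 1.0,
        "excluded_contrast_scale": 0.625,
        "fragmentation": (2, 0.7),
        "miss_prob": 0.2,
        "miss_contrast": -0.1,
        "function_level_scale": 0.5,
    },
}


def contrast_factor(contrast: float) -> float:
    """Map a signed contrast to a multiplicative nucleolus/nucleoplasm ratio.

    Positive values are ratios directly (+2.0 → nucleolus at 2× nucleoplasm);
    values in [−1, 0] are fractional depletions (−0.8 → 0.2× nucleoplasm).
    """
    c = float(contrast)
    if c > 0:
        return c
    if c >= -1.0:
        return 1.0 + c
    raise ValidationError(f"contrast must be > -1, got {c}")


@dataclass(frozen=True)
class ChannelDef:
    """One marker channel: its role, nucleoplasm level and nucleolar contrast."""

    name: str
    role: str  # nuclear_stain | marker | function
    nucleoplasm_level: float
    contrast: float

    def __post_init__(self) -> None:
        if self.role not in (NUCLEAR_STAIN, MARKER, FUNCTION):
            raise ValidationError(f"unknown channel role {self.role!r}")
        if self.nucleoplasm_level <= 0:
            raise ValidationError("nucleoplasm_level must be positive")
        contrast_factor(self.contrast)  # validates range

    @property
    def factor(self) -> float:
        return contrast_factor(self.contrast)

    @property
    def polarity(self) -> str:
        if self.role != MARKER:
            return UNKNOWN
        if self.factor > 1.0:
            return ENRICHED
        if self.factor < 1.0:
            return EXCLUDED
        return UNKNOWN


def default_channels() -> Tuple[ChannelDef, ...]:
    """The five-channel panel used throughout: DAPI, nucleolin, CAS, HuR, EU.

    Levels are in arbitrary camera units on a 16-bit scale.  The EU-like
    functional channel is strongly nucleolar (ratio 8) because nascent-RNA
    labelling is dominated by rDNA transcription.
    """
    return (
        ChannelDef("dapi", NUCLEAR_STAIN, 3000.0, 1.0),
        ChannelDef("nucleolin", MARKER, 1000.0, 2.0),
        ChannelDef("cas", MARKER, 1000.0, -0.8),
        ChannelDef("hur", MARKER, 1000.0, -0.8),
        ChannelDef("eu", FUNCTION, 300.0, 8.0),
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic field.

    Geometry is expressed in µm; images are rendered on a pixel grid of
    ``field_shape`` at ``pixel_size`` µm/pixel laterally (and ``z_spacing``
    µm/slice for 3D fields).  Identical specs (including ``seed``) render
    bit-identical output.
    """

    field_shape: Tuple[int, ...] = (256, 256)
    pixel_size: float = 0.2
    z_spacing: Optional[float] = None
    n_nuclei: int = 4
    nucleus_radius_range: Tuple[float, float] = (3.5, 5.0)
    nucleoli_per_nucleus_range: Tuple[int, int] = (1, 3)
    nucleolus_radius_range: Tuple[float, float] = (0.8, 1.5)
    background_level: float = 50.0
    channels: Tuple[ChannelDef, ...] = field(default_factory=default_channels)
    noise_sigma: float = 0.0
    poisson_scaling: bool = False
    condition: str = "control"
    fragmentation: Optional[Tuple[int, float]] = None
    miss_prob: float = 0.0
    miss_contrast: float = -0.1
    nucleolar_level_scale: Tuple[Tuple[str, float], ...] = ()
    dtype: str = "uint16"
    allow_border_nuclei: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_shape) not in (2, 3):
            raise ValidationError("field_shape must be 2D or 3D")
        if len(self.field_shape) == 3 and (self.z_spacing is None or self.z_spacing <= 0):
            raise ValidationError("3D fields require a positive z_spacing")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        lo, hi = self.nucleus_radius_range
        nlo, nhi = self.nucleolus_radius_range
        if not (0 < lo <= hi) or not (0 < nlo <= nhi):
            raise ValidationError("radius ranges must be positive and ordered")
        if nhi >= hi:
            raise ValidationError("nucleolus radii must be smaller than nucleus radii")
        klo, khi = self.nucleoli_per_nucleus_range
        if not (1 <= klo <= khi):
            raise ValidationError("nucleoli_per_nucleus_range must be ≥ 1 and ordered")
        if self.n_nuclei < 1:
            raise ValidationError("n_nuclei must be ≥ 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be ≥ 0")
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if not (0 <= self.miss_prob <= 1):
            raise ValidationError("miss_prob must be in [0, 1]")
        if self.fragmentation is not None:
            n_split, shrink = self.fragmentation
            if n_split < 1 or not (0 < shrink < 1):
                raise ValidationError("fragmentation is (n_split ≥ 1, 0 < shrink < 1)")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValidationError("channel names must be unique")
        np.dtype(self.dtype)  # raises on nonsense
        if not np.issubdtype(np.dtype(self.dtype), np.integer):
            raise ValidationError("dtype must be an integer type")

    @property
    def is_3d(self) -> bool:
        return len(self.field_shape) == 3

    def replace(self, **kw) -> "SceneSpec":
        return dataclasses.replace(self, **kw)

    def channel(self, name: str) -> ChannelDef:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def level_scale_for(self, name: str) -> float:
        return dict(self.nucleolar_level_scale).get(name, 1.0)


@dataclass
class GroundTruth:
    """True label masks and planted intensities for one rendered scene."""

    nucleus_labels: np.ndarray
    nucleolus_labels: np.ndarray
    parent_of: Dict[int, int]
    planted_mean: pd.DataFrame  # columns: nucleolus, channel, planted_mean
    missed_by: Dict[str, FrozenSet[int]]
    border_nuclei: FrozenSet[int]

    def nucleolus_ids(self) -> List[int]:
        return sorted(self.parent_of)

    def planted(self, nucleolus: int, channel: str) -> float:
        df = self.planted_mean
        row = df[(df.nucleolus == nucleolus) & (df.channel == channel)]
        return float(row.planted_mean.iloc[0])


class Scene(NamedTuple):
    images: Dict[str, ChannelImage]
    truth: GroundTruth
    spec: SceneSpec


def apply_condition(spec: SceneSpec, condition: Optional[str] = None) -> SceneSpec:
    """Return a spec re-parameterized for a named experimental condition.

    The base spec is interpreted as the unperturbed (control) description;
    the condition's entry in :data:`CONDITION_PARAMS` rewrites contrasts,
    levels, fragmentation and planted miss probabilities accordingly.
    """
    cond = spec.condition if condition is None else condition
    if cond not in CONDITIONS:
        raise ValidationError(
            f"unknown condition {cond!r}; expected one of {CONDITIONS}"
        )
    params = CONDITION_PARAMS[cond]
    if not params:
        return spec.replace(condition=cond)

    level_scale = float(params.get("level_scale", 1.0))
    new_channels = []
    for ch in spec.channels:
        contrast = ch.contrast
        if ch.role == MARKER:
            if ch.polarity == EXCLUDED and "excluded_contrast_scale" in params:
                contrast = contrast * float(params["excluded_contrast_scale"])
            elif ch.polarity == ENRICHED:
                if params.get("invert_enriched"):
                    # ratio c>1 becomes the mirrored depletion 1/c − 1
                    contrast = 1.0 / ch.factor - 1.0
                elif "enriched_contrast_to" in params:
                    contrast = float(params["enriched_contrast_to"])
        new_channels.append(
            dataclasses.replace(
                ch,
                contrast=contrast,
                nucleoplasm_level=ch.nucleoplasm_level * level_scale,
            )
        )

    scale = dict(spec.nucleolar_level_scale)
    if "function_level_scale" in params:
        for ch in spec.channels:
            if ch.role == FUNCTION:
                scale[ch.name] = scale.get(ch.name, 1.0) * float(
                    params["function_level_scale"]
                )

    return spec.replace(
        condition=cond,
        channels=tuple(new_channels),
        fragmentation=params.get("fragmentation", spec.fragmentation),
        miss_prob=float(params.get("miss_prob", spec.miss_prob)),
        miss_contrast=float(params.get("miss_contrast", spec.miss_contrast)),
        nucleolar_level_scale=tuple(sorted(scale.items())),
    )


# ---------------------------------------------------------------------------
# geometry


@dataclass
class _Nucleus:
    center: np.ndarray  # physical µm, (y, x) or (z, y, x)
    semi_axes: np.ndarray  # µm, same order
    theta: float  # in-plane rotation
    nucleoli: List[Tuple[np.ndarray, float]]  # (center µm, radius µm)


def _spacings(spec: SceneSpec) -> np.ndarray:
    if spec.is_3d:
        return np.array([spec.z_spacing, spec.pixel_size, spec.pixel_size])
    return np.array([spec.pixel_size, spec.pixel_size])


def _rotate_inplane(vec: np.ndarray, theta: float) -> np.ndarray:
    """Rotate the trailing (y, x) components of a physical offset."""
    out = vec.copy()
    y, x = vec[-2], vec[-1]
    out[-2] = math.cos(theta) * y - math.sin(theta) * x
    out[-1] = math.sin(theta) * y + math.cos(theta) * x
    return out


_MAX_TRIES = 400

#: minimum physical gap (µm) between distinct nucleoli/remnants so that they
#: stay resolvable as separate components after median filtering (~3 px at
#: the default 0.2 µm sampling); touching-nucleolus splitting is out of scope
_MIN_GAP = 0.6


def _sample_nuclei(spec: SceneSpec, rng: np.random.Generator) -> List[_Nucleus]:
    sp = _spacings(spec)
    extent = np.array(spec.field_shape) * sp  # physical µm
    lo, hi = spec.nucleus_radius_range
    nuclei: List[_Nucleus] = []
    for _ in range(spec.n_nuclei):
        for attempt in range(_MAX_TRIES):
            a = rng.uniform(lo, hi)  # in-plane semi-major
            b = a * rng.uniform(0.75, 1.0)
            theta = rng.uniform(0.0, math.pi)
            if spec.is_3d:
                # keep nuclei thick enough in z that the structuring ellipsoid
                # of the hole filters fits inside the nucleoplasm
                c_ax = a * rng.uniform(0.7, 0.9)
                semi = np.array([c_ax, a, b])
            else:
                semi = np.array([a, b])
            rmax = float(semi.max())
            if spec.allow_border_nuclei:
                center = rng.uniform(np.zeros_like(extent), extent)
            else:
                margin = semi + 0.2  # conservative per-axis bound
                if np.any(extent - 2 * margin <= 0):
                    continue
                center = rng.uniform(margin, extent - margin)
            ok = all(
                np.linalg.norm(center - n.center) >= rmax + float(n.semi_axes.max()) + 0.3
                for n in nuclei
            )
            if ok:
                nuclei.append(_Nucleus(center, semi, theta, []))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(nuclei) + 1}/{spec.n_nuclei} "
                f"after {_MAX_TRIES} tries; field too crowded"
            )
    return nuclei


def _sample_nucleoli(spec: SceneSpec, nuclei: List[_Nucleus], rng: np.random.Generator) -> None:
    klo, khi = spec.nucleoli_per_nucleus_range
    rlo, rhi = spec.nucleolus_radius_range
    for nuc in nuclei:
        k = int(rng.integers(klo, khi + 1))
        r_hi = min(rhi, float(nuc.semi_axes.min()) - 0.3)
        if r_hi < rlo:
            raise PlacementError(
                "nucleolus radii do not fit inside the sampled nucleus; "
                "shrink nucleolus_radius_range or grow the nuclei"
            )
        # place largest-first; restart the whole nucleus on congestion
        for restart in range(60):
            radii = sorted(rng.uniform(rlo, r_hi, size=k), reverse=True)
            placed: List[Tuple[np.ndarray, float]] = []
            for r in radii:
                # sample the centre inside the ellipse shrunk by r (+ margin),
                # in the nucleus frame, then rotate back; the rendered disk is
                # additionally clipped to the nucleus mask so containment is
                # exact at pixel level
                shrunk = nuc.semi_axes - r - 0.1
                for attempt in range(_MAX_TRIES):
                    while True:
                        u = rng.uniform(-1.0, 1.0, size=len(shrunk))
                        if np.sum(u * u) <= 1.0:
                            break
                    center = nuc.center + _rotate_inplane(u * shrunk, nuc.theta)
                    if all(
                        np.linalg.norm(center - c0) >= r + r0 + _MIN_GAP
                        for c0, r0 in placed
                    ):
                        placed.append((center, float(r)))
                        break
                else:
                    break  # congestion: restart this nucleus
            if len(placed) == k:
                nuc.nucleoli = placed
                break
        else:
            raise PlacementError(
                "could not place nucleoli without overlap; reduce "
                "nucleoli_per_nucleus_range or nucleolus radii"
            )


def _inside_shrunk(nuc: _Nucleus, center: np.ndarray, r: float) -> bool:
    """Is a disk of radius r at `center` (conservatively) inside the nucleus?"""
    shrunk = nuc.semi_axes - r - 0.05
    if np.any(shrunk <= 0):
        return False
    u = _rotate_inplane(center - nuc.center, -nuc.theta)
    return float(np.sum((u / shrunk) ** 2)) <= 1.0


def _fragment(spec: SceneSpec, nuclei: List[_Nucleus], rng: np.random.Generator) -> None:
    """Replace nucleoli by disjoint remnants clustered at the parent position.

    Each nucleolus of radius r is replaced by ``n_split`` remnants of radius
    shrink×r arranged on a ring around the parent centre (random orientation,
    spacing that keeps remnants resolvable), staying inside the parent
    nucleus — the drug phenotype of the compartment breaking into smaller
    intranuclear remnants.  A nucleolus whose surroundings are too crowded
    for a ring keeps a single shrunken remnant instead: fragmentation in real
    cells is heterogeneous, and a geometry error would be the wrong outcome.
    """
    if spec.fragmentation is None:
        return
    n_split, shrink = spec.fragmentation
    for nuc in nuclei:
        remnants: List[Tuple[np.ndarray, float]] = []
        for center, r in nuc.nucleoli:
            rr = r * shrink
            if n_split == 1:
                remnants.append((center, rr))
                continue
            # ring radius: remnants pairwise ≥ 2rr + gap apart
            d = max(rr + 0.5 * _MIN_GAP, (2 * rr + _MIN_GAP) / (2 * math.sin(math.pi / n_split)))
            placed_ring = None
            for attempt in range(_MAX_TRIES):
                phi0 = rng.uniform(0, 2 * math.pi)
                pts = []
                for j in range(n_split):
                    phi = phi0 + 2 * math.pi * j / n_split
                    off = np.zeros_like(center)
                    off[-2] = d * math.sin(phi)
                    off[-1] = d * math.cos(phi)
                    pts.append(center + off)
                if all(
                    _inside_shrunk(nuc, p, rr)
                    and all(
                        np.linalg.norm(p - q) >= rr + qr + _MIN_GAP
                        for q, qr in remnants
                    )
                    for p in pts
                ):
                    placed_ring = pts
                    break
            if placed_ring is not None:
                remnants.extend((p, rr) for p in placed_ring)
            else:
                remnants.append((center, rr))  # crowded: partial fragmentation
        nuc.nucleoli = remnants


# ---------------------------------------------------------------------------
# rasterization


def _ellipse_mask(spec: SceneSpec, nuc: _Nucleus, grids: Sequence[np.ndarray]) -> np.ndarray:
    sp = _spacings(spec)
    offs = [g * s - c for g, s, c in zip(grids, sp, nuc.center)]
    if spec.is_3d:
        w, y, x = offs
    else:
        y, x = offs
    ct, st = math.cos(nuc.theta), math.sin(nuc.theta)
    u = ct * y + st * x
    v = -st * y + ct * x
    if spec.is_3d:
        cz, ay, bx = nuc.semi_axes
        return (w / cz) ** 2 + (u / ay) ** 2 + (v / bx) ** 2 <= 1.0
    ay, bx = nuc.semi_axes
    return (u / ay) ** 2 + (v / bx) ** 2 <= 1.0


def _disk_mask(spec: SceneSpec, center: np.ndarray, r: float, grids: Sequence[np.ndarray]) -> np.ndarray:
    sp = _spacings(spec)
    d2 = sum((g * s - c) ** 2 for g, s, c in zip(grids, sp, center))
    return d2 <= r * r


def render_scene(spec: SceneSpec) -> Tuple[Dict[str, ChannelImage], GroundTruth]:
    """Render one field: one image per channel plus its ground truth.

    Intensities are planted noise-free (recorded as ``planted_mean`` per
    nucleolus and channel, after dtype quantization), then Gaussian noise is
    added, and the result is clipped and rounded to the declared dtype.
    """
    rng = np.random.default_rng(spec.seed)
    nuclei = _sample_nuclei(spec, rng)
    _sample_nucleoli(spec, nuclei, rng)
    _fragment(spec, nuclei, rng)

    grids = np.ogrid[tuple(slice(0, s) for s in spec.field_shape)]
    nucleus_labels = np.zeros(spec.field_shape, dtype=np.int32)
    nucleolus_labels = np.zeros(spec.field_shape, dtype=np.int32)
    parent_of: Dict[int, int] = {}
    nucleolus_masks: List[Tuple[int, np.ndarray]] = []
    border: set[int] = set()

    label = 0
    for i, nuc in enumerate(nuclei, start=1):
        m = _ellipse_mask(spec, nuc, grids)
        if not m.any():  # border-allowed nucleus fell outside the field
            continue
        nucleus_labels[m] = i
        edges = [m.take(0, axis=ax).any() or m.take(-1, axis=ax).any() for ax in range(m.ndim)]
        if any(edges):
            border.add(i)
        for center, r in nuc.nucleoli:
            dm = _disk_mask(spec, center, r, grids) & m
            if not dm.any():  # clipped away at the field border
                continue
            label += 1
            nucleolus_labels[dm] = label
            parent_of[label] = i
            nucleolus_masks.append((label, dm))

    # planted per-marker miss sets (DRB-style demarcation failures); a
    # nucleolus is missed by at most one marker, so miss sets are disjoint
    excluded = [c.name for c in spec.channels if c.polarity == EXCLUDED]
    missed_by: Dict[str, set] = {name: set() for name in excluded}
    if spec.miss_prob > 0 and excluded:
        if spec.miss_prob * len(excluded) > 1.0:
            raise ValidationError("miss_prob × number of negative markers must be ≤ 1")
        for lab, _ in nucleolus_masks:
            u = rng.uniform()
            slot = int(u // spec.miss_prob)
            if slot < len(excluded):
                missed_by[excluded[slot]].add(lab)

    info = np.iinfo(np.dtype(spec.dtype))
    images: Dict[str, ChannelImage] = {}
    planted_rows = []
    nucleus_any = nucleus_labels > 0
    for ch in spec.channels:
        img = np.full(spec.field_shape, float(spec.background_level))
        img[nucleus_any] = ch.nucleoplasm_level
        scale = spec.level_scale_for(ch.name)
        for lab, dm in nucleolus_masks:
            contrast = ch.contrast
            if lab in missed_by.get(ch.name, ()):
                contrast = spec.miss_contrast
            level = ch.nucleoplasm_level * contrast_factor(contrast) * scale
            img[dm] = level
            planted_rows.append(
                {
                    "nucleolus": lab,
                    "channel": ch.name,
                    "planted_mean": float(np.clip(round(level), info.min, info.max)),
                }
            )
        if spec.noise_sigma > 0:
            noise = rng.standard_normal(spec.field_shape) * spec.noise_sigma
            if spec.poisson_scaling:
                noise *= np.sqrt(np.maximum(img, 0.0) / ch.nucleoplasm_level)
            img = img + noise
        img = np.clip(np.rint(img), info.min, info.max).astype(spec.dtype)
        images[ch.name] = ChannelImage(
            pixels=img,
            pixel_size=spec.pixel_size,
            z_spacing=spec.z_spacing,
            polarity=ch.polarity,
            name=ch.name,
        )

    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        nucleolus_labels=nucleolus_labels,
        parent_of=parent_of,
        planted_mean=pd.DataFrame(planted_rows, columns=["nucleolus", "channel", "planted_mean"]),
        missed_by={k: frozenset(v) for k, v in missed_by.items()},
        border_nuclei=frozenset(border),
    )
    return images, truth


def render_replicates(
    spec: SceneSpec, n_fields: int, base_seed: int
) -> List[Scene]:
    """Render ``n_fields`` independent fields with derived, recorded seeds.

    Field ``i`` uses seed ``(base_seed + 7919·i) mod 2^31`` (recorded on the
    returned spec, so any field can be re-rendered individually); a single
    field therefore reproduces ``render_scene`` at ``base_seed`` exactly.
    """
    if n_fields < 1:
        raise ValidationError("n_fields must be ≥ 1")
    scenes: List[Scene] = []
    for i in range(n_fields):
        seed = (int(base_seed) + 7919 * i) % (2**31)
        s = spec.replace(seed=seed)
        images, truth = render_scene(s)
        scenes.append(Scene(images=images, truth=truth, spec=s))
    return scenes
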