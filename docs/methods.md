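# Methods

## The demarcation model

A nucleolar marker channel is a grayscale image `f` in which nucleoli differ
from the surrounding nucleoplasm either positively (marker enriched in
nucleoli) or negatively (marker excluded).  Demarcation is a residue
operation with a structuring element `B`:

- light holes (enriched marker): `LH(f) = f − (f ∘ B)` (white top-hat),
- dark holes (excluded marker):  `DH(f) = (f • B) − f` (black top-hat),

where `∘`/`•` are grayscale opening/closing.  Both residues are non-negative,
zero on locally flat regions, invariant to additive background offsets, and
related by exact duality `DH(f) = LH(f_max − f)`.  `B` is a disk in 2D and an
ellipsoid in 3D whose axes are scaled by the voxel spacings, with its radius
given in µm; the default radius is 1.25× the largest expected nucleolus
radius, so that whole nucleoli — and nothing much larger — survive into the
residue.  All neighbourhood operators (top-hats, median, annulus dilation)
use reflection padding at image borders.  The residue is median-filtered
(3×3(×3) by default) before scoring.

Two excluded-marker images can be summed pixel-wise at widened precision and
rescaled linearly onto the dtype range (`add`).  Because the markers' planted
misses are independent, a nucleolus that is a weak hole in one channel is
usually a strong hole in the other, and the sum is a deeper relative hole
than the weaker input everywhere.  Note the combined depth is a weighted
average of the input depths plus the effect of offset removal: it dominates
the *weaker* input at every nucleolus, not necessarily the stronger one.
The operational claim — and the tested property — is about detection: recall
of dark-hole segmentation on the add image is never below the better single
marker and is usually strictly higher.

## Segment scoring

Nuclei come from a global Otsu threshold of the nuclear stain (or a fixed
user threshold in the ImageJ-style mask mode), hole-filled, size-filtered
(default ≥ 15 µm²), connected-component labelled; labels touching the field
border are flagged rather than deleted.  Within each nucleus the
median-filtered residue is thresholded (intranuclear Otsu by default, or a
fixed threshold), components are taken with 8-connectivity in 2D /
26-connectivity in 3D, and a candidate is accepted iff

1. its area is within `[min_area, max_area]` (defaults 0.5–80 µm² in 2D,
   chosen from typical HeLa nucleolar sizes; volumetric bounds are supplied
   explicitly in 3D), and
2. its mean residue exceeds the mean residue of a surrounding 1 µm-wide
   intranuclear annulus (excluding all candidates) by a floor.

The floor is *relative* by default: `0.25 × median(source | nucleus)`, i.e. a
quarter of the nucleus's typical staining level.  A relative floor keeps
scoring invariant to global linear intensity rescaling — in particular to
the rescale inside `add` — where an absolute response floor would not be; an
absolute mode exists.  The 0.25 default sits between the strong hole depth
of healthy negative markers (≈0.8× nucleoplasm) and the collapsed depth
after heat shock (≈0.16×), which is what converts the heat phenotype into
the expected detection failure.  Accepted candidates are relabelled
contiguously with their parent nucleus recorded.

Evaluation against ground truth uses greedy one-to-one matching by
descending IoU (ties: lower predicted label), counting a match at
IoU ≥ 0.5 by default; recall, precision and mean matched IoU are reported,
with per-nucleus miss lists.

## Quantification and statistics

Channels of interest are measured on the original images, never on residues:
per segment, the float64 mean and sum of pixel values (so
`mean × n_pixels = integrated` exactly) plus area/volume in physical units.
Automated QC removes what a microscopist would discard by eye: segments of
border-truncated nuclei, segments outside configured size bounds, segments
whose scoring contrast excess was marginal, and all segments of nuclei with
more than 10 segments.  QC only removes rows; it never edits surviving
values.

Within each replicate (independent experiment) and channel, every nucleolar
mean is divided by that replicate's control mean-of-nucleolar-means, making
the control average exactly 1 per replicate.  The statistical unit is the
replicate mean (individual nucleoli within an experiment are
pseudoreplicates); a per-nucleolus mode exists for exploration.  Conditions
are compared to control with a two-sided two-sample t-test on replicate
means — Welch by default as the variance-robust choice, with a
pooled-variance Student's option.  At n = 3 replicates the Welch
approximation is conservative (empirical type-I ≈ 0.02–0.03 at α = 0.05)
while the pooled test is calibrated (≈ 0.04–0.05); the calibration checks in
the test suite therefore exercise the pooled variant, and the conservatism
of the Welch default is asserted separately.  Significance is annotated
`*` for p < 0.05 and `**` for p < 0.01; no multiple-testing correction is
applied by default (a Holm-style correction can be applied downstream by the
caller on the reported p-values).

## The synthetic scene generator

Scenes are fields of non-overlapping random ellipses (2D) or ellipsoids
(3D, z semi-axis 0.7–0.9× the in-plane semi-major so nuclei stay thicker
than the structuring element in z), each containing 1–3 disk/spherical
nucleoli of 0.8–1.5 µm radius at 0.2 µm/pixel by default — typical HeLa
geometry.  Distinct nucleoli are kept ≥ 0.6 µm apart so they remain
resolvable as separate components after median filtering; splitting touching
nucleoli is explicitly out of scope.  A channel is (role, nucleoplasm level,
contrast): contrast c > 0 is the nucleolus/nucleoplasm ratio (+2.0 → exactly
2×), −1 ≤ c ≤ 0 a fractional depletion (−0.8 → 0.2×).  Default panel: DAPI
(uniform nuclear), nucleolin (+2.0), CAS and HuR (−0.8), and an EU-like
nascent-RNA channel (+8.0 — strongly nucleolar, as rDNA transcription
dominates the signal; a high ratio also keeps per-segment means insensitive
to the few boundary pixels a segmentation can add).

Conditions rewrite the base spec through one editable table
(`CONDITION_PARAMS`); the numbers encode qualitative phenotypes, as no
quantitative contrasts exist to inherit:

| condition | encoding |
| --- | --- |
| control | identity |
| heat | excluded-marker contrast × 0.2 (markers enter nucleoli) |
| DEM | all levels × 0.9; EU nucleolar level × 0.7 |
| actinomycinD | enriched ratio c → 1/c − 1 (positive marker becomes a dark hole); EU × 0.2 |
| DRB | enriched ratio → 1.0 (no contrast); excluded contrast × 0.625; fragmentation (2 remnants, shrink 0.7); per-marker miss probability 0.2 at contrast −0.1; EU × 0.5 |

The fraction of heat-relocated marker is a free parameter, not an inferred
value.  DRB fragmentation replaces each nucleolus with two remnants of 0.7×
its radius on a ring near the parent (inside the nucleus; a crowded
nucleolus keeps a single shrunken remnant — fragmentation in cells is
heterogeneous).  Planted misses are assigned so each nucleolus is missed by
at most one negative marker: the miss sets are random, differ across seeds,
and are disjoint, which is what makes the add-combination comparison sharp.
Rendering plants intensities noise-free (recorded per nucleolus and channel
after dtype quantization), adds Gaussian noise of a configurable sigma —
optionally scaled by `sqrt(I / nucleoplasm_level)` as a Poisson-like model;
the imaging noise model is otherwise unspecified — then clips and rounds to
the declared integer dtype.  Identical specs (including seed) render
bit-identical scenes.

What the generator does *not* emulate: optical PSF blur, photobleaching,
chromatic aberration, chromatin texture, irregular nuclear shapes, partial-
volume boundary intensities.  Passing tests therefore certify the operator
contracts and the pipeline's statistical machinery under idealized contrast
and noise, not performance on real micrographs, where boundary blur and
texture will reduce IoU and make the scoring floor a genuine tuning
parameter.

## Numerical and design choices

- Top-hats computed in int64; responses stay exact for integer inputs (the
  oracle-equivalence tests assert bitwise equality with per-pixel
  brute-force opening/closing).
- "SNR ≈ 5" in the recovery checks means noise sigma = (nucleolus −
  nucleoplasm step)/5 on the demarcation channel (sigma 200 for the default
  panel); "moderate noise" in the quantification checks is sigma = 10% of
  the marker nucleoplasm level (sigma 100).
- Problem sizes in the suite and the reproduction script (25–50 fields per
  condition, 3 replicates × 3 fields per experiment arm with ≥ 30 cells per
  replicate where cell counts matter, 1000 null simulations) keep everything
  desk-scale on a single CPU.
- Degenerate inputs: a blank nuclear stain yields zero nuclei (a warning,
  not an error); an all-flat residue yields zero candidates; empty
  predictions evaluate to recall 0 with precision flagged undefined;
  conditions with fewer than two replicates are flagged and not tested.
- Tie-breaks: greedy IoU matching prefers larger IoU, then lower predicted
  label.  Replicate seeds derive linearly from the base seed and are
  recorded in every output, so any field can be re-rendered alone.
- Pipeline outputs (per-nucleolus CSV, QC exclusion log with reasons,
  comparison CSV, config and run log as YAML) are deterministic down to
  bytes for a fixed config.

## Known limitations

- Per-nucleus Otsu thresholding of the residue assumes at least one genuine
  hole per nucleus drives the bimodality; nuclei with no nucleolus can yield
  a spurious candidate that the intensity floor must reject.
- The volumetric route needs nuclei thicker in z than the structuring
  element; very flat nuclei (or too large a radius) collapse the whole
  nucleoplasm into residue.  Recovered 3D volumes run ~10% low at
  0.25 × 0.25 × 0.3 µm sampling from surface voxelization and median
  erosion.
- Touching nucleoli are not split (no watershed); the generator enforces
  resolvable gaps, real data will not.
- `add` assumes the two negative-marker images are registered and of equal
  geometry; no registration is performed.
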