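# nucleoseg

Nucleolar demarcation and quantification in multi-channel fluorescence
microscopy, for cell biologists measuring how stress and transcription
inhibitors reorganize the nucleolus.

The nucleolus can be outlined from either side of its contrast: a **positive
marker** concentrated in nucleoli (e.g. nucleolin) makes them bright blobs in
the nucleus, while a **negative marker** excluded from nucleoli (e.g. CAS,
HuR) leaves them as dark holes in the nucleoplasm.  `nucleoseg` implements
both detection routes and everything downstream of them:

- **Hole filters** — "detect light holes" is the white top-hat
  `f − opening(f)`, "detect dark holes" the black top-hat `closing(f) − f`,
  with a disk (2D) or anisotropy-aware ellipsoid (3D) structuring element
  sized in µm, followed by median denoising.
- **Arithmetic add** — pixel-wise summation of two negative-marker images at
  widened precision (rescaled, never saturated), which deepens nucleolar
  holes that either marker alone demarcates weakly — the rescue strategy for
  drug-fragmented nucleoli.
- **Segment scoring** — within DAPI-segmented nuclei, connected components of
  the median-filtered holes image are accepted by size constraints
  (µm²/µm³) and intensity above the local intranuclear background annulus,
  in 2D or volumetrically in 3D z-stacks.
- **Quantification** — per-nucleolus mean/integrated intensity of any channel
  measured on the original images, automated QC (border nuclei, size,
  contrast, segment-count caps), normalization to each replicate's control,
  and replicate-level two-sample t-tests annotated `*` (p < 0.05) /
  `**` (p < 0.01).
- **Synthetic benchmark** — a scene generator with per-pixel ground truth
  that emulates control, heat-shock, oxidant (DEM), actinomycin D and DRB
  phenotypes (contrast collapse, marker sign flips, nucleolar fragmentation,
  per-marker planted misses), so the whole pipeline is testable without real
  data.

## Worked example

```python
from nucleoseg import (SceneSpec, render_scene, segment_nuclei,
                       score_nucleoli, evaluate_segmentation,
                       default_structuring_radius)
from nucleoseg.pipeline import demarcate

images, truth = render_scene(SceneSpec(seed=3))      # noise-free control field
nuclei = segment_nuclei(images["dapi"])
radius = default_structuring_radius(1.5)             # 1.875 µm
seg = score_nucleoli(demarcate(images, "light", ["nucleolin"], radius), nuclei)
m = evaluate_segmentation(seg, truth)
print(seg.n_segments, round(m.recall, 2), round(m.mean_matched_iou, 2))
```

prints

```
6 1.0 0.99
```

— all six planted nucleoli are recovered once each, with boundaries matching
the planted disks (mean IoU 0.99).  The scripts in `examples/` walk through
the other capabilities; for instance `examples/02_negative_markers_and_add.py`
prints

```
 cas: mean recall over 10 DRB fields = 0.822
 hur: mean recall over 10 DRB fields = 0.724
 add: mean recall over 10 DRB fields = 0.987
```

showing that summing the two negative markers recovers the nucleoli each
single marker misses after drug-induced fragmentation, and
`examples/03_quantify_drug_effect.py` runs the full pipeline and prints the
normalized per-channel comparison table with SEM and significance stars.

A thin CLI mirrors the stages:

```bash
nucleoseg simulate --condition DRB --fields 3 --seed 7 --out scenes/
nucleoseg segment scenes/field000.ome.tif --marker nucleolin \
    --marker-mode light --radius-um 1.875 --out seg.tif
nucleoseg evaluate seg.tif scenes/field000_nucleoli.tif
nucleoseg run config.yaml --out results/
```

## Layout

```
src/nucleoseg/       library (filters, scene, scoring, quantify, io, pipeline, cli)
examples/            one narrative script per capability
tests/               pytest suite incl. end-to-end acceptance properties
scripts/acceptance.py  headline-number reproduction
docs/methods.md      models, parameters, numerical choices, limitations
```
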