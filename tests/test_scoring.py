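"""Nucleus segmentation, segment scoring (2D/3D), and evaluation metrics."""

import numpy as np
import pytest

from nucleoseg import (
    ChannelImage,
    SceneSpec,
    ScoringConstraints,
    SegmentLabels,
    ValidationError,
    apply_condition,
    detect_light_holes,
    evaluate_segmentation,
    median_denoise,
    render_scene,
    score_nucleoli,
    score_nucleoli_3d,
    segment_nuclei,
)
from nucleoseg.filters import HolesImage
from nucleoseg.pipeline import demarcate

from _util import STRUCT_RADIUS, score_scene


class TestSegmentNuclei:
    def test_blank_image_gives_zero_nuclei(self):
        img = ChannelImage(np.zeros((64, 64), dtype=np.uint16), 0.2)
        assert segment_nuclei(img).labels.max() == 0

    def test_threshold_above_everything_gives_zero_nuclei(self, control_scene):
        images, _ = control_scene
        out = segment_nuclei(images["dapi"], threshold=70000)
        assert out.labels.max() == 0

    def test_recovers_planted_nuclei_with_high_overlap(self):
        for seed in range(5):
            images, truth = render_scene(SceneSpec(seed=seed, n_nuclei=5))
            got = segment_nuclei(images["dapi"])
            assert len(got.ids) == int(truth.nucleus_labels.max())
            for nid in np.unique(truth.nucleus_labels)[1:]:
                tm = truth.nucleus_labels == nid
                # the matching predicted label is the mode within the true mask
                pid = np.bincount(got.labels[tm]).argmax()
                assert pid > 0
                overlap = (tm & (got.labels == pid)).sum() / tm.sum()
                assert overlap >= 0.99

    def test_border_nuclei_flagged_not_deleted(self):
        spec = SceneSpec(seed=7, allow_border_nuclei=True, n_nuclei=6)
        images, truth = render_scene(spec)
        if not truth.border_nuclei:
            pytest.skip("no border nucleus sampled for this geometry")
        got = segment_nuclei(images["dapi"])
        assert got.border_labels  # flagged
        assert len(got.ids) == int(truth.nucleus_labels.max())


class TestScoreNucleoli:
    def test_zero_template_gives_zero_segments(self, control_scene):
        images, _ = control_scene
        nuclei = segment_nuclei(images["dapi"])
        holes = HolesImage(
            response=np.zeros_like(images["dapi"].pixels, dtype=float),
            polarity_used="light",
            structuring_radius=1.0,
            pixel_size=0.2,
            source=images["nucleolin"].pixels,
        )
        seg = score_nucleoli(holes, nuclei)
        assert seg.n_segments == 0

    def test_control_scene_full_recovery(self, control_scene):
        """Noise-free control: one segment per planted nucleolus, IoU ≥ 0.7."""
        images, truth = control_scene
        seg = score_scene(images, "light", ["nucleolin"])
        assert seg.n_segments == len(truth.parent_of)
        m = evaluate_segmentation(seg, truth, iou_threshold=0.7)
        assert m.recall == 1.0 and m.precision == 1.0

    def test_segments_contained_in_parent_nucleus(self, noisy_scene):
        images, _ = noisy_scene
        nuclei = segment_nuclei(images["dapi"])
        seg = score_scene(images, "dark", ["cas"])
        for lab, parent in seg.parent_of.items():
            assert np.all(nuclei.labels[seg.labels == lab] == parent)

    def test_constraint_monotonicity(self, noisy_scene):
        """Tighter size or intensity constraints never add segments."""
        images, _ = noisy_scene
        nuclei = segment_nuclei(images["dapi"])
        tpl = demarcate(images, "light", ["nucleolin"], STRUCT_RADIUS)
        base = score_nucleoli(tpl, nuclei, ScoringConstraints()).n_segments
        tighter_area = score_nucleoli(
            tpl, nuclei, ScoringConstraints(min_area=3.0)
        ).n_segments
        higher_floor = score_nucleoli(
            tpl, nuclei, ScoringConstraints(min_intensity_above_background=0.6)
        ).n_segments
        assert tighter_area <= base and higher_floor <= base

    def test_deterministic(self, noisy_scene):
        images, _ = noisy_scene
        a = score_scene(images, "dark", ["cas"])
        b = score_scene(images, "dark", ["cas"])
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.parent_of == b.parent_of

    def test_add_recovers_single_marker_misses(self):
        """Combined negative markers keep single-marker detections and add misses."""
        checked = 0
        for seed in range(10):
            spec = apply_condition(SceneSpec(seed=seed), "DRB")
            images, truth = render_scene(spec)
            single = evaluate_segmentation(score_scene(images, "dark", ["cas"]), truth)
            combo = evaluate_segmentation(score_scene(images, "add", ["cas", "hur"]), truth)
            found_single = {t for t, _, _ in single.matches}
            found_combo = {t for t, _, _ in combo.matches}
            assert found_single <= found_combo
            misses = set(truth.missed_by["cas"]) & set(single.missed)
            if misses:
                assert misses & found_combo
                checked += 1
        assert checked >= 3

    def test_constraint_validation(self):
        with pytest.raises(ValidationError):
            ScoringConstraints(min_area=5.0, max_area=1.0)
        with pytest.raises(ValidationError):
            ScoringConstraints(background_annulus_width=0.0)
        with pytest.raises(ValidationError):
            ScoringConstraints(threshold_mode="fixed")


def spherical_spec(seed=1, r=1.2, z_spacing=0.3, nz=40):
    return SceneSpec(
        field_shape=(nz, 80, 80),
        pixel_size=0.25,
        z_spacing=z_spacing,
        n_nuclei=1,
        nucleus_radius_range=(3.6, 4.0),
        nucleoli_per_nucleus_range=(1, 1),
        nucleolus_radius_range=(r, r),
        seed=seed,
    )


VOL_CONSTRAINTS = ScoringConstraints(min_area=0.3, max_area=60.0)


class TestScoring3D:
    def test_single_slice_stack_reduces_to_2d(self):
        images2d, _ = render_scene(SceneSpec(seed=11))
        nuclei2d = segment_nuclei(images2d["dapi"])
        seg2d = score_nucleoli(
            demarcate(images2d, "light", ["nucleolin"], STRUCT_RADIUS), nuclei2d
        )
        images3d = {
            k: ChannelImage(v.pixels[None], v.pixel_size, 0.3, v.polarity, v.name)
            for k, v in images2d.items()
        }
        nuclei3d = segment_nuclei(images3d["dapi"], min_nucleus_area=15.0 * 0.3)
        c = ScoringConstraints(min_area=0.5 * 0.3, max_area=80.0 * 0.3)
        seg3d = score_nucleoli_3d(
            demarcate(images3d, "light", ["nucleolin"], STRUCT_RADIUS), nuclei3d, c
        )
        np.testing.assert_array_equal(seg2d.labels, seg3d.labels[0])

    def test_sphere_volume_within_15pct_of_analytic(self):
        r = 1.2
        analytic = 4 / 3 * np.pi * r**3
        images, _ = render_scene(spherical_spec(seed=2, r=r))
        nuclei = segment_nuclei(images["dapi"])
        seg = score_nucleoli_3d(
            demarcate(images, "light", ["nucleolin"], 1.5), nuclei, VOL_CONSTRAINTS
        )
        assert seg.n_segments == 1
        vol = float(seg.stats.area.iloc[0])
        assert abs(vol - analytic) / analytic <= 0.15

    def test_anisotropic_and_isotropic_same_count(self):
        for seed in (1, 3):
            a_img, _ = render_scene(spherical_spec(seed=seed, z_spacing=0.3, nz=40))
            i_img, _ = render_scene(spherical_spec(seed=seed, z_spacing=0.25, nz=48))
            count = []
            for images in (a_img, i_img):
                nuclei = segment_nuclei(images["dapi"])
                seg = score_nucleoli_3d(
                    demarcate(images, "light", ["nucleolin"], 1.5),
                    nuclei,
                    VOL_CONSTRAINTS,
                )
                count.append(seg.n_segments)
            assert count[0] == count[1]

    def test_missing_z_spacing_rejected(self):
        holes = HolesImage(
            response=np.zeros((4, 8, 8)),
            polarity_used="light",
            structuring_radius=1.0,
            pixel_size=0.25,
            z_spacing=None,
        )
        from nucleoseg import NucleusLabels

        with pytest.raises(ValidationError):
            score_nucleoli_3d(holes, NucleusLabels(np.zeros((4, 8, 8), np.int32)),
                              VOL_CONSTRAINTS)


class TestEvaluate:
    def test_perfect_prediction_scores_one(self, control_scene):
        _, truth = control_scene
        pred = SegmentLabels(labels=truth.nucleolus_labels.copy(),
                             parent_of=dict(truth.parent_of))
        m = evaluate_segmentation(pred, truth)
        assert m.recall == 1.0 and m.precision == 1.0 and m.mean_matched_iou == 1.0

    def test_empty_prediction_flagged(self, control_scene):
        _, truth = control_scene
        pred = SegmentLabels(labels=np.zeros_like(truth.nucleolus_labels), parent_of={})
        m = evaluate_segmentation(pred, truth)
        assert m.recall == 0.0 and m.precision == 0.0 and m.precision_undefined

    def test_label_permutation_invariance(self, control_scene):
        _, truth = control_scene
        labels = truth.nucleolus_labels
        ids = [int(i) for i in np.unique(labels) if i > 0]
        rng = np.random.default_rng(0)
        perm = dict(zip(ids, rng.permutation(ids)))
        remap = np.zeros(max(ids) + 1, dtype=np.int32)
        for k, v in perm.items():
            remap[k] = v
        shuffled = SegmentLabels(labels=remap[labels], parent_of={v: truth.parent_of[k] for k, v in perm.items()})
        m0 = evaluate_segmentation(
            SegmentLabels(labels=labels.copy(), parent_of=dict(truth.parent_of)), truth
        )
        m1 = evaluate_segmentation(shuffled, truth)
        assert (m0.recall, m0.precision, m0.mean_matched_iou) == (
            m1.recall, m1.precision, m1.mean_matched_iou
        )
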