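"""Measurement, QC, normalization and replicate-level statistics."""

import numpy as np
import pandas as pd
import pytest

from nucleoseg import (
    ChannelDef,
    ChannelImage,
    PairingError,
    SceneSpec,
    SegmentLabels,
    ValidationError,
    measure_function_channel,
    measure_segments,
    normalize_to_control,
    qc_filter,
    render_scene,
    stars,
    summarize_and_test,
)


def truth_segments(truth):
    """Use ground-truth nucleolus masks as segments (IoU 1 by construction)."""
    return SegmentLabels(
        labels=truth.nucleolus_labels.copy(),
        parent_of=dict(truth.parent_of),
        border_nuclei=truth.border_nuclei,
    )


def measure_scene(spec, channels=("nucleolin", "eu"), **kw):
    images, truth = render_scene(spec)
    seg = truth_segments(truth)
    return measure_segments(seg, {c: images[c] for c in channels}, **kw), images, truth, seg


class TestMeasure:
    def test_noise_free_means_equal_planted(self, control_scene):
        images, truth = control_scene
        table = measure_segments(
            truth_segments(truth), {c: images[c] for c in ("nucleolin", "cas", "eu")}
        )
        for _, row in table.iterrows():
            for ch in ("nucleolin", "cas", "eu"):
                assert row[f"mean_{ch}"] == truth.planted(row["nucleolus"], ch)

    def test_mean_times_pixels_equals_integrated(self, noisy_scene):
        images, truth = noisy_scene
        table = measure_segments(truth_segments(truth), {"eu": images["eu"]})
        np.testing.assert_allclose(
            table["mean_eu"] * table["n_pixels"], table["integrated_eu"], rtol=0, atol=1e-9
        )

    def test_shape_mismatch_rejected(self, control_scene):
        images, truth = control_scene
        bad = ChannelImage(np.zeros((10, 10), dtype=np.uint16), 0.2)
        with pytest.raises(ValidationError):
            measure_segments(truth_segments(truth), {"x": bad})

    def test_monte_carlo_coverage_of_segment_means(self):
        """Mean over n noisy pixels lands within ±4 s/√n essentially always."""
        sigma, hits, total = 150.0, 0, 0
        for seed in range(200):
            spec = SceneSpec(field_shape=(128, 128), n_nuclei=1, seed=seed,
                             noise_sigma=sigma, nucleoli_per_nucleus_range=(1, 1))
            table, _, truth, _ = measure_scene(spec, channels=("cas",))
            row = table.iloc[0]
            planted = truth.planted(row["nucleolus"], "cas")
            hits += abs(row["mean_cas"] - planted) <= 4 * sigma / np.sqrt(row["n_pixels"])
            total += 1
        assert hits / total >= 0.99

    def test_function_channel_joins_same_machinery(self, control_scene):
        images, truth = control_scene
        seg = truth_segments(truth)
        table = measure_segments(seg, {"nucleolin": images["nucleolin"]})
        out = measure_function_channel(seg, images["nucleolin"], table, name="fn")
        np.testing.assert_allclose(out["mean_fn"], out["mean_nucleolin"])


class TestQC:
    def test_clean_table_unchanged(self, control_scene):
        images, truth = control_scene
        seg = truth_segments(truth)
        table = measure_segments(seg, {"eu": images["eu"]})
        kept, excluded = qc_filter(table, seg)
        pd.testing.assert_frame_equal(kept, table)
        assert excluded.empty

    def test_oversized_artifact_dropped_with_area_reason(self, control_scene):
        images, truth = control_scene
        seg = truth_segments(truth)
        table = measure_segments(seg, {"eu": images["eu"]})
        bad = table["nucleolus"].iloc[0]
        table.loc[table["nucleolus"] == bad, "area_um2"] = 500.0
        kept, excluded = qc_filter(table, seg, area_bounds=(0.5, 80.0))
        assert set(excluded["nucleolus"]) == {bad}
        assert list(excluded["reason"]) == ["area"]
        assert bad not in set(kept["nucleolus"])

    def test_border_nucleus_segments_dropped(self):
        spec = SceneSpec(seed=8, allow_border_nuclei=True, n_nuclei=6)
        images, truth = render_scene(spec)
        if not truth.border_nuclei:
            pytest.skip("no border nucleus sampled")
        seg = truth_segments(truth)
        table = measure_segments(seg, {"eu": images["eu"]})
        kept, excluded = qc_filter(table, seg)
        assert set(excluded["reason"]) == {"border"}
        assert set(excluded["nucleus"]) <= set(truth.border_nuclei)
        assert not set(kept["nucleus"]) & set(truth.border_nuclei)

    def test_qc_never_alters_surviving_rows(self, control_scene):
        images, truth = control_scene
        seg = truth_segments(truth)
        table = measure_segments(seg, {"eu": images["eu"]})
        table.loc[table.index[0], "area_um2"] = 500.0
        kept, _ = qc_filter(table, seg, area_bounds=(0.5, 80.0))
        pd.testing.assert_frame_equal(kept, table.loc[kept.index])


def toy_table(cond_means, noise=0.0, seed=0, n_nucleoli=5):
    """Measurement table with known per-condition true means, 3 replicates."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, mu in cond_means.items():
        for rep in range(3):
            for k in range(n_nucleoli):
                rows.append(
                    dict(scene_id=f"{cond}-{rep}", replicate=rep, condition=cond,
                         nucleus=k // 2, nucleolus=k + 1,
                         mean_x=mu * (1 + noise * rng.standard_normal()))
                )
    return pd.DataFrame(rows)


class TestNormalize:
    def test_control_normalizes_to_exactly_one(self):
        t = toy_table({"control": 2.0}, noise=0.05)
        out = normalize_to_control(t, "control")
        per_rep = out.groupby("replicate")["norm_x"].mean()
        np.testing.assert_allclose(per_rep, 1.0)

    def test_halved_treatment_recovers_half(self):
        t = toy_table({"control": 2.0, "drug": 1.0})
        out = normalize_to_control(t, "control")
        assert np.allclose(out.loc[out.condition == "drug", "norm_x"], 0.5)

    def test_missing_control_replicate_raises_pairing_error(self):
        t = toy_table({"control": 1.0, "drug": 0.5})
        t = t[~((t.condition == "control") & (t.replicate == 1))]
        with pytest.raises(PairingError):
            normalize_to_control(t, "control")

    def test_normalization_idempotent(self):
        t = toy_table({"control": 2.0, "drug": 1.2}, noise=0.03)
        once = normalize_to_control(t, "control")
        again = once.drop(columns=["mean_x"]).rename(columns={"norm_x": "mean_x"})
        twice = normalize_to_control(again, "control")
        np.testing.assert_allclose(twice["norm_x"], once["norm_x"])

    def test_planted_forty_pct_reduction_both_channels(self):
        """Two channels dropped to 0.6× control recover 0.6 within 5% under noise."""
        b23 = ChannelDef("b23", "marker", 800.0, 3.0)
        rows = []
        for cond, scale in (("control", 1.0), ("DRB", 0.6)):
            for rep in range(3):
                spec = SceneSpec(
                    seed=rep + (0 if cond == "control" else 100),
                    noise_sigma=100.0,
                    channels=tuple(list(SceneSpec().channels) + [b23]),
                    nucleolar_level_scale=(("b23", scale), ("nucleolin", scale)),
                )
                table, *_ = measure_scene(spec, channels=("b23", "nucleolin"),
                                          replicate=rep, condition=cond,
                                          scene_id=f"{cond}-{rep}")
                rows.append(table)
        out = normalize_to_control(pd.concat(rows, ignore_index=True), "control")
        res = summarize_and_test(out, "control")
        got = res[res.condition == "DRB"].set_index("channel")["normalized_mean"]
        for ch in ("b23", "nucleolin"):
            assert abs(got[ch] - 0.6) / 0.6 <= 0.05


class TestSummarizeAndTest:
    def test_identical_groups_give_t0_p1(self):
        t = toy_table({"control": 1.0, "sham": 1.0}, noise=0.0)
        out = normalize_to_control(t, "control")
        res = summarize_and_test(out, "control")
        row = res[res.condition == "sham"].iloc[0]
        assert row.t_statistic == 0.0 and row.p_value == 1.0 and row.annotation == ""

    def test_welch_matches_closed_form_oracle(self):
        """Control replicate means {1,1,1} vs treated {0.5,0.6,0.7}: df=2 closed form."""
        rows = []
        for cond, means in (("control", [1.0, 1.0, 1.0]), ("drug", [0.5, 0.6, 0.7])):
            for rep, mu in enumerate(means):
                rows.append(dict(scene_id=f"{cond}-{rep}", replicate=rep,
                                 condition=cond, nucleus=1, nucleolus=1,
                                 mean_x=mu, norm_x=mu))
        res = summarize_and_test(pd.DataFrame(rows), "control", channels=["x"])
        row = res[res.condition == "drug"].iloc[0]
        # hand computation: se = s/√3 with s = 0.1, t = −0.4/se, df = 2
        se = 0.1 / np.sqrt(3)
        t_expect = -0.4 / se
        # survival of Student t with df=2: sf(x) = (1 − x/√(2+x²))/2
        p_expect = 1 - abs(t_expect) / np.sqrt(2 + t_expect**2)
        assert row.t_statistic == pytest.approx(t_expect, rel=1e-9)
        assert row.p_value == pytest.approx(p_expect, rel=1e-9)
        assert row.annotation == "*"

    def test_single_replicate_flagged_not_tested(self):
        t = toy_table({"control": 1.0, "drug": 0.5})
        t = t[~((t.condition == "drug") & (t.replicate > 0))]
        out = normalize_to_control(t, "control")
        res = summarize_and_test(out, "control")
        row = res[res.condition == "drug"].iloc[0]
        assert np.isnan(row.p_value) and row.warning

    def test_unit_coherence_under_global_rescale(self):
        """Scaling all intensities by a constant changes no normalized statistic."""
        t = toy_table({"control": 2.0, "drug": 1.3}, noise=0.04)
        res1 = summarize_and_test(normalize_to_control(t, "control"), "control")
        t2 = t.assign(mean_x=t.mean_x * 37.0)
        res2 = summarize_and_test(normalize_to_control(t2, "control"), "control")
        for col in ("normalized_mean", "sem", "t_statistic", "p_value"):
            np.testing.assert_allclose(res1[col].astype(float), res2[col].astype(float))

    def test_star_thresholds(self):
        assert stars(0.049) == "*"
        assert stars(0.01) == "*"
        assert stars(0.0099) == "**"
        assert stars(0.05) == ""
        assert stars(float("nan")) == ""
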