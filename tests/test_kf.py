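import numpy as np
import pytest
from dataclasses import replace

from fltseg import (
    DynamicImage,
    KFConfig,
    KineticClass,
    KineticClassSet,
    builtin_schedules,
    classify_voxels,
    dice,
    generate_phantom,
    get_preset,
    load_presets,
    mahalanobis_distance,
    make_frame_schedule,
    reclassify_within_mask,
    restrict_time_window,
    run_kf_preset,
    segment_lesion_kf,
    temporal_smooth,
    true_class_set,
)
from fltseg.kf import LabelImage


def _kc(mu, sigma, sched, tissue="tumour"):
    return KineticClass(tissue, np.asarray(mu, float), np.asarray(sigma, float), sched)


class TestMahalanobis:
    def test_zero_at_class_mean(self):
        sched = make_frame_schedule([(3, 60)])
        kc = _kc([1.0, 2.0, 3.0], [0.5, 0.5, 0.5], sched)
        assert mahalanobis_distance(np.array([1.0, 2.0, 3.0]), kc) == 0.0

    def test_single_frame(self):
        sched = make_frame_schedule([(1, 60)])
        kc = _kc([1.0], [1.0], sched)
        assert mahalanobis_distance(np.array([3.0]), kc) == pytest.approx(2.0)

    def test_two_frames_direct_sum(self):
        sched = make_frame_schedule([(2, 60)])
        kc = _kc([1.0, 3.0], [1.0, 2.0], sched)
        d = mahalanobis_distance(np.array([2.0, 5.0]), kc)
        assert d == pytest.approx(np.sqrt(2.0))

    def test_sigma_scale_divides_distance(self):
        sched = make_frame_schedule([(2, 60)])
        kc = _kc([0.0, 0.0], [1.0, 1.0], sched)
        p = np.array([3.0, 4.0])
        assert mahalanobis_distance(p, kc, 2.0) == pytest.approx(
            mahalanobis_distance(p, kc, 1.0) / 2.0
        )

    def test_degenerate_sigma_in_scope_rejected(self):
        sched = make_frame_schedule([(2, 60)])
        kc = _kc([1.0, 1.0], [0.0, 1.0], sched)
        with pytest.raises(ValueError, match="degenerate"):
            mahalanobis_distance(np.array([1.0, 1.0]), kc)
        # out-of-scope zero sigma is fine
        assert mahalanobis_distance(
            np.array([1.0, 2.0]), kc, frame_indices=np.array([1])
        ) == pytest.approx(1.0)


class TestTemporalSmooth:
    def _img(self, tac):
        sched = make_frame_schedule([(len(tac), 60)])
        data = np.asarray(tac, float)[None, None, None, :]
        return DynamicImage(data, (1, 1, 1), sched)

    def test_constant_unchanged(self):
        out = temporal_smooth(self._img([2.0, 2.0, 2.0, 2.0]))
        np.testing.assert_array_equal(out.data[0, 0, 0], [2.0] * 4)

    def test_three_point_mean_with_edge_rule(self):
        out = temporal_smooth(self._img([0.0, 3.0, 0.0]))
        np.testing.assert_allclose(out.data[0, 0, 0], [1.5, 1.0, 1.5])

    def test_single_frame_identity(self):
        out = temporal_smooth(self._img([7.0]))
        np.testing.assert_array_equal(out.data[0, 0, 0], [7.0])

    def test_two_frames(self):
        out = temporal_smooth(self._img([0.0, 4.0]))
        np.testing.assert_allclose(out.data[0, 0, 0], [2.0, 2.0])


class TestTimeWindow:
    def test_full_window_keeps_all(self):
        sched = builtin_schedules()["vumc_trt_39"]
        idx = restrict_time_window(sched, (0.0, 61.0))
        np.testing.assert_array_equal(idx, np.arange(39))

    @pytest.mark.parametrize("window", [(30.0, 60.0), (0.0, 5.0), (15.0, 60.0)])
    def test_enumerated_midtime_oracle(self, window):
        sched = builtin_schedules()["vumc_trt_39"]
        idx = restrict_time_window(sched, window)
        expected = [
            i
            for i, m in enumerate(sched.mid_times_min)
            if window[0] <= m <= window[1]
        ]
        np.testing.assert_array_equal(idx, expected)
        assert len(expected) > 0

    def test_empty_selection_rejected(self):
        sched = builtin_schedules()["vumc_trt_39"]
        with pytest.raises(ValueError, match="no frame"):
            restrict_time_window(sched, (60.5, 61.0))
        with pytest.raises(ValueError):
            restrict_time_window(sched, (30.0, 20.0))


def _no_reclass(preset="KF1"):
    return replace(get_preset(preset), reclass_global={})


class TestClassifyVoxels:
    def test_noiseless_matched_classes_recover_truth(
        self, noiseless_phantom, matched_classes, noiseless_spec
    ):
        lab = classify_voxels(
            noiseless_phantom.image, matched_classes, _no_reclass(),
            dose_mbq=noiseless_spec.dose_mbq,
        )
        truth_names = np.array(
            [noiseless_phantom.label_table[i] for i in range(len(noiseless_phantom.label_table))]
        )
        got_names = np.array([lab.table[i] for i in range(len(lab.table))])
        assert np.array_equal(
            got_names[lab.labels], truth_names[noiseless_phantom.truth_labels]
        )

    def test_tie_breaks_to_first_class(self):
        sched = make_frame_schedule([(2, 60)])
        a = _kc([0.0, 0.0], [1.0, 1.0], sched, "first")
        b = _kc([2.0, 2.0], [1.0, 1.0], sched, "second")
        kcs = KineticClassSet((a, b))
        img = DynamicImage(np.full((1, 1, 1, 2), 1.0), (1, 1, 1), sched)
        cfg = KFConfig(class_subset=("first", "second"))
        lab = classify_voxels(img, kcs, cfg)
        assert lab.table[int(lab.labels[0, 0, 0])] == "first"

    def test_vectorised_equals_brute_force(self, small_spec_factory):
        spec = small_spec_factory(noise_level=0.7, seed=5)
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        cfg = _no_reclass()
        lab = classify_voxels(out.image, kcs, cfg, dose_mbq=spec.dose_mbq)
        # independent per-voxel loop over the distance definition
        norm = out.image.data / spec.dose_mbq
        flat = norm.reshape(-1, out.image.n_frames)
        expect = np.empty(flat.shape[0], dtype=int)
        for v in range(flat.shape[0]):
            dists = [mahalanobis_distance(flat[v], c) for c in kcs.classes]
            expect[v] = int(np.argmin(dists))
        np.testing.assert_array_equal(lab.labels.ravel(), expect)

    def test_uniform_sigma_scaling_preserves_labels(self, small_spec_factory):
        spec = small_spec_factory(noise_level=0.7, seed=9)
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        labels = [
            classify_voxels(
                out.image, kcs, replace(_no_reclass(), sigma_scale=s),
                dose_mbq=spec.dose_mbq,
            ).labels
            for s in (0.5, 1.0, 2.0)
        ]
        np.testing.assert_array_equal(labels[0], labels[1])
        np.testing.assert_array_equal(labels[1], labels[2])

    def test_removing_a_class_only_reassigns_its_voxels(self, small_spec_factory):
        spec = small_spec_factory(noise_level=0.7, seed=13)
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        full = classify_voxels(out.image, kcs, _no_reclass(), dose_mbq=spec.dose_mbq)
        reduced = classify_voxels(
            out.image, kcs, replace(_no_reclass(), omit_classes=("liver",)),
            dose_mbq=spec.dose_mbq,
        )
        full_names = np.array([full.table[i] for i in range(len(full.table))])[full.labels]
        red_names = np.array([reduced.table[i] for i in range(len(reduced.table))])[reduced.labels]
        changed = full_names != red_names
        assert np.all(full_names[changed] == "liver")
        assert "liver" not in reduced.table.values()

    def test_reclass_global_applied(self, noiseless_phantom, matched_classes, noiseless_spec):
        lab = classify_voxels(
            noiseless_phantom.image, matched_classes, get_preset("KF1"),
            dose_mbq=noiseless_spec.dose_mbq,
        )
        assert not lab.mask("vertebrae").any()  # all vertebrae relabelled tumour
        vert_truth = noiseless_phantom.truth_labels == {
            v: k for k, v in noiseless_phantom.label_table.items()
        }["vertebrae"]
        assert np.all(lab.mask("tumour")[vert_truth])

    def test_window_plus_degenerate_sigma(self):
        sched = make_frame_schedule([(2, 60)])
        kcs = KineticClassSet((_kc([1.0, 1.0], [0.0, 1.0], sched),))
        img = DynamicImage(np.ones((1, 1, 1, 2)), (1, 1, 1), sched)
        with pytest.raises(ValueError, match="degenerate"):
            classify_voxels(img, kcs, KFConfig())
        # restricting the window away from the zero-sigma frame succeeds
        lab = classify_voxels(img, kcs, KFConfig(time_window_min=(1.0, 2.0)))
        assert lab.labels.shape == (1, 1, 1)


class TestReclassifyWithinMask:
    @pytest.fixture()
    def labels(self):
        lab = np.array([[[0, 1], [2, 1]]])
        return LabelImage(lab, {0: "lung", 1: "liver", 2: "tumour"})

    def test_empty_map_is_identity(self, labels):
        out = reclassify_within_mask(labels, np.ones((1, 2, 2), bool), {})
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_only_inside_mask_relabelled(self, labels):
        mask = np.zeros((1, 2, 2), bool)
        mask[0, 0, 1] = True  # one of the two liver voxels
        out = reclassify_within_mask(labels, mask, {"liver": "tumour"})
        assert out.table[int(out.labels[0, 0, 1])] == "tumour"
        assert out.table[int(out.labels[0, 1, 1])] == "liver"

    def test_voxel_count_conserved_and_idempotent(self, labels):
        mask = np.ones((1, 2, 2), bool)
        out1 = reclassify_within_mask(labels, mask, {"liver": "tumour"})
        out2 = reclassify_within_mask(out1, mask, {"liver": "tumour"})
        assert out1.labels.size == labels.labels.size
        np.testing.assert_array_equal(out1.labels, out2.labels)

    def test_unknown_target_rejected(self, labels):
        with pytest.raises(KeyError):
            reclassify_within_mask(labels, np.ones((1, 2, 2), bool), {"liver": "bone"})


class TestSegmentLesion:
    def _labels(self, arr, table):
        return LabelImage(np.asarray(arr), table)

    def test_all_tumour_interior(self):
        lab = self._labels(np.full((2, 2, 2), 1), {0: "lung", 1: "tumour"})
        mask = np.zeros((2, 2, 2), bool)
        mask[0] = True
        r = segment_lesion_kf(lab, mask, KFConfig(), (2.0, 2.0, 2.0))
        assert r.detected and r.n_voxels == 4
        np.testing.assert_array_equal(r.voi, mask)
        assert r.volume_cm3 == pytest.approx(4 * 8 / 1000.0)

    def test_no_tumour_means_undetected(self):
        lab = self._labels(np.zeros((2, 2, 2), int), {0: "lung", 1: "tumour"})
        r = segment_lesion_kf(lab, np.ones((2, 2, 2), bool), KFConfig())
        assert not r.detected and r.n_voxels == 0

    def test_in_mask_reclass_included(self):
        lab = self._labels(np.full((1, 1, 2), 2), {0: "lung", 1: "tumour", 2: "liver"})
        cfg = KFConfig(reclass_in_mask={"liver": "tumour"})
        r = segment_lesion_kf(lab, np.ones((1, 1, 2), bool), cfg)
        assert r.detected and r.n_voxels == 2

    def test_empty_mask_rejected(self):
        lab = self._labels(np.zeros((1, 1, 1), int), {0: "tumour"})
        with pytest.raises(ValueError, match="empty"):
            segment_lesion_kf(lab, np.zeros((1, 1, 1), bool), KFConfig())


class TestPresets:
    def test_table_of_nine(self):
        presets = load_presets()
        assert sorted(presets) == [f"KF{i}" for i in range(1, 10)]
        assert presets["KF8"].kc_source == "vumc"
        assert presets["KF9"].kc_source == "vumc"
        assert presets["KF2"].temporal_smoothing
        assert presets["KF3"].resample_direction == "scan_to_classes"
        assert presets["KF4"].time_window_min == (9.0, 60.0)
        assert presets["KF5"].time_window_min == (20.0, 60.0)
        assert presets["KF6"].omit_classes == ("liver",)
        assert set(presets["KF7"].omit_classes) == {"liver", "vertebrae"}
        assert presets["KF9"].reclass_in_mask == {"liver": "tumour", "vertebrae": "tumour"}

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            get_preset("KF42")


class TestRunPreset:
    def test_kf1_detects_all_noiseless_lesions(
        self, noiseless_phantom, matched_classes, noiseless_spec
    ):
        out = noiseless_phantom
        res = run_kf_preset(
            out.image, {"hammersmith": matched_classes}, out.lesion_masks, "KF1",
            dose_mbq=noiseless_spec.dose_mbq,
        )
        assert all(r.detected for r in res.values())
        for lid, r in res.items():
            assert dice(r.voi, out.true_lesion_masks[lid]) == 1.0

    def test_kf7_labels_no_liver_or_vertebrae(self, small_spec_factory):
        spec = small_spec_factory(noise_level=0.7, seed=21)
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        cfg = get_preset("KF7")
        lab = classify_voxels(out.image, kcs, cfg, dose_mbq=spec.dose_mbq)
        assert "liver" not in lab.table.values()
        assert "vertebrae" not in lab.table.values()

    def test_all_presets_run_on_matched_phantom(self, small_spec_factory):
        spec = small_spec_factory(noise_level=0.3, seed=2)
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        sources = {"hammersmith": kcs, "vumc": kcs}
        for name in load_presets():
            res = run_kf_preset(out.image, sources, out.lesion_masks, name,
                                dose_mbq=spec.dose_mbq)
            assert set(res) == set(out.lesion_masks)

    def test_missing_kc_source_rejected(self, noiseless_phantom, matched_classes):
        with pytest.raises(KeyError, match="source"):
            run_kf_preset(
                noiseless_phantom.image, {"hammersmith": matched_classes},
                noiseless_phantom.lesion_masks, "KF8",
            )

    def test_kf5_agrees_with_kf1_when_adaptations_are_inert(self, noiseless_spec):
        # flat late TACs and no liver-like voxels in the masks: the KF5 window
        # and liver reclassification change nothing relative to KF1
        from fltseg.phantom import PhantomSpec, Shape, TissueModel

        sched = builtin_schedules()["vumc_trt_39"]
        tissues = {
            "lung": TissueModel("lung", "flat", 0.5),
            "tumour": TissueModel("tumour", "flat", 6.0),
        }
        spec = PhantomSpec(
            grid_shape=(16, 16, 8),
            spacing_mm=(4.0, 4.0, 4.0),
            schedule=sched,
            tissues=tissues,
            organs=[],
            lesions=[("l1", Shape("sphere", (32.0, 32.0, 16.0), (8.0, 8.0, 8.0)))],
            noise_level=0.0,
        )
        out = generate_phantom(spec)
        kcs = true_class_set(spec)
        r1 = run_kf_preset(out.image, {"hammersmith": kcs}, out.lesion_masks, "KF1",
                           dose_mbq=spec.dose_mbq)
        r5 = run_kf_preset(out.image, {"hammersmith": kcs}, out.lesion_masks, "KF5",
                           dose_mbq=spec.dose_mbq)
        np.testing.assert_array_equal(r1["l1"].voi, r5["l1"].voi)
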