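"""Sparse-grid full-lung classification and ILA scoring."""

import numpy as np
import pytest

from lungtex.fullscan import (BACKGROUND, EmptyLungError, LabelMap,
                              certainty_overlay, classify_scan, grid_nodes,
                              ila_curve, ila_score, nearest_node_index)
from lungtex.tissue import ILA_CLASSES, TissueClass
from lungtex.volume import CTVolume


class _OracleClassifier:
    """Deterministic stand-in classifier (synthetic): the probability
    vector at a point depends only on its coordinates."""

    def __init__(self, fn):
        self.fn = fn

    def classify_points(self, vol, points, batch_size=128):
        out = []
        for p in points:
            probs = np.asarray(self.fn(p.coord), dtype=float)
            out.append(probs / probs.sum())
        return np.stack(out)


def _constant_class(cls, certainty=0.9):
    def fn(coord):
        p = np.full(8, (1 - certainty) / 7)
        p[int(cls)] = certainty
        return p
    return _OracleClassifier(fn)


def _full_mask_volume(shape=(10, 10, 10)):
    return CTVolume(voxels=np.zeros(shape),
                    lung_mask=np.ones(shape, dtype=bool))


def _brute_force_nearest(voxels, nodes):
    out = np.empty(len(voxels), dtype=int)
    for n, v in enumerate(voxels):
        d2 = ((nodes - v) ** 2).sum(axis=1)
        out[n] = int(np.argmin(d2))   # argmin takes the lowest index on ties
    return out


class TestGridClassification:
    def test_10cube_at_spacing_5_has_8_nodes_and_full_coverage(self):
        vol = _full_mask_volume()
        nodes = grid_nodes(vol, 5)
        assert len(nodes) == 8
        lmap = classify_scan(vol, _constant_class(TissueClass.GG), 5)
        assert np.all(lmap.labels != BACKGROUND)

    def test_nearest_node_assignment_matches_brute_force(self):
        vol = _full_mask_volume()
        nodes = grid_nodes(vol, 5)
        voxels = np.argwhere(vol.lung_mask)
        got = nearest_node_index(voxels, nodes)
        np.testing.assert_array_equal(got, _brute_force_nearest(voxels, nodes))

    def test_classify_scan_agrees_voxelwise_with_brute_force(self):
        rng = np.random.default_rng(0)
        mask = rng.random((10, 10, 10)) < 0.7
        mask[0, 0, 0] = True
        vol = CTVolume(voxels=np.zeros((10, 10, 10)), lung_mask=mask)
        clf = _OracleClassifier(
            lambda c: 1.0 + np.arange(8) * ((c[0] + 2 * c[1] + 3 * c[2]) % 5))
        lmap = classify_scan(vol, clf, 5)
        nodes = grid_nodes(vol, 5)
        probs = clf.classify_points(vol, [type("P", (), {"coord": tuple(n)})()
                                          for n in nodes])
        voxels = np.argwhere(mask)
        nearest = _brute_force_nearest(voxels, nodes)
        for v, ni in zip(voxels, nearest):
            assert lmap.labels[tuple(v)] == probs[ni].argmax()
            assert lmap.certainty[tuple(v)] == pytest.approx(probs[ni].max())

    def test_spacing_one_equals_exhaustive_classification(self):
        rng = np.random.default_rng(1)
        mask = rng.random((6, 6, 6)) < 0.6
        mask[3, 3, 3] = True
        vol = CTVolume(voxels=np.zeros((6, 6, 6)), lung_mask=mask)
        clf = _OracleClassifier(lambda c: np.roll(np.arange(8) + 1.0, c[0]))
        lmap = classify_scan(vol, clf, 1)
        for v in np.argwhere(mask):
            expected = clf.classify_points(
                vol, [type("P", (), {"coord": tuple(v)})()])[0]
            assert lmap.labels[tuple(v)] == expected.argmax()

    def test_grid_nodes_agree_between_spacings(self):
        vol = _full_mask_volume((15, 15, 15))
        clf = _OracleClassifier(lambda c: np.arange(8) + 1.0 + (c[2] % 3))
        coarse = classify_scan(vol, clf, 5)
        fine = classify_scan(vol, clf, 1)
        for n in grid_nodes(vol, 5):
            assert coarse.labels[tuple(n)] == fine.labels[tuple(n)]

    def test_interpolation_introduces_no_new_classes(self):
        vol = _full_mask_volume()
        clf = _OracleClassifier(
            lambda c: np.eye(8)[int(c[0] >= 5) * 6])  # only NP or PS
        lmap = classify_scan(vol, clf, 5)
        assert set(np.unique(lmap.labels[lmap.lung])) <= {0, 6}

    def test_constant_classifier_gives_uniform_map(self):
        vol = _full_mask_volume()
        lmap = classify_scan(vol, _constant_class(TissueClass.RETIC, 0.8), 5)
        lung = lmap.lung
        assert np.all(lmap.labels[lung] == int(TissueClass.RETIC))
        np.testing.assert_allclose(lmap.certainty[lung], 0.8)

    def test_mask_required_and_empty_mask_rejected(self):
        vol = CTVolume(voxels=np.zeros((10, 10, 10)),
                       lung_mask=np.zeros((10, 10, 10), dtype=bool))
        with pytest.raises(EmptyLungError):
            classify_scan(vol, _constant_class(TissueClass.NP), 5)
        with pytest.raises(ValueError):
            classify_scan(_full_mask_volume(), _constant_class(TissueClass.NP), 0)


def _half_gg_map(certainty_gg=1.0):
    labels = np.full((10, 10, 10), BACKGROUND, dtype=np.int16)
    cert = np.zeros((10, 10, 10))
    labels[:5] = int(TissueClass.GG)
    labels[5:] = int(TissueClass.NP)
    cert[:5] = certainty_gg
    cert[5:] = 1.0
    return LabelMap(labels=labels, certainty=cert)


class TestIlaScore:
    def test_all_normal_map_scores_zero(self):
        labels = np.full((6, 6, 6), int(TissueClass.NP), dtype=np.int16)
        lmap = LabelMap(labels=labels, certainty=np.ones((6, 6, 6)))
        for t in (0.0, 0.5, 0.95):
            assert ila_score(lmap, t).score == 0.0

    def test_half_gg_at_full_certainty_scores_50(self):
        lmap = _half_gg_map()
        assert ila_score(lmap, 0.95).score == 50.0
        assert ila_score(lmap, 0.0).score == 50.0

    def test_threshold_is_strict_so_one_scores_zero(self):
        lmap = _half_gg_map()
        assert ila_score(lmap, 1.0).score == 0.0

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 8, (12, 12, 12)).astype(np.int16)
        cert = rng.uniform(0, 1, (12, 12, 12))
        lmap = LabelMap(labels=labels, certainty=cert)
        curve = ila_curve(lmap, np.linspace(0, 1, 21))
        scores = [s.score for s in curve]
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0 <= s <= 100 for s in scores)

    def test_emphysema_excluded_by_default_but_configurable(self):
        labels = np.full((4, 4, 4), int(TissueClass.CL), dtype=np.int16)
        lmap = LabelMap(labels=labels, certainty=np.ones((4, 4, 4)))
        assert ila_score(lmap, 0.5).score == 0.0
        widened = ila_score(lmap, 0.5,
                            ila_classes=set(ILA_CLASSES) | {TissueClass.CL})
        assert widened.score == 100.0

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ila_score(_half_gg_map(), 1.5)


class TestCertaintyOverlay:
    def test_groups_cover_lung_and_partition_ila(self):
        lmap = _half_gg_map(certainty_gg=0.6)
        ov = certainty_overlay(lmap)
        lung = lmap.lung
        assert np.all(ov["group"][lung] > 0)
        assert np.all(ov["group"][~lung] == 0)
        assert np.all(ov["group"][lmap.labels == int(TissueClass.GG)] == 2)
        assert np.all(ov["group"][lmap.labels == int(TissueClass.NP)] == 1)

    def test_single_group_when_not_partitioned(self):
        ov = certainty_overlay(_half_gg_map(), ila_partition=False)
        assert set(np.unique(ov["group"])) <= {0, 1}

    def test_quantized_export_round_trips_bit_exact(self, tmp_path):
        import SimpleITK as sitk

        ov = certainty_overlay(_half_gg_map(certainty_gg=0.6180339))
        path = tmp_path / "cert.nii"
        img = sitk.GetImageFromArray(ov["certainty"].transpose(2, 1, 0))
        sitk.WriteImage(img, str(path))
        back = sitk.GetArrayFromImage(sitk.ReadImage(str(path))).transpose(2, 1, 0)
        np.testing.assert_array_equal(back, ov["certainty"])
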