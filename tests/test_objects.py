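"""Cluster extraction, morphometry, and heuristic non-bowel removal."""

import numpy as np
import pytest

from pftquant.errors import ConfigError
from pftquant.objects import (
    DEFAULT_RULES,
    ClusterMorphometry,
    HeuristicRule,
    classify_nonbowel,
    compute_morphometry,
    label_clusters,
    load_rules,
    remove_nonbowel,
    remove_small_clusters,
    resample_isotropic,
    save_rules,
)

SPACING = (4.0, 0.8, 0.8)
CUBE_SPHERICITY = np.pi ** (1 / 3) * 6 ** (2 / 3) / 6  # ~0.806, discrete max


def _digital_ball(radius, size):
    g = np.indices((size, size, size)) - size // 2
    return (g**2).sum(axis=0) <= radius**2


class TestLabelClusters:
    def test_empty_mask_has_no_clusters(self):
        _, n = label_clusters(np.zeros((4, 16, 16), bool))
        assert n == 0

    def test_diagonal_voxels_connect_under_26_connectivity(self):
        m = np.zeros((4, 16, 16), bool)
        m[1, 5, 5] = m[2, 6, 6] = True
        _, n = label_clusters(m)
        assert n == 1

    def test_phantom_clusters_count_tubes_plus_confounders(self, clean_phantom):
        pair, truth = clean_phantom
        full = truth.bowel_mask_pre.copy()
        for m in truth.confounder_masks.values():
            full |= m
        _, n_bowel = label_clusters(truth.bowel_mask_pre)
        n_conf = sum(label_clusters(m)[1] for m in truth.confounder_masks.values())
        _, n = label_clusters(full)
        assert n == n_bowel + n_conf  # disjoint by construction


class TestRemoveSmallClusters:
    def test_tiny_cluster_removed_exact_1ml_retained(self):
        m = np.zeros((14, 32, 32), bool)
        m[1, 2, 2:7] = True  # 5 voxels at 1 mm^3 = 0.005 mL
        m[3:13, 10:20, 10:20] = True  # 10x10x10 voxels = exactly 1.0 mL
        out = remove_small_clusters(m, (1.0, 1.0, 1.0), min_ml=1.0)
        assert not out[1, 2, 2:7].any()
        assert out.sum() == 1000  # exactly-1.0-mL cluster kept (strict <)

    def test_zero_min_is_identity(self, rng):
        m = rng.random((4, 20, 20)) > 0.8
        assert np.array_equal(remove_small_clusters(m, SPACING, min_ml=0.0), m)

    def test_idempotent_and_volume_monotone(self, rng):
        m = rng.random((6, 24, 24)) > 0.7
        once = remove_small_clusters(m, SPACING, 1.0)
        twice = remove_small_clusters(once, SPACING, 1.0)
        assert np.array_equal(once, twice)
        assert once.sum() <= m.sum()


class TestResampleIsotropic:
    def test_isotropic_input_unchanged(self, rng):
        m = rng.random((6, 24, 24)) > 0.7
        out, iso = resample_isotropic(m, (1.0, 1.0, 1.0))
        assert iso == 1.0 and np.array_equal(out, m)

    def test_anisotropic_slab_volume_preserved(self):
        m = np.zeros((10, 40, 40), bool)
        m[3:6, 10:23, 10:23] = True  # ~1.3 mL at 0.8 x 0.8 x 4 mm
        native_ml = m.sum() * np.prod(SPACING) / 1000
        out, iso = resample_isotropic(m, SPACING)
        iso_ml = out.sum() * iso**3 / 1000
        assert iso == 0.8
        assert iso_ml == pytest.approx(native_ml, rel=0.05)

    def test_empty_stays_empty(self):
        out, _ = resample_isotropic(np.zeros((4, 16, 16), bool), SPACING)
        assert not out.any()


class TestMorphometry:
    def test_single_voxel_cube_closed_form(self):
        labels = np.zeros((8, 8, 8), int)
        labels[4, 4, 4] = 1
        (m,) = compute_morphometry(labels, 1.0)
        assert m.sphericity == pytest.approx(CUBE_SPHERICITY, abs=1e-9)
        assert m.unstable

    def test_craniocaudal_rod_angle_and_span(self):
        labels = np.zeros((8, 64, 8), int)
        labels[4, 5:55, 4] = 1  # thin rod along the row (craniocaudal) axis
        (rod,) = compute_morphometry(labels, 1.0)
        assert rod.principal_axis_angle_deg <= 5.0
        assert rod.craniocaudal_span_frac == pytest.approx(50 / 64)

    def test_ball_rounder_than_rod_and_cube_is_max(self):
        ball_labels = _digital_ball(10, 31).astype(int)
        (ball,) = compute_morphometry(ball_labels, 1.0)
        rod_labels = np.zeros((8, 64, 8), int)
        rod_labels[4, 5:55, 4] = 1
        (rod,) = compute_morphometry(rod_labels, 1.0)
        # Face counting overestimates smooth area ~1.5x, so the digital ball
        # sits near 0.65 and every cluster stays below the cube bound.
        assert ball.sphericity > rod.sphericity
        assert 0.55 <= ball.sphericity <= CUBE_SPHERICITY * 1.05
        assert rod.sphericity < 0.45

    def test_face_count_area_against_sphere_area(self):
        ball = _digital_ball(10, 31)
        from pftquant.objects import _surface_area_faces

        area = _surface_area_faces(ball, 1.0)
        smooth = 4 * np.pi * 10**2
        assert smooth < area < 1.7 * smooth


class TestClassification:
    def test_spinal_canal_archetype(self):
        features = ClusterMorphometry(
            label=1,
            volume_ml=5.0,
            centroid_norm=(0.8, 0.5, 0.5),
            bbox_extent_mm=(8.0, 90.0, 8.0),
            sphericity=0.35,
            principal_axis_angle_deg=2.0,
            craniocaudal_span_frac=0.7,
        )
        assert classify_nonbowel(features) == "spinal_canal"

    def test_phantom_confounders_get_their_own_class(self, clean_phantom):
        pair, truth = clean_phantom
        for name, mask in truth.confounder_masks.items():
            labels, n = label_clusters(mask)
            labels_iso, iso = resample_isotropic(labels, SPACING)
            for m in compute_morphometry(labels_iso, iso):
                assert classify_nonbowel(m) == name, (name, m)

    def test_phantom_bowel_retained(self, clean_phantom):
        pair, truth = clean_phantom
        labels, _ = label_clusters(truth.bowel_mask_pre)
        labels_iso, iso = resample_isotropic(labels, SPACING)
        for m in compute_morphometry(labels_iso, iso):
            assert classify_nonbowel(m) is None

    def test_unknown_feature_rejected_at_rule_construction(self):
        with pytest.raises(ConfigError, match="unknown feature"):
            HeuristicRule("bladder", [("girth", 0.0, 1.0)])

    def test_rule_table_json_round_trip(self, tmp_path):
        path = tmp_path / "rules.json"
        save_rules(DEFAULT_RULES, path)
        loaded = load_rules(path)
        assert [r.object_class for r in loaded] == [r.object_class for r in DEFAULT_RULES]
        assert loaded[0].predicates == DEFAULT_RULES[0].predicates


class TestRemoveNonbowel:
    def test_bowel_only_mask_unchanged(self, clean_phantom):
        pair, truth = clean_phantom
        out, log = remove_nonbowel(truth.bowel_mask_pre, SPACING)
        assert np.array_equal(out, truth.bowel_mask_pre)
        assert log == []

    def test_all_six_confounders_mostly_removed(self, clean_phantom):
        pair, truth = clean_phantom
        full = truth.bowel_mask_pre.copy()
        for m in truth.confounder_masks.values():
            full |= m
        out, log = remove_nonbowel(full, SPACING)
        removed = sum(
            1 for m in truth.confounder_masks.values() if (out & m).sum() < 0.5 * m.sum()
        )
        retained = (out & truth.bowel_mask_pre).sum() / truth.bowel_mask_pre.sum()
        assert removed >= 4
        assert retained >= 0.95
        assert len(log) >= 4

    def test_empty_mask_noop(self):
        out, log = remove_nonbowel(np.zeros((4, 16, 16), bool), SPACING)
        assert not out.any() and log == []
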