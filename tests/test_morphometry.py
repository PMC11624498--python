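"""Skeleton graph construction, branch metrics and the 18 features."""

import numpy as np
import pytest

from rsomvasc import (
    DualBandVolume,
    ValidationError,
    branch_metrics,
    detect_surface,
    extract_features,
    generate_vessel_tree,
    junction_angles,
    plexus_phantom,
    rasterize,
    segment_dermis,
    segment_vessels,
    skeletonize_graph,
)
from rsomvasc.core import FEATURE_NAMES, SkinMask


SP10 = (10.0, 10.0, 10.0)


class TestTopology:
    def test_straight_tube(self, straight_tube):
        g = skeletonize_graph(straight_tube, SP10)
        assert g.n_branches == 1
        assert len(g.endpoints) == 2 and len(g.junctions) == 0
        assert g.type_counts() == {"J2J": 0, "J2E": 0, "E2E": 1}

    def test_y_phantom(self, y_mask):
        g = skeletonize_graph(y_mask, SP10)
        assert len(g.junctions) == 1
        assert g.type_counts() == {"J2J": 0, "J2E": 3, "E2E": 0}

    def test_empty_mask_gives_empty_graph(self):
        g = skeletonize_graph(np.zeros((10, 10, 10), bool), SP10)
        assert g.n_branches == 0 and not g.nodes

    @pytest.mark.parametrize("seed", [2, 5, 9])
    def test_random_phantom_counts_equal_ground_truth(self, seed):
        tree = plexus_phantom(seed=seed)
        gt = tree.ground_truth()
        _, low, high = rasterize(tree, spacing=(8.0,) * 3, return_masks=True)
        g = skeletonize_graph(low | high, (8.0,) * 3)
        assert g.n_branches == gt["n_branches"]
        assert len(g.junctions) == gt["n_junctions"]
        assert g.type_counts() == {
            "J2J": gt["n_j2j"], "J2E": gt["n_j2e"], "E2E": gt["n_e2e"],
        }

    def test_spur_pruning_removes_short_side_twig(self, straight_tube):
        mask = straight_tube.copy()
        # a 30 um twig off the side of the tube
        mask[20:24, 20:23, 40] = True
        g = skeletonize_graph(mask, SP10, prune_len=80.0)
        assert g.n_branches == 1 and len(g.junctions) == 0


class TestBranchMetrics:
    def test_straight_tube_tortuosity_exactly_one(self, straight_tube):
        bm = branch_metrics(skeletonize_graph(straight_tube, SP10))
        assert bm.tortuosity.iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_semicircle_tortuosity_is_half_pi(self, semicircle_mask):
        bm = branch_metrics(skeletonize_graph(semicircle_mask, SP10))
        assert bm.tortuosity.iloc[0] == pytest.approx(np.pi / 2, abs=0.02)

    def test_helix_length_matches_closed_form(self, helix_mask):
        bm = branch_metrics(skeletonize_graph(helix_mask, SP10))
        expected = 2 * np.sqrt((2 * np.pi * 100) ** 2 + 200**2)
        assert bm.length.iloc[0] == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("radius", [30, 40])
    def test_diameter_recovery_within_15_percent(self, radius):
        from conftest import tube_mask

        mask = tube_mask((40, 40, 80), (200, 200, 100), (200, 200, 600), radius)
        bm = branch_metrics(skeletonize_graph(mask, SP10))
        assert bm.diameter.iloc[0] == pytest.approx(2 * radius, rel=0.15)

    def test_tortuosity_at_least_one(self):
        tree = plexus_phantom(seed=3)
        _, low, high = rasterize(tree, spacing=(8.0,) * 3, return_masks=True)
        bm = branch_metrics(skeletonize_graph(low | high, (8.0,) * 3))
        torts = bm.tortuosity.dropna()
        assert (torts >= 1.0 - 1e-6).all()


class TestJunctionAngles:
    def test_symmetric_y_gives_120_degrees(self, y_mask):
        angles = junction_angles(skeletonize_graph(y_mask, SP10))
        assert angles.iloc[0] == pytest.approx(120.0, abs=3.0)

    def test_no_junctions_raises(self, straight_tube):
        with pytest.raises(ValidationError):
            junction_angles(skeletonize_graph(straight_tube, SP10))

    def test_mean_over_pairs_arithmetic(self):
        # angles (90, 90, 180) average to 120
        assert np.mean([90.0, 90.0, 180.0]) == pytest.approx(120.0)


def _full_features(vol_masks, spacing):
    vol, low, high = vol_masks
    mask = segment_dermis(vol, detect_surface(vol), 100.0, 500.0)
    segment_vessels(vol, mask)
    g = skeletonize_graph(mask.vessel_mask, spacing)
    return extract_features(vol, mask, g)


@pytest.fixture(scope="module")
def plexus_features():
    tree = plexus_phantom(seed=2)
    out = rasterize(tree, spacing=(8.0,) * 3, return_masks=True)
    return _full_features(out, (8.0,) * 3)


class TestExtractFeatures:

    def test_all_18_features_present_and_finite(self, plexus_features):
        assert list(plexus_features.index) == list(FEATURE_NAMES)
        assert plexus_features.notna().all()

    def test_branch_conservation(self, plexus_features):
        tree = plexus_phantom(seed=2)
        _, low, high = rasterize(tree, spacing=(8.0,) * 3, return_masks=True)
        g = skeletonize_graph(low | high, (8.0,) * 3)
        counts = g.type_counts()
        assert g.n_branches == counts["J2J"] + counts["J2E"] + counts["E2E"]

    def test_junctions_to_vessels_ratio_definition(self, plexus_features):
        f = plexus_features
        assert f["junctions_to_vessels_ratio"] == pytest.approx(
            f["num_junctions"] / f["num_vessels"]
        )

    def test_vascular_density_in_unit_interval(self, plexus_features):
        assert 0.0 <= plexus_features["vascular_density"] <= 1.0

    def test_uniform_intensity_gives_unit_vessel_signal(self, plexus_features):
        # noiseless phantom paints vessels at intensity 1 in a single band
        assert plexus_features["mean_signal_vessels"] == pytest.approx(1.0)

    def test_single_tube_counts(self, straight_tube):
        low = straight_tube.astype(float)
        vol = DualBandVolume(low, np.zeros_like(low), SP10)
        mask = SkinMask(
            surface_depth=np.zeros(low.shape[1:]),
            de_mask=np.ones_like(straight_tube),
            vessel_mask=straight_tube,
        )
        g = skeletonize_graph(straight_tube, SP10)
        f = extract_features(vol, mask, g)
        assert f["num_vessels"] == 1
        assert f["num_junctions"] == 0
        assert f["junctions_to_vessels_ratio"] == 0.0
        assert np.isnan(f["avg_junction_angle"])

    def test_vascular_density_matches_analytic_cylinder(self):
        tree = generate_vessel_tree(
            n_seeds=1, branching_prob=0.0, radius_range=(25.0, 25.0), seed=4
        )
        out = rasterize(tree, spacing=SP10, return_masks=True)
        f = _full_features(out, SP10)
        vol, low, high = out
        mask = segment_dermis(vol, detect_surface(vol), 100.0, 500.0)
        b = tree.branches[0]
        analytic = np.pi * np.mean(b.radii**2) * b.length / (
            mask.de_mask.sum() * 1000.0
        )
        assert f["vascular_density"] == pytest.approx(analytic, rel=0.15)

    def test_empty_graph_yields_zero_counts_and_missing_means(self):
        shape = (30, 20, 20)
        vol = DualBandVolume(np.zeros(shape), np.zeros(shape), SP10)
        vol.low[10:12] = 1.0  # epidermis only
        mask = SkinMask(
            surface_depth=np.full(shape[1:], 100.0),
            de_mask=np.zeros(shape, bool),
            vessel_mask=np.zeros(shape, bool),
        )
        mask.de_mask[15:25] = True
        g = skeletonize_graph(mask.vessel_mask, SP10)
        f = extract_features(vol, mask, g)
        assert f["num_vessels"] == 0 and f["num_junctions"] == 0
        assert np.isnan(f["avg_vessel_diameter"])


class TestInvariances:
    def test_rotation_about_z(self):
        tree = plexus_phantom(seed=2)
        vol, low, high = rasterize(tree, spacing=(8.0,) * 3, return_masks=True)
        f0 = _full_features((vol, low, high), (8.0,) * 3)
        rot = DualBandVolume(
            np.rot90(vol.low, axes=(1, 2)).copy(),
            np.rot90(vol.high, axes=(1, 2)).copy(),
            vol.spacing,
        )
        f1 = _full_features((rot, None, None), (8.0,) * 3)
        for count in ("num_vessels", "num_junctions", "num_j2j_branches", "num_j2e_branches"):
            assert f0[count] == f1[count]
        for cont in ("avg_vessel_length", "avg_vessel_diameter", "avg_tortuosity",
                     "de_thickness", "vascular_density"):
            assert f1[cont] == pytest.approx(f0[cont], rel=0.15)

    def test_spacing_equivariance(self):
        """Same physical phantom on 8 and 16 um grids: identical counts,
        micrometre features within the discretisation bound."""
        tree = generate_vessel_tree(
            n_seeds=3, branching_prob=0.3, radius_range=(50.0, 60.0),
            domain=(900.0, 1400.0, 1400.0), seed=7, max_branches=12,
            min_steps_before_branch=14, min_branch_len=220.0,
            bifurcation_half_deg=(40.0, 60.0), collision_margin=60.0,
        )
        results = {}
        for sp in (8.0, 16.0):
            _, low, high = rasterize(tree, spacing=(sp,) * 3, return_masks=True)
            g = skeletonize_graph(low | high, (sp,) * 3)
            bm = branch_metrics(g)
            results[sp] = (g.n_branches, len(g.junctions),
                           bm.length.mean(), bm.diameter.mean())
        coarse, fine = results[16.0], results[8.0]
        assert coarse[:2] == fine[:2]
        assert coarse[2] == pytest.approx(fine[2], rel=0.15)
        assert coarse[3] == pytest.approx(fine[3], rel=0.15)
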