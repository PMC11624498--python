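"""Phantom generators: trees, rasterisation, PORH series, cohorts."""

import numpy as np
import pytest
from scipy import stats

from rsomvasc import (
    ReactivityModel,
    ValidationError,
    effect_preset,
    generate_cohort,
    generate_porh_series,
    generate_vessel_tree,
    rasterize,
    tube_field_phantom,
)
from rsomvasc.phantom import EFFECT_FEATURES


class TestVesselTree:
    def test_no_branching_gives_single_branch(self):
        tree = generate_vessel_tree(n_seeds=1, branching_prob=0.0, seed=0)
        gt = tree.ground_truth()
        assert gt["n_branches"] == 1
        assert gt["n_junctions"] == 0

    def test_deterministic_under_seed(self):
        a = generate_vessel_tree(n_seeds=3, branching_prob=0.3, seed=5)
        b = generate_vessel_tree(n_seeds=3, branching_prob=0.3, seed=5)
        assert len(a.branches) == len(b.branches)
        for ba, bb in zip(a.branches, b.branches):
            np.testing.assert_array_equal(ba.points, bb.points)
            np.testing.assert_array_equal(ba.radii, bb.radii)

    def test_ground_truth_consistent_with_independent_walk(self):
        """Counts attached to the spec equal those recomputed by walking the
        stored structure from scratch."""
        tree = generate_vessel_tree(n_seeds=5, branching_prob=0.5, seed=7)
        gt = tree.ground_truth()
        branches = tree.merged_branches()
        degree: dict[int, int] = {}
        for b in branches:
            for n in (b.start_node, b.end_node):
                degree[n] = degree.get(n, 0) + 1
        assert gt["n_branches"] == len(branches)
        assert gt["n_junctions"] == sum(d >= 3 for d in degree.values())
        types = {"J2J": 0, "J2E": 0, "E2E": 0}
        for b in branches:
            kinds = sorted(
                "J" if degree[n] >= 3 else "E" for n in (b.start_node, b.end_node)
            )
            types[kinds[1] + "2" + kinds[0]] += 1
        assert (gt["n_j2j"], gt["n_j2e"], gt["n_e2e"]) == (
            types["J2J"], types["J2E"], types["E2E"],
        )
        assert gt["n_j2j"] + gt["n_j2e"] + gt["n_e2e"] == gt["n_branches"]

    def test_centrelines_confined_to_dermis_band(self):
        tree = generate_vessel_tree(n_seeds=4, branching_prob=0.3, seed=3)
        z_top, z_bot = tree.dermis_band
        for b in tree.branches:
            assert (b.points[:, 0] > z_top).all()
            assert (b.points[:, 0] < z_bot).all()
            assert (b.radii > 0).all()

    def test_radius_range_validation(self):
        with pytest.raises(ValidationError):
            generate_vessel_tree(radius_range=(10.0, 400.0))
        with pytest.raises(ValidationError):
            generate_vessel_tree(domain=(900.0, 100.0, 100.0))


class TestRasterize:
    def test_band_assignment_by_radius_threshold(self):
        tree = generate_vessel_tree(
            n_seeds=1, branching_prob=0.0, radius_range=(40.0, 40.0), seed=2
        )
        vol, low_mask, high_mask = rasterize(
            tree, band_radius_threshold=30.0, return_masks=True
        )
        assert low_mask.any() and not high_mask.any()
        vol2, low2, high2 = rasterize(
            tree, band_radius_threshold=80.0, return_masks=True
        )
        assert high2.any() and not low2.any()

    def test_noiseless_volume_is_binary_valued(self):
        tree = generate_vessel_tree(n_seeds=2, branching_prob=0.0, seed=1)
        vol = rasterize(tree, noise_sd=0.0)
        assert set(np.unique(vol.low)) <= {0.0, 1.0}
        assert set(np.unique(vol.high)) <= {0.0, 1.0}

    def test_cylinder_volume_matches_analytic(self):
        tree = generate_vessel_tree(
            n_seeds=1, branching_prob=0.0, radius_range=(25.0, 25.0), seed=4
        )
        _, low, high = rasterize(tree, spacing=(10.0, 10.0, 10.0), return_masks=True)
        voxels = int((low | high).sum())
        b = tree.branches[0]
        analytic = np.pi * np.mean(b.radii**2) * b.length / 1000.0  # voxels of 1000 um^3
        assert abs(voxels - analytic) / analytic < 0.15


class TestPorhSeries:
    @staticmethod
    def _null_model():
        model = ReactivityModel(noise_sd=0.01)
        for phases in model.factors.values():
            for tp in phases:
                phases[tp].radius = 1.0
                phases[tp].recruit_prob = 0.0
                phases[tp].intensity = 1.0
        return model

    def test_null_dynamics_produce_identical_volumes(self):
        tree = tube_field_phantom(seed=1)
        vols, _ = generate_porh_series(tree, self._null_model(), "healthy", seed=2)
        base = vols["baseline"]
        for tp, v in vols.items():
            np.testing.assert_array_equal(v.low, base.low)
            np.testing.assert_array_equal(v.high, base.high)

    def test_ground_truth_diameter_change_by_construction(self):
        tree = tube_field_phantom(seed=1)
        model = ReactivityModel(noise_sd=0.0)
        model.factors["healthy"]["hyp1"].radius = 1.3
        model.factors["healthy"]["hyp1"].recruit_prob = 0.0
        _, truth = generate_porh_series(tree, model, "healthy", seed=0)
        assert truth["hyp1"]["delta_avg_vessel_diameter_pct"] == pytest.approx(30.0)

    def test_unknown_group_rejected(self):
        tree = tube_field_phantom(seed=1)
        with pytest.raises(ValidationError, match="unknown group"):
            generate_porh_series(tree, ReactivityModel(), "mouse", seed=0)

    def test_model_invariants_enforced(self):
        model = ReactivityModel()
        model.factors["healthy"]["baseline"].radius = 1.1
        with pytest.raises(ValidationError):
            model.validate()
        model = ReactivityModel()
        model.factors["patient"]["hyp1"].radius = 2.0  # above healthy
        with pytest.raises(ValidationError):
            model.validate()


class TestCohortGenerator:
    def test_matches_cohort_schema(self):
        cohort = generate_cohort(13, "null", seed=0)
        assert len(cohort.subjects) == 26
        assert cohort.groups.sum() == 13
        cohort.validate()

    def test_deterministic_under_seed(self):
        a = generate_cohort(5, "strong", seed=9)
        b = generate_cohort(5, "strong", seed=9)
        np.testing.assert_array_equal(a.features.to_numpy(), b.features.to_numpy())
        assert a.covariates.equals(b.covariates)

    def test_strong_effect_matches_closed_form_t(self):
        """Shifted features show p < 0.01 by the closed-form pooled t formula."""
        cohort = generate_cohort(13, "strong", seed=3)
        from rsomvasc import percent_change

        delta = percent_change(cohort).xs("hyp1", level=1).loc[cohort.subjects]
        groups = cohort.groups
        pvals = []
        for feature in EFFECT_FEATURES:
            x = delta.loc[groups[groups == 0].index, feature].to_numpy()
            y = delta.loc[groups[groups == 1].index, feature].to_numpy()
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
            t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            pvals.append(2 * stats.t.sf(abs(t), n1 + n2 - 2))
        # a 2-SD shift has ~99% per-feature power at alpha 0.01; allow one
        # borderline draw among the nine shifted features
        assert sum(p < 0.01 for p in pvals) >= 8
        assert all(p < 0.05 for p in pvals)

    def test_effect_presets(self):
        assert (effect_preset("null").to_numpy() == 0).all()
        strong = effect_preset("strong")
        assert (strong.loc["hyp1", list(EFFECT_FEATURES)] != 0).all()
        assert (strong.loc["occl1"] == 0).all()
        with pytest.raises(ValidationError):
            effect_preset("bogus")
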