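"""Shared fixtures: analytic tube phantoms and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from rsomvasc import generate_cohort


def tube_mask(shape, p0, p1, radius, spacing=10.0):
    """Binary mask of a capsule (cylinder with rounded caps) on a cubic grid."""
    grids = np.meshgrid(*[np.arange(s) * spacing for s in shape], indexing="ij")
    pos = np.stack(grids, axis=-1)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    length = np.linalg.norm(d)
    d = d / length
    t = np.clip((pos - p0) @ d, 0.0, length)
    closest = p0 + t[..., None] * d
    return np.linalg.norm(pos - closest, axis=-1) <= radius


def curve_mask(shape, curve_points, radius, spacing=10.0):
    """Binary mask of a tube around an arbitrary sampled space curve."""
    grids = np.meshgrid(*[np.arange(s) * spacing for s in shape], indexing="ij")
    vox = np.stack(grids, axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(curve_points).query(vox)
    return (dist <= radius).reshape(shape)


@pytest.fixture(scope="session")
def straight_tube():
    """A 500 um straight tube of radius 30 um on a 10 um grid."""
    return tube_mask((40, 40, 80), (200, 200, 100), (200, 200, 600), 30)


@pytest.fixture(scope="session")
def y_mask():
    """Three tubes meeting at one point with 120 degree planar separation."""
    centre = (200, 300, 300)
    masks = []
    for ang in (90, 210, 330):
        a = np.radians(ang)
        end = (200, 300 + 250 * np.sin(a), 300 + 250 * np.cos(a))
        masks.append(tube_mask((40, 60, 60), centre, end, 25))
    return masks[0] | masks[1] | masks[2]


@pytest.fixture(scope="session")
def semicircle_mask():
    """A semicircular arc (bend radius 200 um, tube radius 25 um)."""
    theta = np.linspace(0.0, np.pi, 600)
    arc = np.stack(
        [np.full_like(theta, 200.0), 250 + 200 * np.sin(theta), 300 + 200 * np.cos(theta)],
        axis=1,
    )
    return curve_mask((40, 60, 62), arc, 25)


@pytest.fixture(scope="session")
def helix_mask():
    """Two helix turns: r=100 um, pitch 200 um, tube radius 25 um."""
    t = np.linspace(0.0, 4 * np.pi, 400)
    curve = np.stack(
        [200 + 200 * t / (2 * np.pi), 300 + 100 * np.sin(t), 300 + 100 * np.cos(t)],
        axis=1,
    )
    return curve_mask((120, 60, 60), curve, 25)


@pytest.fixture(scope="session")
def null_cohort():
    return generate_cohort(13, "null", seed=42)


@pytest.fixture(scope="session")
def strong_cohort():
    return generate_cohort(13, "strong", seed=7)
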