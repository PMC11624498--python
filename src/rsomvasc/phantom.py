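"""Ground-truthed synthetic phantoms: vessel trees, dual-band volumes, PORH
time series and feature-level cohorts.

The clinical cohort behind the method is not public, so every downstream
stage is exercised on synthetic data with known ground truth.  Vessel
networks are grown by a stochastic branching random walk confined to a dermis
band beneath an epidermis slab; volumes are rasterised on a regular grid with
branches assigned to the low or high frequency band by mean radius — an
explicit geometric emulation of the acoustic frequency split.  Reactivity
over the PORH timeline is imposed as per-phase multiplicative factors on
radius, branch recruitment and signal intensity, with a blunted hyperemic
response encoded for the patient group.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    COVARIATE_NAMES,
    FEATURE_NAMES,
    POST_TIMEPOINTS,
    TIMEPOINTS,
    CohortTable,
    DualBandVolume,
    ValidationError,
    logger,
)

_STEP_UM = 15.0          # random-walk step length
_TAPER = 0.25            # fractional radius taper from dermis top to bottom
_CHILD_RADIUS_FACTOR = 0.85
_COLLISION_MARGIN_UM = 25.0
_BIFURCATION_ANGLE_DEG = (25.0, 50.0)   # half-angle range of child divergence


# ---------------------------------------------------------------------------
# Vessel tree specification
# ---------------------------------------------------------------------------

@dataclass
class TreeBranch:
    points: np.ndarray          # (n, 3) centreline in um, (z, y, x)
    radii: np.ndarray           # (n,) per-point radius in um
    start_node: int
    end_node: int

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        c = self.chord
        return self.length / c if c > 0 else np.nan

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())

    @property
    def volume(self) -> float:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        r_mid = 0.5 * (self.radii[:-1] + self.radii[1:])
        return float(np.sum(np.pi * r_mid**2 * seg))


@dataclass
class VesselTreeSpec:
    """A synthetic dermal vessel network with exact ground truth attached."""

    branches: list[TreeBranch]
    nodes: dict[int, np.ndarray]               # node id -> (z, y, x) um
    node_branches: dict[int, list[int]]        # node id -> incident branch ids
    dermis_band: tuple[float, float]           # [z_top, z_bottom] um
    epidermis_thickness: float                 # um
    domain: tuple[float, float, float]         # (z, y, x) extent in um

    @property
    def surface_z(self) -> float:
        return self.dermis_band[0] - self.epidermis_thickness

    def node_degree(self, node_id: int) -> int:
        return len(self.node_branches[node_id])

    def merged_branches(self) -> list[TreeBranch]:
        """Branches with chains through degree-2 nodes concatenated.

        A degree-2 node (e.g. where a recruited branch extends an endpoint) is
        invisible to a skeleton, so all morphometric ground truth is defined
        on the merged structure.
        """
        branches = [
            TreeBranch(b.points.copy(), b.radii.copy(), b.start_node, b.end_node)
            for b in self.branches
        ]
        incident: dict[int, list[int]] = {n: [] for n in self.nodes}
        for i, b in enumerate(branches):
            incident[b.start_node].append(i)
            incident[b.end_node].append(i)
        changed = True
        while changed:
            changed = False
            for node, ids in incident.items():
                live = [i for i in ids if branches[i] is not None]
                if len(live) != 2 or live[0] == live[1]:
                    continue
                i, j = live
                b1, b2 = branches[i], branches[j]
                p1, r1 = (b1.points, b1.radii)
                if b1.start_node == node:  # orient b1 to end at node
                    p1, r1 = p1[::-1], r1[::-1]
                    other1 = b1.end_node
                else:
                    other1 = b1.start_node
                p2, r2 = (b2.points, b2.radii)
                if b2.end_node == node:   # orient b2 to start at node
                    p2, r2 = p2[::-1], r2[::-1]
                    other2 = b2.start_node
                else:
                    other2 = b2.end_node
                merged = TreeBranch(
                    np.vstack([p1, p2[1:]]),
                    np.concatenate([r1, r2[1:]]),
                    other1,
                    other2,
                )
                branches[i] = merged
                branches[j] = None
                incident[other2] = [i if k == j else k for k in incident[other2]]
                incident[other1] = [i if k == j else k for k in incident[other1]]
                incident[node] = []
                changed = True
                break
        return [b for b in branches if b is not None]

    def ground_truth(self) -> dict:
        """Exact morphometric ground truth recomputed from the structure."""
        branches = self.merged_branches()
        degrees: dict[int, int] = {}
        for b in branches:
            for n in (b.start_node, b.end_node):
                degrees[n] = degrees.get(n, 0) + 1
        n_junctions = sum(1 for d in degrees.values() if d >= 3)
        types = {"J2J": 0, "J2E": 0, "E2E": 0}
        for b in branches:
            kinds = sorted(
                "J" if degrees[n] >= 3 else "E" for n in (b.start_node, b.end_node)
            )
            types["".join([kinds[1], "2", kinds[0]])] += 1
        lengths = np.array([b.length for b in branches])
        torts = np.array([b.tortuosity for b in branches])
        radii = np.array([b.mean_radius for b in branches])
        volumes = np.array([b.volume for b in branches])
        return {
            "n_branches": len(branches),
            "n_junctions": n_junctions,
            "n_endpoints": sum(1 for d in degrees.values() if d == 1),
            "n_j2j": types["J2J"],
            "n_j2e": types["J2E"],
            "n_e2e": types["E2E"],
            "branch_lengths": lengths,
            "branch_tortuosities": torts,
            "branch_mean_radii": radii,
            "branch_volumes": volumes,
            "avg_vessel_length": float(lengths.mean()) if len(lengths) else np.nan,
            "avg_vessel_diameter": float(2 * radii.mean()) if len(radii) else np.nan,
            "avg_vessel_volume": float(volumes.mean()) if len(volumes) else np.nan,
        }


def generate_vessel_tree(
    n_seeds: int = 4,
    branching_prob: float = 0.25,
    radius_range: tuple[float, float] = (12.0, 35.0),
    domain: tuple[float, float, float] = (900.0, 800.0, 800.0),
    seed: int = 0,
    dermis_band: tuple[float, float] = (200.0, 700.0),
    epidermis_thickness: float = 100.0,
    max_branches: int = 60,
    avoid_collisions: bool = True,
    min_steps_before_branch: int = 3,
    min_branch_len: float = 60.0,
    bifurcation_half_deg: tuple[float, float] = _BIFURCATION_ANGLE_DEG,
    collision_margin: float = _COLLISION_MARGIN_UM,
    band_clearance: float = 0.0,
) -> VesselTreeSpec:
    """Grow a vessel network by a branching random walk inside the dermis band.

    Radii taper with depth; a per-step ``branching_prob`` terminates the
    current branch at a junction and spawns two children diverging
    symmetrically from the parent direction.  Self-avoidance keeps unrelated
    branches from touching, and branches that terminate before
    ``min_branch_len`` micrometres are discarded, so the rasterised topology
    matches the stored ground truth.  ``min_steps_before_branch`` sets the
    minimum distance between consecutive junctions on one lineage (in steps
    of 15 um).
    """
    rng = np.random.default_rng(seed)
    z_top, z_bot = dermis_band
    if not (0 < radius_range[0] <= radius_range[1] < (z_bot - z_top) / 2):
        raise ValidationError(
            f"radius_range {radius_range} must lie in (0, dermis thickness/2)"
        )
    lateral_margin = radius_range[1] + 2 * collision_margin
    if domain[1] <= 2 * lateral_margin or domain[2] <= 2 * lateral_margin:
        raise ValidationError(f"domain {domain} too small for radius_range {radius_range}")
    if domain[0] < z_bot:
        raise ValidationError("domain depth must cover the dermis band")

    branches: list[TreeBranch] = []
    nodes: dict[int, np.ndarray] = {}
    node_branches: dict[int, list[int]] = {}
    occupied: list[np.ndarray] = []        # (point, radius) history of finished steps
    occupied_radii: list[float] = []

    def new_node(coord: np.ndarray) -> int:
        nid = len(nodes)
        nodes[nid] = coord.copy()
        node_branches[nid] = []
        return nid

    def depth_radius(r0: float, z: float) -> float:
        frac = np.clip((z - z_top) / (z_bot - z_top), 0.0, 1.0)
        return max(r0 * (1.0 - _TAPER * frac), radius_range[0] * 0.5)

    # seed points and initial directions; queue entries are
    # (start node, direction, base radius, generation, walk id, exempt walk ids)
    queue: list[tuple] = []
    seed_points: list[np.ndarray] = []
    occupied_wid: list[int] = []
    walk_counter = 0
    min_seed_dist = 2 * radius_range[1] + 4 * collision_margin
    for _ in range(n_seeds):
        for _attempt in range(200):
            inset_y = max(lateral_margin, 0.22 * domain[1])
            inset_x = max(lateral_margin, 0.22 * domain[2])
            p = np.array([
                rng.uniform(z_top + radius_range[1] + band_clearance,
                            z_bot - radius_range[1] - band_clearance),
                rng.uniform(inset_y, domain[1] - inset_y),
                rng.uniform(inset_x, domain[2] - inset_x),
            ])
            if all(np.linalg.norm(p - q) >= min_seed_dist for q in seed_points):
                break
        seed_points.append(p)
        d = rng.normal(size=3)
        d[0] *= 0.4  # bias walks laterally, like a dermal plexus
        d /= np.linalg.norm(d)
        r0 = rng.uniform(*radius_range)
        queue.append((new_node(p), d, r0, 0, walk_counter, frozenset()))
        walk_counter += 1

    while queue and len(branches) < max_branches:
        start_node, direction, r0, gen, wid, exempt_wids = queue.pop(0)
        p = nodes[start_node].copy()
        pts = [p.copy()]
        radii = [depth_radius(r0, p[0])]
        lo_steps = max(8, int(np.ceil(min_branch_len / _STEP_UM)) + 1)
        n_steps = int(rng.integers(lo_steps, max(28, lo_steps + 8)))
        ended_at_junction = False
        own_start = len(occupied)
        for step in range(n_steps):
            direction = direction + rng.normal(scale=0.25, size=3)
            direction /= np.linalg.norm(direction)
            q = p + _STEP_UM * direction
            # reflect off the dermis band and lateral walls
            if not (z_top + radii[-1] + band_clearance < q[0] < z_bot - radii[-1] - band_clearance):
                direction[0] *= -1
                q = p + _STEP_UM * direction
            hit_wall = False
            for ax, ext in ((1, domain[1]), (2, domain[2])):
                if not (lateral_margin < q[ax] < ext - lateral_margin):
                    hit_wall = True
            if hit_wall:
                break
            r_here = depth_radius(r0, q[0])
            if avoid_collisions:
                blocked = False
                if own_start > 0:
                    other = np.asarray(occupied[:own_start])
                    dist_q = np.linalg.norm(other - q, axis=1)
                    clearance = (
                        np.asarray(occupied_radii[:own_start]) + r_here + collision_margin
                    )
                    # points of the parent and sibling walks near the shared
                    # start node are exempt, otherwise children could never
                    # leave the junction; unrelated walks always block
                    dist_start = np.linalg.norm(other - nodes[start_node], axis=1)
                    related = np.isin(np.asarray(occupied_wid[:own_start]), list(exempt_wids)) \
                        if exempt_wids else np.zeros(own_start, dtype=bool)
                    exempt = related & (dist_start <= clearance + 3 * _STEP_UM)
                    blocked = ((dist_q < clearance) & ~exempt).any()
                # self-avoidance: the walk must not curl back onto its own
                # older points (the last few steps are trivially close)
                recent = int(np.ceil((2 * r_here + collision_margin) / _STEP_UM)) + 1
                if not blocked and len(pts) > recent:
                    own = np.asarray(pts[: len(pts) - recent])
                    own_r = np.asarray(radii[: len(pts) - recent])
                    dist_own = np.linalg.norm(own - q, axis=1)
                    blocked = (dist_own < own_r + r_here + collision_margin).any()
                if blocked:
                    break
            p = q
            pts.append(p.copy())
            radii.append(r_here)
            occupied.append(p.copy())
            occupied_radii.append(r_here)
            occupied_wid.append(wid)
            if (
                step >= min_steps_before_branch
                and rng.random() < branching_prob
                and len(branches) + len(queue) + 2 < max_branches
            ):
                ended_at_junction = True
                break
        if (len(pts) - 1) * _STEP_UM < min_branch_len:
            continue  # too short to survive spur pruning; discard
        end_node = new_node(p)
        bid = len(branches)
        branches.append(
            TreeBranch(np.array(pts), np.array(radii), start_node, end_node)
        )
        node_branches[start_node].append(bid)
        node_branches[end_node].append(bid)
        if ended_at_junction:
            child_r = max(r0 * _CHILD_RADIUS_FACTOR, radius_range[0])
            # symmetric bifurcation: children diverge by +/- a random
            # half-angle in a random plane through the parent direction
            normal = rng.normal(size=3)
            normal -= np.dot(normal, direction) * direction
            normal /= np.linalg.norm(normal)
            half = np.radians(rng.uniform(*bifurcation_half_deg))
            wid_a, wid_b = walk_counter, walk_counter + 1
            walk_counter += 2
            for sign, cw, sib in ((1.0, wid_a, wid_b), (-1.0, wid_b, wid_a)):
                child_dir = np.cos(half) * direction + sign * np.sin(half) * normal
                child_dir /= np.linalg.norm(child_dir)
                queue.append((end_node, child_dir, child_r, gen + 1, cw,
                              frozenset({wid, sib})))

    # drop isolated nodes left by degenerate walks
    used = {n for nb in (b for b in branches) for n in (nb.start_node, nb.end_node)}
    nodes = {n: c for n, c in nodes.items() if n in used}
    node_branches = {n: ids for n, ids in node_branches.items() if n in used}

    spec = VesselTreeSpec(
        branches=branches,
        nodes=nodes,
        node_branches=node_branches,
        dermis_band=dermis_band,
        epidermis_thickness=epidermis_thickness,
        domain=domain,
    )
    logger.debug(
        "generated tree: %d branches, %d junctions",
        len(branches), spec.ground_truth()["n_junctions"],
    )
    return spec


#: Recommended voxel spacing for the fixture networks below.
PLEXUS_SPACING: tuple[float, float, float] = (8.0, 8.0, 8.0)
TUBE_FIELD_SPACING: tuple[float, float, float] = (5.0, 5.0, 5.0)


def plexus_phantom(seed: int = 0) -> VesselTreeSpec:
    """A junction-rich branching network for topology validation.

    Radii (24-32 um) stay at or above three voxels on the recommended
    :data:`PLEXUS_SPACING` grid, junctions sit at least 150 um apart and
    branches diverge widely, so the skeletonised topology of the noiseless
    rasterisation reproduces the ground-truth branch and junction counts.
    """
    return generate_vessel_tree(
        n_seeds=3, branching_prob=0.2, radius_range=(24.0, 32.0),
        domain=(900.0, 900.0, 900.0), seed=seed, max_branches=25,
        min_steps_before_branch=10, min_branch_len=150.0,
        bifurcation_half_deg=(40.0, 60.0),
    )


def tube_field_phantom(seed: int = 0) -> VesselTreeSpec:
    """A field of disjoint unbranched vessels for reactivity recovery.

    Junction blobs are the one skeleton region whose medial axis fragments
    under strong dilation, so the diameter-change recovery fixture uses
    unbranched tubes whose radii remain resolvable (>= 2.5 voxels on the
    :data:`TUBE_FIELD_SPACING` grid) in every PORH phase, including the
    occlusion constriction.
    """
    return generate_vessel_tree(
        n_seeds=6, branching_prob=0.0, radius_range=(20.0, 28.0),
        domain=(900.0, 900.0, 900.0), seed=seed, max_branches=16,
        min_branch_len=150.0, collision_margin=40.0, band_clearance=10.0,
    )


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def rasterize(
    spec: VesselTreeSpec,
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0),
    band_radius_threshold: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    epidermis_intensity: float = 1.0,
    return_masks: bool = False,
):
    """Rasterise a vessel tree into a dual-band volume.

    Voxels whose centre lies within the local radius of a centreline get
    intensity 1.  Branches with mean radius >= ``band_radius_threshold`` are
    written to the low band, the rest to the high band.  An epidermis slab of
    ``epidermis_intensity`` is written above the dermis in both bands.
    Gaussian noise (sd ``noise_sd``) is added and clipped at zero.
    """
    spacing = np.asarray(spacing, dtype=float)
    shape = tuple(int(round(e / s)) for e, s in zip(spec.domain, spacing))
    low = np.zeros(shape)
    high = np.zeros(shape)
    low_mask = np.zeros(shape, dtype=bool)
    high_mask = np.zeros(shape, dtype=bool)
    for b in spec.branches:
        target = low_mask if b.mean_radius >= band_radius_threshold else high_mask
        pts, radii = _resample_polyline(b.points, b.radii, min(spacing) / 2.0)
        for p, r in zip(pts, radii):
            _paint_ball(target, p, r, spacing)
    low[low_mask] = 1.0
    high[high_mask] = 1.0

    # epidermis slab above the dermis band in both bands
    z = (np.arange(shape[0]) + 0.5) * spacing[0]
    ep_sel = (z >= spec.surface_z) & (z < spec.dermis_band[0])
    low[ep_sel, :, :] = np.maximum(low[ep_sel, :, :], epidermis_intensity)
    high[ep_sel, :, :] = np.maximum(high[ep_sel, :, :], epidermis_intensity)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        low = np.clip(low + rng.normal(scale=noise_sd, size=shape), 0, None)
        high = np.clip(high + rng.normal(scale=noise_sd, size=shape), 0, None)

    volume = DualBandVolume(low, high, tuple(spacing))
    if return_masks:
        return volume, low_mask, high_mask
    return volume


def _resample_polyline(points: np.ndarray, radii: np.ndarray, step: float):
    """Resample a polyline at spacing <= step so painted balls overlap."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1], radii[:1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    si = np.linspace(0.0, total, n)
    out_p = np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])
    out_r = np.interp(si, s, radii)
    return out_p, out_r


_BALL_CACHE: dict = {}


def _paint_ball(mask: np.ndarray, centre: np.ndarray, radius: float, spacing: np.ndarray):
    key = (round(float(radius), 1), tuple(spacing))
    if key not in _BALL_CACHE:
        half = np.ceil(radius / spacing).astype(int)
        grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
        d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
        _BALL_CACHE[key] = (np.argwhere(d2 <= radius**2) - half, half)
    offsets, half = _BALL_CACHE[key]
    idx = np.floor(centre / spacing).astype(int)
    vox = offsets + idx
    ok = np.all((vox >= 0) & (vox < np.asarray(mask.shape)), axis=1)
    vox = vox[ok]
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True


# ---------------------------------------------------------------------------
# PORH reactivity
# ---------------------------------------------------------------------------

@dataclass
class PhaseFactors:
    radius: float = 1.0
    recruit_prob: float = 0.0      # probability each endpoint sprouts a branch
    intensity: float = 1.0


@dataclass
class ReactivityModel:
    """Per-phase, per-group multiplicative reactivity factors.

    Defaults encode the study conditions: occlusion minute 1 is near baseline,
    minutes 2-3 show a mild radius reduction, and the healthy hyperemic
    response (dilation plus capillary recruitment at cuff release) is larger
    than the blunted patient response.
    """

    factors: dict = field(default_factory=lambda: {
        "healthy": {
            "baseline": PhaseFactors(),
            "occl1": PhaseFactors(1.0, 0.0, 1.0),
            "occl2": PhaseFactors(0.9, 0.0, 0.95),
            "occl3": PhaseFactors(0.9, 0.0, 0.95),
            "hyp1": PhaseFactors(1.30, 0.5, 1.2),
            "hyp2": PhaseFactors(1.15, 0.25, 1.1),
        },
        "patient": {
            "baseline": PhaseFactors(),
            "occl1": PhaseFactors(1.0, 0.0, 1.0),
            "occl2": PhaseFactors(0.9, 0.0, 0.95),
            "occl3": PhaseFactors(0.9, 0.0, 0.95),
            "hyp1": PhaseFactors(1.08, 0.1, 1.05),
            "hyp2": PhaseFactors(1.05, 0.05, 1.0),
        },
    })
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for group, phases in self.factors.items():
            b = phases["baseline"]
            if not (b.radius == 1.0 and b.recruit_prob == 0.0 and b.intensity == 1.0):
                raise ValidationError(f"baseline factors must be 1 for group {group!r}")
            for tp in ("occl1", "occl2", "occl3"):
                if phases[tp].radius > 1.0:
                    raise ValidationError("occlusion radius factors must be <= 1")
        h = self.factors["healthy"]["hyp1"].radius
        p = self.factors["patient"]["hyp1"].radius
        if h < p:
            raise ValidationError(
                "healthy hyperemia radius factor must not be below the patient factor"
            )
        if h == p:
            logger.info("reactivity model encodes no group effect (null dynamics)")


def apply_phase(spec: VesselTreeSpec, phase: PhaseFactors, rng: np.random.Generator) -> VesselTreeSpec:
    """Return a copy of the tree with phase factors applied."""
    out = copy.deepcopy(spec)
    for b in out.branches:
        b.radii = b.radii * phase.radius
    if phase.recruit_prob > 0:
        degrees = {n: out.node_degree(n) for n in out.nodes}
        endpoints = [n for n, d in degrees.items() if d == 1]
        for nid in endpoints:
            if rng.random() >= phase.recruit_prob:
                continue
            incident = out.branches[out.node_branches[nid][0]]
            anchor = out.nodes[nid]
            tail = incident.points[-1] - incident.points[0]
            norm = np.linalg.norm(tail)
            direction = tail / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
            direction = direction + rng.normal(scale=0.5, size=3)
            direction /= np.linalg.norm(direction)
            n_steps = int(rng.integers(5, 10))
            pts = [anchor.copy()]
            r = incident.radii[-1] * 0.8
            p = anchor.copy()
            z_top, z_bot = out.dermis_band
            for _ in range(n_steps):
                q = p + _STEP_UM * direction
                if not (z_top + r < q[0] < z_bot - r):
                    direction[0] *= -1
                    q = p + _STEP_UM * direction
                p = q
                pts.append(p.copy())
            end = len(out.nodes)
            while end in out.nodes:
                end += 1
            out.nodes[end] = p.copy()
            out.node_branches[end] = []
            bid = len(out.branches)
            out.branches.append(
                TreeBranch(np.array(pts), np.full(len(pts), r), nid, end)
            )
            out.node_branches[nid].append(bid)
            out.node_branches[end].append(bid)
    return out


def generate_porh_series(
    spec: VesselTreeSpec,
    model: ReactivityModel | None = None,
    group: str = "healthy",
    seed: int = 0,
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0),
    band_radius_threshold: float = 30.0,
):
    """Generate the six PORH-phase volumes plus per-phase ground truth.

    Returns ``(volumes, ground_truth)`` where ``volumes`` maps timepoint ->
    DualBandVolume and ``ground_truth`` maps timepoint -> the exact tree
    morphometry dict, augmented with ground-truth percentage changes
    (``delta_avg_vessel_diameter_pct`` etc.) relative to baseline.

    The noise field is frozen across the timeline (same noise seed per phase),
    emulating static speckle, so null dynamics produce identical volumes.
    """
    model = model or ReactivityModel()
    model.validate()
    if group not in model.factors:
        raise ValidationError(
            f"unknown group {group!r}; expected one of {sorted(model.factors)}"
        )
    rng = np.random.default_rng(seed)
    recruit_seeds = {tp: rng.integers(2**31) for tp in TIMEPOINTS}
    noise_seed = int(rng.integers(2**31))
    volumes: dict[str, DualBandVolume] = {}
    truth: dict[str, dict] = {}
    for tp in TIMEPOINTS:
        phase = model.factors[group][tp]
        tree = apply_phase(spec, phase, np.random.default_rng(recruit_seeds[tp]))
        vol = rasterize(
            tree, spacing=spacing, band_radius_threshold=band_radius_threshold,
            noise_sd=model.noise_sd, seed=noise_seed,
        )
        vol.low *= phase.intensity
        vol.high *= phase.intensity
        volumes[tp] = vol
        truth[tp] = tree.ground_truth()
    base = truth["baseline"]
    for tp in POST_TIMEPOINTS:
        for key in ("avg_vessel_diameter", "avg_vessel_length", "avg_vessel_volume", "n_branches"):
            b = base[key]
            truth[tp][f"delta_{key}_pct"] = (
                100.0 * (truth[tp][key] - b) / b if b else np.nan
            )
    return volumes, truth


# ---------------------------------------------------------------------------
# Feature-level cohort generator
# ---------------------------------------------------------------------------

#: Log-scale medians of the 18 baseline features (typical magnitudes for a
#: 4x2 mm forearm scan) and a common log-sd.  Baselines are drawn identically
#: for both groups, so the cohort is null at baseline by construction.
BASELINE_MEDIANS: dict[str, float] = {
    "avg_junction_angle": 100.0,
    "avg_vessel_length": 300.0,
    "avg_tortuosity": 1.3,
    "length_to_width_ratio": 8.0,
    "avg_vessel_diameter": 40.0,
    "avg_vessel_volume": 4.0e5,
    "num_vessels": 150.0,
    "junction_density": 40.0,
    "vascular_density": 0.08,
    "junctions_to_vessels_ratio": 0.4,
    "num_j2j_branches": 60.0,
    "num_j2e_branches": 80.0,
    "num_junctions": 60.0,
    "de_thickness": 500.0,
    "total_vessel_area": 2.0,
    "mean_signal_vessels": 0.5,
    "mean_signal_de": 0.2,
    "de_area": 1.5,
}

BASELINE_LOG_SD = 0.25

#: Standard deviation of per-subject percentage changes (percentage points).
DELTA_SD = 10.0

#: Healthy-group mean percentage change per phase (same shape for every
#: feature unless an effect profile overrides it).
_HEALTHY_DELTA = {"occl1": 0.0, "occl2": -8.0, "occl3": -8.0, "hyp1": 20.0, "hyp2": 10.0}

#: Nine features carrying the group effect in the "strong"/"paper_like"
#: presets: three per scale of detail.
EFFECT_FEATURES: tuple[str, ...] = (
    "avg_vessel_length", "avg_vessel_diameter", "avg_vessel_volume",
    "num_vessels", "num_j2j_branches", "num_junctions",
    "de_thickness", "total_vessel_area", "mean_signal_de",
)


def effect_preset(name: str) -> pd.DataFrame:
    """Patient-minus-healthy offsets of the mean percentage change.

    Rows: post-baseline timepoints; columns: the 18 features.  ``null`` is all
    zero; ``strong`` shifts nine features (three per scale) by 2 within-group
    SDs at hyperemia minute 1 (half that at minute 2); ``paper_like`` uses a
    1-SD shift on the same nine features.
    """
    offs = pd.DataFrame(0.0, index=list(POST_TIMEPOINTS), columns=list(FEATURE_NAMES))
    if name == "null":
        return offs
    if name == "strong":
        shift = -2.0 * DELTA_SD
    elif name == "paper_like":
        shift = -1.0 * DELTA_SD
    else:
        raise ValidationError(f"unknown effect preset {name!r}")
    offs.loc["hyp1", list(EFFECT_FEATURES)] = shift
    offs.loc["hyp2", list(EFFECT_FEATURES)] = shift / 2.0
    return offs


#: Bernoulli frequencies of the binary covariates per group and the
#: age/BMI normal parameters (identical across groups by default).
DEFAULT_COVARIATE_MODEL: dict = {
    "age": (67.0, 10.0),
    "bmi": (25.7, 3.4),
    "sex_male": {"healthy": 5 / 13, "patient": 9 / 13},
    "hypertension": {"healthy": 4 / 13, "patient": 10 / 13},
    "smoking": {"healthy": 0 / 13, "patient": 4 / 13},
    "hyperlipidemia": {"healthy": 2 / 13, "patient": 2 / 13},
    "diabetes": {"healthy": 0 / 13, "patient": 2 / 13},
}


def generate_cohort(
    n_per_group: int = 13,
    effect_sizes: pd.DataFrame | str = "null",
    covariate_model: dict | None = None,
    seed: int = 0,
    delta_sd: float = DELTA_SD,
) -> CohortTable:
    """Draw a feature-level cohort without imaging.

    Baseline features are log-normal and identically distributed in both
    groups.  Post-baseline values are ``baseline * (1 + delta/100)`` with
    ``delta ~ Normal(mu, delta_sd)`` where ``mu`` follows the healthy response
    profile plus, for patients, the ``effect_sizes`` offset (a preset name or
    a timepoint x feature DataFrame of patient-minus-healthy offsets in
    percentage points).
    """
    if n_per_group < 2:
        raise ValidationError("need at least 2 subjects per group")
    if isinstance(effect_sizes, str):
        effect_sizes = effect_preset(effect_sizes)
    cov_model = covariate_model or DEFAULT_COVARIATE_MODEL
    rng = np.random.default_rng(seed)
    names = list(FEATURE_NAMES)
    log_medians = np.log([BASELINE_MEDIANS[f] for f in names])

    rows = []
    cov_rows = []
    for g, gname in enumerate(("healthy", "patient")):
        for i in range(n_per_group):
            subject = f"{gname[0].upper()}{i + 1:02d}"
            baseline = np.exp(rng.normal(log_medians, BASELINE_LOG_SD))
            rows.append((subject, "baseline", baseline))
            for tp in POST_TIMEPOINTS:
                mu = np.full(len(names), _HEALTHY_DELTA[tp])
                if g == 1:
                    mu = mu + effect_sizes.loc[tp, names].to_numpy(dtype=float)
                delta = rng.normal(mu, delta_sd)
                rows.append((subject, tp, baseline * (1 + delta / 100.0)))
            cov_rows.append({
                "subject": subject,
                "group": g,
                "age": rng.normal(*cov_model["age"]),
                "sex": int(rng.random() < cov_model["sex_male"][gname]),
                "bmi": rng.normal(*cov_model["bmi"]),
                "hypertension": int(rng.random() < cov_model["hypertension"][gname]),
                "smoking": int(rng.random() < cov_model["smoking"][gname]),
                "hyperlipidemia": int(rng.random() < cov_model["hyperlipidemia"][gname]),
                "diabetes": int(rng.random() < cov_model["diabetes"][gname]),
            })
    index = pd.MultiIndex.from_tuples(
        [(s, tp) for s, tp, _ in rows], names=["subject", "timepoint"]
    )
    features = pd.DataFrame([v for _, _, v in rows], index=index, columns=names)
    covariates = pd.DataFrame(cov_rows).set_index("subject")[
        ["group", *COVARIATE_NAMES]
    ]
    return CohortTable(features=features, covariates=covariates)
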