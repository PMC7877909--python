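"""Synthetic inputs with planted ground truth.

Every input the pipeline consumes can be generated here with machine-readable
truth: a labelled neuropil atlas (34 regions by default), two-channel tracing
volumes in which the postsynaptic signal is split into neurites genuinely
connected to the presynaptic terminal field versus planted off-target
clutter, nine-layer fan-shaped-body sub-parcellations, paired soma channels
with a known co-localized subset, arena trajectories from closed-form motion
models, and calcium traces with a known stimulus onset and response
amplitude.

All generators are pure functions of their arguments including the seed:
the same call twice returns byte-identical output.  No optical realism is
attempted (no PSF, bleaching or scattering) and the region shapes are
compact blobs, not anatomical neuropils; what the generators guarantee is
the *topology* and *bookkeeping* that the quantification stages are defined
on (connectivity to terminals, disjoint clutter, exact voxel allocations,
closed-form kinematics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .behavior import Trajectory
from .calcium import CalciumTrace
from .volio import LabelAtlas, VolumeImage

__all__ = [
    "REGION_ABBREVIATIONS",
    "TracingPlan",
    "GroundTruth",
    "TrajectoryTruth",
    "CalciumTruth",
    "Stationary",
    "Straight",
    "Circle",
    "CorrelatedWalk",
    "generate_atlas",
    "generate_fsb_layers",
    "generate_tracing_brain",
    "generate_cell_channels",
    "generate_trajectories",
    "generate_calcium_traces",
]

#: The 34 central-brain neuropil regions of the standard-brain parcellation.
REGION_ABBREVIATIONS: list[tuple[str, str]] = [
    ("AL", "antennal lobe"),
    ("AMMC", "antennal mechanosensory and motor center"),
    ("ATL", "antler"),
    ("AVLP", "anterior ventrolateral protocerebrum"),
    ("CRE", "crepine"),
    ("EB", "ellipsoid body"),
    ("EPA", "epaulette"),
    ("FSB", "fan-shaped body"),
    ("FLA", "flange"),
    ("GA", "shoulder of lateral accessory lobe"),
    ("GOR", "gorget of ventral complex"),
    ("IB", "interior bridge"),
    ("ICL", "inferior clamp"),
    ("IPS", "inferior posterior slope"),
    ("IVLP", "inferior ventrolateral protocerebrum"),
    ("LAL", "lateral accessory lobe"),
    ("LB", "bulb of lateral complex"),
    ("LH", "lateral horn"),
    ("MB", "mushroom body"),
    ("NO", "noduli"),
    ("OTU", "optic tubercle"),
    ("PB", "protocerebral bridge"),
    ("PLP", "posterior lateral protocerebrum"),
    ("PRW", "prow"),
    ("PVLP", "posterior ventrolateral protocerebrum"),
    ("SAD", "saddle"),
    ("SCL", "superior clamp"),
    ("SEG", "subesophageal ganglion"),
    ("SIP", "superior intermediate protocerebrum"),
    ("SLP", "superior lateral protocerebrum"),
    ("SMP", "superior medial protocerebrum"),
    ("SPS", "superior posterior plate"),
    ("VES", "vest of ventral complex"),
    ("WED", "wedge"),
]

_SIGNAL = 100.0  # planted fluorescence amplitude, a.u.
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


# ---------------------------------------------------------------------------
# plans and truth containers

@dataclass
class TracingPlan:
    """Recipe for one synthetic tracing specimen."""

    target_regions: list[tuple[int, float]]      # (region id, weight in [0,1])
    terminal_region: int
    n_clutter_components: int = 0
    clutter_volume_range: tuple[int, int] = (20, 60)   # voxels per blob
    noise_sigma: float = 0.0                     # intensity a.u.
    neurite_step: int = 1                        # voxels per random-walk move
    n_neurite_voxels: int = 400                  # total neurite voxel budget
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_regions:
            total = sum(w for _, w in self.target_regions)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("target-region weights must sum to 1")
            if any(not 0 <= w <= 1 for _, w in self.target_regions):
                raise ValueError("weights must be in [0, 1]")
        if self.n_clutter_components < 0:
            raise ValueError("n_clutter_components must be >= 0")
        lo, hi = self.clutter_volume_range
        if lo < 1 or hi < lo:
            raise ValueError("clutter_volume_range must be a positive interval")
        if self.neurite_step < 1:
            raise ValueError("neurite_step must be >= 1")


@dataclass
class TrajectoryTruth:
    """Analytic kinematics for deterministic motion models (None otherwise)."""

    pathlength: float | None          # mm
    mean_speed: float | None          # mm/s
    mean_angular_speed: float | None  # deg/s


@dataclass
class CalciumTruth:
    onset_index: int
    amplitude_ratio: float
    baseline: float


@dataclass
class GroundTruth:
    """Planted truth for one synthetic input (fields filled as applicable)."""

    connected_mask: np.ndarray | None = None
    clutter_mask: np.ndarray | None = None
    terminal_mask: np.ndarray | None = None
    per_region_planted_fraction: dict[int, float] = field(default_factory=dict)
    planted_coloc_count: int = 0
    planted_cell_centroids: dict[str, np.ndarray] = field(default_factory=dict)
    trajectory_truth: dict[str, TrajectoryTruth] = field(default_factory=dict)
    calcium_truth: CalciumTruth | None = None
    partial: bool = False             # set when a walk budget was unreachable

    @property
    def connected_voxel_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, np.argwhere(self.connected_mask)))

    @property
    def clutter_voxel_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, np.argwhere(self.clutter_mask)))


# ---------------------------------------------------------------------------
# atlas

def generate_atlas(grid_shape: tuple[int, int, int], n_regions: int = 34,
                   seed: int = 0) -> LabelAtlas:
    """Pack ``n_regions`` disjoint compact blobs into a label grid.

    Region centers are rejection-sampled with a minimum pairwise distance
    scaled to the per-region volume share; each voxel within reach of a
    center joins that center's (Voronoi) region, so regions are pairwise
    disjoint by construction.  With ``n_regions=34`` the region table
    carries the standard 34 central-brain abbreviations.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError("grid_shape must be three positive integers")
    rng = np.random.default_rng(seed)

    d_min = max(2.0, 0.7 * (np.prod(shape) / n_regions) ** (1.0 / 3.0))
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * n_regions
    while len(centers) < n_regions:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"grid {shape} too small to host {n_regions} disjoint regions")
        cand = rng.uniform([0.5] * 3, np.array(shape) - 0.5)
        if all(np.linalg.norm(cand - c) >= d_min for c in centers):
            centers.append(cand)
    centers_arr = np.array(centers)

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    d = np.linalg.norm(coords[:, None, :] - centers_arr[None, :, :], axis=2)
    nearest = d.argmin(axis=1)
    nearest_d = d[np.arange(len(coords)), nearest]
    radius = max(1.5, d_min / 2.0)
    labels = np.where(nearest_d <= radius, nearest + 1, 0)
    labels = labels.reshape(shape).astype(np.int64)

    if len(set(np.unique(labels)) - {0}) != n_regions:
        raise ValueError(
            f"grid {shape} too small to host {n_regions} disjoint regions")

    if n_regions == len(REGION_ABBREVIATIONS):
        rows = [{"id": i + 1, "abbreviation": ab, "name": nm}
                for i, (ab, nm) in enumerate(REGION_ABBREVIATIONS)]
    else:
        rows = [{"id": i + 1, "abbreviation": f"R{i + 1:02d}",
                 "name": f"synthetic region {i + 1}"}
                for i in range(n_regions)]
    return LabelAtlas(labels=labels, region_table=pd.DataFrame(rows))


def generate_fsb_layers(fsb_mask: np.ndarray, n_layers: int = 9,
                        axis: int = 0) -> np.ndarray:
    """Partition a mask into contiguous slabs (layer 1 = ventral end).

    Every in-mask voxel gets exactly one layer label 1..n_layers; slabs are
    ordered along ``axis``.
    """
    fsb_mask = np.asarray(fsb_mask, dtype=bool)
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    if not fsb_mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(fsb_mask)[:, axis]
    lo, hi = int(idx.min()), int(idx.max())
    extent = hi - lo + 1
    coord = np.arange(fsb_mask.shape[axis])
    layer_of = 1 + np.clip((coord - lo) * n_layers // extent, 0, n_layers - 1)
    shape = [1, 1, 1]
    shape[axis] = -1
    out = np.where(fsb_mask, layer_of.reshape(shape), 0)
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# tracing volumes

def _region_centroid(labels: np.ndarray, region_id: int) -> np.ndarray:
    vox = np.argwhere(labels == region_id)
    if len(vox) == 0:
        raise ValueError(f"region {region_id} not present in atlas")
    return vox.mean(axis=0)


def _terminal_field(labels: np.ndarray, region_id: int,
                    n_voxels: int = 40) -> np.ndarray:
    """Compact subset of the terminal region nearest its centroid."""
    vox = np.argwhere(labels == region_id)
    c = vox.mean(axis=0)
    order = np.argsort(np.linalg.norm(vox - c, axis=1), kind="stable")
    keep = vox[order[: min(n_voxels, len(vox))]]
    mask = np.zeros(labels.shape, dtype=bool)
    mask[tuple(keep.T)] = True
    return mask


def _grow_neurites(labels: np.ndarray, terminal_mask: np.ndarray,
                   plan: TracingPlan, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, bool]:
    """Biased unit-step random walks from terminal voxels into each target
    region; unit steps guarantee 26-connectivity to the terminal field."""
    shape = np.array(labels.shape)
    mask = np.zeros(labels.shape, dtype=bool)
    partial = False
    terminals = np.argwhere(terminal_mask)

    def walk(region_id: int, centroid: np.ndarray, quota: int,
             passable: np.ndarray) -> int:
        """One walk from a terminal voxel; plants up to ``quota`` new raw
        in-region voxels.  Returns the number planted.

        Like real neurite bundles, which run through inter-neuropil tracts
        rather than through unrelated neuropils, the walk keeps a 1-voxel
        standoff from foreign regions (so even the dilated tube cannot
        enter them); only background, the target region and the terminal
        region are traversable.
        """
        pos = terminals[rng.integers(len(terminals))].copy()
        mask[tuple(pos)] = True
        planted = 0
        for _step in range(4000 * plan.neurite_step):
            if planted >= quota:
                break
            if labels[tuple(pos)] == region_id:
                move = rng.integers(-1, 2, size=3)
            else:
                move = np.sign(centroid - pos).astype(int)
                flip = rng.random(3) < 0.08
                move[flip] = rng.integers(-1, 2, size=int(flip.sum()))
            cand = np.clip(pos + move, 0, shape - 1)
            if not passable[tuple(cand)]:
                for _retry in range(8):   # deflect around foreign neuropil
                    alt = np.clip(pos + rng.integers(-1, 2, size=3),
                                  0, shape - 1)
                    if passable[tuple(alt)]:
                        cand = alt
                        break
                else:
                    cand = pos
            pos = cand
            key = tuple(pos)
            if not mask[key]:
                mask[key] = True
                if labels[key] == region_id:
                    planted += 1
        return planted

    # budgets are enforced on the *dilated* tube (what the pipeline sees):
    # grow in chunks, re-measuring the dilated in-region count, because the
    # 1-voxel dilation inflates small neurite sets proportionally more
    for region_id, weight in plan.target_regions:
        centroid = _region_centroid(labels, region_id)
        region = labels == region_id
        # a region cannot host more tube voxels than ~60% of its volume
        budget = min(int(round(weight * plan.n_neurite_voxels)),
                     int(0.6 * region.sum()))
        foreign = (labels != 0) & ~region & (labels != plan.terminal_region)
        passable = ~(ndimage.binary_dilation(foreign, structure=_STRUCT26)
                     & ~(region | (labels == plan.terminal_region)))
        for _attempt in range(300):
            dilated_count = int(
                (ndimage.binary_dilation(mask, structure=_STRUCT26)
                 & region).sum())
            deficit = budget - dilated_count
            if deficit <= 0:
                break
            # each raw voxel dilates to at most ~9 new in-region voxels, so
            # keep chunks small enough not to overshoot the dilated budget
            got = walk(region_id, centroid, max(1, deficit // 9), passable)
            if got == 0 and deficit > budget // 10:
                continue
        else:
            partial = True
            warnings.warn(
                f"region {region_id}: neurite budget {budget} not reached; "
                f"truth flagged partial", stacklevel=3)
    # tube radius 1 voxel; dilation of a 26-connected path stays connected
    return ndimage.binary_dilation(mask, structure=_STRUCT26), partial


def _place_clutter(connected: np.ndarray, terminal: np.ndarray,
                   plan: TracingPlan, rng: np.random.Generator) -> np.ndarray:
    """Blobs with no 26-path to the terminals: every candidate keeps a
    Chebyshev distance >= 2 from the connected set."""
    shape = np.array(connected.shape)
    forbidden = ndimage.binary_dilation(connected | terminal,
                                        structure=_STRUCT26, iterations=2)
    clutter = np.zeros(connected.shape, dtype=bool)
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in connected.shape),
                             indexing="ij")
    for i in range(plan.n_clutter_components):
        vol = rng.integers(plan.clutter_volume_range[0],
                           plan.clutter_volume_range[1] + 1)
        radius = max(1.0, (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))
        placed = False
        for _try in range(500):
            center = rng.uniform([0.0] * 3, shape - 1.0)
            ball = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                    + (xx - center[2]) ** 2) <= radius ** 2
            if not ball.any():
                continue
            near = ndimage.binary_dilation(ball, structure=_STRUCT26,
                                           iterations=2)
            if (ball & forbidden).any() or (near & clutter).any():
                continue
            clutter |= ball
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place clutter blob {i + 1}/"
                f"{plan.n_clutter_components} disjoint from the signal")
    return clutter


def generate_tracing_brain(
    atlas: LabelAtlas, plan: TracingPlan,
) -> tuple[VolumeImage, VolumeImage, GroundTruth]:
    """Two-channel tracing specimen with exact connectivity truth.

    The presynaptic channel holds a compact terminal field inside the
    terminal region.  The postsynaptic channel holds neurite tubes grown by
    biased random walk from terminal voxels into the target regions (voxel
    allocation proportional to the plan weights), plus clutter blobs with no
    26-connected suprathreshold path to the terminals, plus additive
    Gaussian noise on the postsynaptic channel.
    """
    labels = atlas.labels
    known = set(atlas.region_ids)
    for rid, _ in plan.target_regions:
        if rid not in known:
            raise ValueError(f"target region {rid} not in atlas")
    if plan.terminal_region not in known:
        raise ValueError(f"terminal region {plan.terminal_region} not in atlas")
    rng = np.random.default_rng(plan.seed)

    terminal = _terminal_field(labels, plan.terminal_region)
    connected, partial = _grow_neurites(labels, terminal, plan, rng)
    clutter = _place_clutter(connected, terminal, plan, rng)

    pre = np.zeros(labels.shape, dtype=np.float32)
    pre[terminal] = _SIGNAL
    post = np.zeros(labels.shape, dtype=np.float32)
    post[connected | clutter] = _SIGNAL
    if plan.noise_sigma > 0:
        post = post + rng.normal(0.0, plan.noise_sigma,
                                 size=post.shape).astype(np.float32)
        post = np.clip(post, 0.0, None)

    target_ids = [rid for rid, _ in plan.target_regions]
    in_targets = np.isin(labels, target_ids) & connected
    total = int(in_targets.sum())
    fractions = {
        rid: (float(((labels == rid) & connected).sum()) / total
              if total else 0.0)
        for rid in target_ids
    }
    truth = GroundTruth(connected_mask=connected, clutter_mask=clutter,
                        terminal_mask=terminal,
                        per_region_planted_fraction=fractions, partial=partial)
    return (
        VolumeImage(pre, channel_name="presynaptic"),
        VolumeImage(post, channel_name="postsynaptic"),
        truth,
    )


# ---------------------------------------------------------------------------
# soma channels

def _sample_points(rng: np.random.Generator, n: int, shape: np.ndarray,
                   margin: float, min_separation: float,
                   existing: list[np.ndarray]) -> list[np.ndarray]:
    pts = list(existing)
    out: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(4000):
            cand = rng.uniform([margin] * 3, shape - 1 - margin)
            if all(np.linalg.norm(cand - p) >= min_separation for p in pts):
                pts.append(cand)
                out.append(cand)
                break
        else:
            raise ValueError(
                f"could not pack {n} somata at separation {min_separation} "
                f"into grid {tuple(int(s) for s in shape)}")
    return out


def generate_cell_channels(
    grid_shape: tuple[int, int, int],
    n_th: int,
    n_tango: int,
    n_coloc: int,
    soma_radius: float = 3.0,
    min_separation: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[VolumeImage, VolumeImage, GroundTruth]:
    """Paired soma channels with exactly ``n_coloc`` shared centroids.

    Somata are spherical top-hats of ``soma_radius`` convolved with a
    1-voxel Gaussian; co-localized pairs share a centroid up to sub-voxel
    jitter (< 1 voxel).  All same-channel somata are at pairwise distance
    >= ``min_separation``.
    """
    if n_coloc > min(n_th, n_tango):
        raise ValueError("n_coloc cannot exceed min(n_th, n_tango)")
    shape = np.array(grid_shape, dtype=float)
    rng = np.random.default_rng(seed)
    margin = soma_radius + 1

    shared = _sample_points(rng, n_coloc, shape, margin, min_separation, [])
    th_only = _sample_points(rng, n_th - n_coloc, shape, margin,
                             min_separation, shared)
    tango_only = _sample_points(rng, n_tango - n_coloc, shape, margin,
                                min_separation, shared + th_only)
    th_pts = np.array(shared + th_only).reshape(-1, 3)
    jitter = rng.uniform(-0.45, 0.45, size=(n_coloc, 3))
    tango_pts = np.array(
        [s + j for s, j in zip(shared, jitter)] + tango_only).reshape(-1, 3)

    def render(points: np.ndarray) -> np.ndarray:
        vol = np.zeros(tuple(int(s) for s in grid_shape), dtype=np.float32)
        if len(points):
            zz, yy, xx = np.meshgrid(*(np.arange(int(s)) for s in grid_shape),
                                     indexing="ij")
            for p in points:
                ball = ((zz - p[0]) ** 2 + (yy - p[1]) ** 2
                        + (xx - p[2]) ** 2) <= soma_radius ** 2
                vol[ball] = _SIGNAL
        vol = ndimage.gaussian_filter(vol, sigma=1.0)
        if noise_sigma > 0:
            vol = vol + rng.normal(0.0, noise_sigma,
                                   size=vol.shape).astype(np.float32)
            vol = np.clip(vol, 0.0, None)
        return vol

    truth = GroundTruth(
        planted_coloc_count=n_coloc,
        planted_cell_centroids={"TH": th_pts, "tango": tango_pts},
    )
    return (
        VolumeImage(render(th_pts), channel_name="TH"),
        VolumeImage(render(tango_pts), channel_name="tango"),
        truth,
    )


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class Stationary:
    pass


@dataclass
class Straight:
    speed: float  # mm/s


@dataclass
class Circle:
    radius: float   # mm
    period: float   # s per revolution


@dataclass
class CorrelatedWalk:
    mu_speed: float = 5.0     # mm/s
    kappa_turn: float = 4.0   # heading concentration; higher = straighter


def generate_trajectories(
    n_flies: int,
    motion_model,
    fps: float = 33.0,
    duration: float = 60.0,
    arena_diameter: float = 37.0,
    seed: int = 0,
    genotype: str = "",
) -> tuple[list[Trajectory], dict[str, TrajectoryTruth]]:
    """Per-fly position series at exact 1/fps spacing spanning ``duration``.

    Series have round(fps*duration)+1 samples so the sampled span equals the
    nominal duration and the closed-form truths hold exactly.  Walkers are
    specularly reflected at the circular arena wall.
    """
    if fps <= 0 or duration <= 0:
        raise ValueError("fps and duration must be > 0")
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(fps * duration)) + 1
    dt = 1.0 / fps
    radius = arena_diameter / 2.0
    span = (n - 1) * dt

    trajs: list[Trajectory] = []
    truths: dict[str, TrajectoryTruth] = {}
    for i in range(n_flies):
        fly_id = f"fly{i:03d}"
        if isinstance(motion_model, Stationary):
            r = 0.8 * radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            pos = np.tile([r * np.cos(th), r * np.sin(th)], (n, 1))
            truth = TrajectoryTruth(0.0, 0.0, 0.0)
        elif isinstance(motion_model, Straight):
            v = motion_model.speed
            start_r = 0.5 * radius * np.sqrt(rng.random())
            start_th = rng.uniform(0, 2 * np.pi)
            p = np.array([start_r * np.cos(start_th),
                          start_r * np.sin(start_th)])
            heading = rng.uniform(0, 2 * np.pi)
            vel = v * np.array([np.cos(heading), np.sin(heading)])
            pos = np.empty((n, 2))
            pos[0] = p
            for t in range(1, n):
                cand = p + vel * dt
                if np.linalg.norm(cand) > radius:    # specular reflection
                    nhat = cand / np.linalg.norm(cand)
                    vel = vel - 2 * np.dot(vel, nhat) * nhat
                    cand = p + vel * dt
                    if np.linalg.norm(cand) > radius:
                        cand = cand / np.linalg.norm(cand) * radius
                p = cand
                pos[t] = p
            truth = TrajectoryTruth(v * span, v, 0.0)
        elif isinstance(motion_model, Circle):
            r, period = motion_model.radius, motion_model.period
            if r >= radius:
                raise ValueError("circle radius must fit inside the arena")
            th0 = rng.uniform(0, 2 * np.pi)
            t_axis = np.arange(n) * dt
            theta = th0 + 2 * np.pi * t_axis / period
            pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
            # chord length per frame, not arc length: the sampled series is
            # a polygon, and its closed-form pathlength is what we store
            chord = 2 * r * np.sin(np.pi * dt / period)
            truth = TrajectoryTruth(chord * (n - 1), chord * fps, 360.0 / period)
        elif isinstance(motion_model, CorrelatedWalk):
            heading = rng.uniform(0, 2 * np.pi)
            p = np.zeros(2)
            pos = np.empty((n, 2))
            pos[0] = p
            sd_turn = 1.0 / np.sqrt(motion_model.kappa_turn)
            for t in range(1, n):
                heading += rng.normal(0.0, sd_turn)
                speed = abs(rng.normal(motion_model.mu_speed,
                                       motion_model.mu_speed / 3.0))
                step = speed * dt * np.array([np.cos(heading), np.sin(heading)])
                cand = p + step
                if np.linalg.norm(cand) > radius:
                    heading += np.pi           # turn back toward the arena
                    cand = p
                p = cand
                pos[t] = p
            truth = TrajectoryTruth(None, None, None)
        else:
            raise TypeError(f"unknown motion model {motion_model!r}")
        trajs.append(Trajectory(fly_id=fly_id, positions=pos, fps=fps,
                                genotype=genotype))
        truths[fly_id] = truth
    return trajs, truths


# ---------------------------------------------------------------------------
# calcium traces

def generate_calcium_traces(
    n_reps: int,
    fps: float = 10.0,
    duration: float = 30.0,
    onset: float = 10.0,
    amplitude_ratio: float = 0.5,
    decay_tau: float = 2.0,
    baseline: float = 100.0,
    noise_sigma: float = 0.0,
    stim_duration: float = 0.45,
    seed: int = 0,
) -> tuple[list[CalciumTrace], GroundTruth]:
    """Replicate calcium traces with a planted exponential transient.

    Each trace equals the baseline F0 before onset; the stimulus interval
    (default 450 ms, the middle of the 400–500 ms optogenetic pulse) is
    flagged shutter-closed; after stimulus end the trace follows
    F0·(1 + a·exp(−(t − t_end)/τ)) so the first open frame carries ΔF/F
    exactly equal to the amplitude ratio a.
    """
    if not 0 < onset < duration:
        raise ValueError("onset must lie inside (0, duration)")
    if baseline <= 0:
        raise ValueError("baseline F0 must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(fps * duration))
    onset_idx = int(round(fps * onset))
    end_idx = onset_idx + max(1, int(round(fps * stim_duration)))
    if end_idx >= n:
        raise ValueError("stimulus extends past the recording")
    t = np.arange(n) / fps
    t_end = end_idx / fps

    traces: list[CalciumTrace] = []
    for rep in range(n_reps):
        f = np.full(n, baseline, dtype=float)
        post = t >= t_end
        f[post] = baseline * (
            1.0 + amplitude_ratio * np.exp(-(t[post] - t_end) / decay_tau))
        shutter = np.zeros(n, dtype=bool)
        shutter[onset_idx:end_idx] = True
        f[shutter] = 0.0
        if noise_sigma > 0:
            f = f + rng.normal(0.0, noise_sigma, size=n)
            f = np.clip(f, 0.0, None)
        traces.append(CalciumTrace(rep_id=f"rep{rep:03d}", F=f,
                                   onset_index=onset_idx, fps=fps,
                                   shutter_closed=shutter))
    truth = GroundTruth(calcium_truth=CalciumTruth(
        onset_index=onset_idx, amplitude_ratio=amplitude_ratio,
        baseline=baseline))
    return traces, truth
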