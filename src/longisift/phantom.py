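"""Synthetic longitudinal fixel phantoms with known ground truth.

The generator replaces signal-level dMRI simulation and fibre tracking with
direct geometric synthesis: white-matter bundles are straight tubes between
spherical endpoint nodes; fixel fibre densities are derived from the tube
geometry (fibre count x per-fibre area x per-voxel expected fibre length),
and tractograms are drawn as centreline-following polylines with random
radial offsets, optional waypoint jitter, and controllable false positives
that switch bundles at a crossing.

Three longitudinal models manipulate per-bundle fibre counts between two
sessions:

* Model 1 — a 75% fibre-count decrease in one isolated bundle;
* Model 2 — two crossing bundles, one halved, the other doubled;
* Model 3 — a central spherical lesion: every bundle whose centreline
  intersects it loses all fibres at the second timepoint.

Unchanged distractor bundles are always present so that error distributions
contain both affected and unaffected bundles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, NodeSet
from .grid import FixelSet, Tractogram, VoxelGrid, voxel_boundary_split

__all__ = [
    "PhantomConfig",
    "Bundle",
    "PhantomPair",
    "build_model",
    "build_isolated_pair",
    "synthesize_fibre_densities",
    "add_density_noise",
    "synthesize_tractogram",
    "perturb_session_tractogram",
    "resample_polyline",
]

logger = logging.getLogger(__name__)

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for phantom synthesis.

    ``baseline_count`` scales every bundle's fibre count; ``noise_sigma`` is
    the relative fibre-density noise level (0.05 emulates an SNR of ~20);
    ``fp_fraction`` of 0.5 makes false positives around half the tractogram.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0
    bundle_radius: float = 1.5
    node_radius: float = 2.0
    baseline_count: int = 1000
    a_fibre: float = 1e-3  # per-fibre cross-sectional area constant, mm^2
    lesion_radius: float = 5.0
    direction_merge_deg: float = 30.0
    max_fixels_per_voxel: int = 3
    quadrature_points: int = 64
    resample_step: float = 1.0
    n_streamlines: int = 2000
    fp_fraction: float = 0.5
    jitter: float = 0.3
    noise_sigma: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class Bundle:
    """A white-matter bundle: straight tube with per-session fibre counts."""

    id: int
    centreline: np.ndarray  # (N, 3) world mm
    radius: float
    endpoints: tuple[int, int]  # node ids
    fibre_count: tuple[int, int]  # (TP1, TP2)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centreline, dtype=np.float64))
        if c.shape[0] < 2:
            raise ValueError("centreline needs >= 2 points")
        if float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1))) <= 0:
            raise ValueError("centreline arc length must be > 0")
        if self.radius <= 0:
            raise ValueError("bundle radius must be > 0")
        if any(n < 0 for n in self.fibre_count):
            raise ValueError("fibre counts must be >= 0")
        object.__setattr__(self, "centreline", c)
        object.__setattr__(self, "fibre_count", tuple(int(n) for n in self.fibre_count))

    @property
    def direction(self) -> np.ndarray:
        d = self.centreline[-1] - self.centreline[0]
        return d / np.linalg.norm(d)


@dataclass
class Crossing:
    """Closest approach between two bundle centrelines within their radii."""

    bundle_a: int
    bundle_b: int
    frac_a: float  # arc-length fraction of the crossing along bundle_a
    frac_b: float
    point: np.ndarray


@dataclass
class PhantomPair:
    """Ground-truth bundles, derived fixels, nodes, and optional lesion."""

    bundles: list[Bundle]
    fixels: FixelSet
    nodes: NodeSet
    config: PhantomConfig
    lesion: tuple[np.ndarray, float] | None = None
    rng_seed: int = 0
    crossings: list[Crossing] = field(default_factory=list)

    @property
    def grid(self) -> VoxelGrid:
        return self.fixels.grid

    def counts(self, session: int) -> np.ndarray:
        return np.array([b.fibre_count[session] for b in self.bundles], dtype=float)

    def bundle_edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(b.endpoints)) for b in self.bundles]

    def fc_connectome(self, session: int) -> Connectome:
        n = self.nodes.n_nodes
        m = np.zeros((n, n))
        for b in self.bundles:
            i, j = sorted(b.endpoints)
            m[i, j] += b.fibre_count[session]
            if i != j:
                m[j, i] += b.fibre_count[session]
        return Connectome(labels=self.nodes.labels, matrix=m, metric="FC")

    def delta_fc_connectome(self) -> Connectome:
        d = self.fc_connectome(1).matrix - self.fc_connectome(0).matrix
        return Connectome(labels=self.nodes.labels, matrix=d, metric="dFC")


# ---------------------------------------------------------------------------
# geometry helpers

def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Arc-length resampling at ~``step`` mm, keeping both endpoints."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(2, int(math.ceil(total / step)) + 1)
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for ax in range(3):
        out[:, ax] = np.interp(targets, arc, pts[:, ax])
    return out


def _perp_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``direction``."""
    u = direction / np.linalg.norm(direction)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(u)))] = 1.0
    n1 = np.cross(u, e)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(u, n1)
    return n1, n2


def _sunflower_disk(n: int, radius: float) -> np.ndarray:
    """Deterministic low-discrepancy sampling of a disk (sunflower layout)."""
    i = np.arange(n)
    r = radius * np.sqrt((i + 0.5) / n)
    th = i * _GOLDEN_ANGLE
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def _segment_point_distance(p0: np.ndarray, p1: np.ndarray, c: np.ndarray) -> float:
    d = p1 - p0
    t = float(np.clip(np.dot(c - p0, d) / max(np.dot(d, d), 1e-300), 0.0, 1.0))
    return float(np.linalg.norm(p0 + t * d - c))


def _centreline_intersects_sphere(centreline: np.ndarray, centre: np.ndarray,
                                  radius: float) -> bool:
    for k in range(len(centreline) - 1):
        if _segment_point_distance(centreline[k], centreline[k + 1], centre) <= radius:
            return True
    return False


def find_crossings(bundles: list[Bundle], step: float = 0.5) -> list[Crossing]:
    """Pairs of bundles whose centrelines approach within the sum of radii."""
    paths = [resample_polyline(b.centreline, step) for b in bundles]
    out: list[Crossing] = []
    for a in range(len(bundles)):
        for b in range(a + 1, len(bundles)):
            diff = paths[a][:, None, :] - paths[b][None, :, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            ia, ib = np.unravel_index(int(np.argmin(d2)), d2.shape)
            if math.sqrt(d2[ia, ib]) <= bundles[a].radius + bundles[b].radius:
                mid = 0.5 * (paths[a][ia] + paths[b][ib])
                out.append(Crossing(a, b, ia / (len(paths[a]) - 1),
                                    ib / (len(paths[b]) - 1), mid))
    return out


# ---------------------------------------------------------------------------
# fibre densities

def synthesize_fibre_densities(
    bundles: list[Bundle], grid: VoxelGrid, config: PhantomConfig
) -> FixelSet:
    """Derive per-session fixel fibre densities from bundle tube geometry.

    For each voxel a tube overlaps, the expected per-fibre length inside the
    voxel is estimated by a deterministic disk quadrature over radial
    offsets (the same uniform-disk distribution from which streamline
    offsets are later drawn); the fixel density is then
    ``fibre_count(session) * a_fibre * expected_length``.  Bundle
    contributions whose directions agree within ``direction_merge_deg``
    (axially) share one fixel; model weights are 1 inside the tissue mask.
    """
    per_voxel: dict[tuple[int, int, int], list[list]] = {}
    merge_cos = math.cos(math.radians(config.direction_merge_deg))
    offsets = _sunflower_disk(config.quadrature_points, 1.0)
    for b in bundles:
        path = resample_polyline(b.centreline, config.resample_step)
        n1, n2 = _perp_frame(b.direction)
        u = b.direction
        # accumulate per-voxel length and direction over the offset quadrature
        acc_len: dict[tuple[int, int, int], float] = {}
        acc_dir: dict[tuple[int, int, int], np.ndarray] = {}
        for ox, oy in offsets * b.radius:
            poly = path + ox * n1 + oy * n2
            for voxel, p0, p1, length in voxel_boundary_split(poly, grid):
                if not grid.contains_voxel(voxel):
                    continue
                t = p1 - p0
                if np.dot(t, u) < 0:
                    t = -t
                acc_len[voxel] = acc_len.get(voxel, 0.0) + length
                acc_dir[voxel] = acc_dir.get(voxel, np.zeros(3)) + t
        q = float(config.quadrature_points)
        for voxel, total in acc_len.items():
            lbar = total / q
            if lbar <= 1e-9:
                continue
            d = acc_dir[voxel]
            d = d / np.linalg.norm(d)
            contrib = [d, lbar, b]
            slots = per_voxel.setdefault(voxel, [])
            merged = False
            for slot in slots:
                if abs(np.dot(slot[0], d)) >= merge_cos:
                    # merge axially: weight directions by tube length
                    d_aligned = d if np.dot(slot[0], d) >= 0 else -d
                    w_old = sum(c[1] for c in slot[2])
                    new_dir = slot[0] * w_old + d_aligned * lbar
                    slot[0] = new_dir / np.linalg.norm(new_dir)
                    slot[2].append(contrib)
                    merged = True
                    break
            if not merged:
                slots.append([d, None, [contrib]])
    voxels, dirs, fds = [], [], []
    for voxel in sorted(per_voxel):
        slots = per_voxel[voxel]
        # enforce the per-voxel fixel budget: keep the densest directions,
        # merge the remainder into their nearest surviving fixel
        totals = [sum(c[1] for c in slot[2]) for slot in slots]
        order = sorted(range(len(slots)), key=lambda k: (-totals[k], k))
        kept = [slots[k] for k in order[: config.max_fixels_per_voxel]]
        for k in order[config.max_fixels_per_voxel:]:
            extra = slots[k]
            dots = [abs(np.dot(extra[0], s[0])) for s in kept]
            kept[int(np.argmax(dots))][2].extend(extra[2])
        for slot in kept:
            fd = np.zeros(2)
            for _d, lbar, b in slot[2]:
                for session in (0, 1):
                    fd[session] += b.fibre_count[session] * config.a_fibre * lbar
            voxels.append(voxel)
            dirs.append(slot[0])
            fds.append(fd)
    n = len(voxels)
    return FixelSet(
        grid=grid,
        voxels=np.array(voxels, dtype=np.int64).reshape(n, 3),
        directions=np.array(dirs).reshape(n, 3),
        weights=np.ones(n),
        fd=np.array(fds).reshape(n, 2),
        max_per_voxel=config.max_fixels_per_voxel,
    )


def add_density_noise(fixels: FixelSet, sigma: float, seed: int) -> FixelSet:
    """Gaussian density noise: fd <- max(0, fd + N(0, sigma * mean fd)).

    Noise is drawn independently per session; the standard deviation scales
    with that session's mean fibre density.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return fixels
    rng = np.random.default_rng(seed)
    fd = fixels.fd.copy()
    for session in range(fd.shape[1]):
        scale = sigma * float(np.mean(fd[:, session]))
        fd[:, session] = np.maximum(0.0, fd[:, session]
                                    + rng.normal(0.0, scale, size=fd.shape[0]))
    return fixels.with_fd(fd)


# ---------------------------------------------------------------------------
# model construction

def _node_set(bundles: list[Bundle], centres: list[np.ndarray],
              radius: float) -> NodeSet:
    labels = tuple(f"node{i:02d}" for i in range(len(centres)))
    return NodeSet(centres=np.array(centres), radii=np.full(len(centres), radius),
                   labels=labels)


def _make_bundles(segments: list[tuple[np.ndarray, np.ndarray]],
                  counts: list[tuple[int, int]], radius: float) -> tuple[list[Bundle], list[np.ndarray]]:
    bundles = []
    centres: list[np.ndarray] = []
    for k, ((p0, p1), fc) in enumerate(zip(segments, counts)):
        na, nb = 2 * k, 2 * k + 1
        bundles.append(Bundle(id=k, centreline=np.array([p0, p1]), radius=radius,
                              endpoints=(na, nb), fibre_count=fc))
        centres.extend([np.asarray(p0, float), np.asarray(p1, float)])
    return bundles, centres


def build_model(model_id: int, config: PhantomConfig | None = None) -> PhantomPair:
    """Construct longitudinal phantom model 1, 2 or 3.

    Model 1: one isolated bundle drops to 25% of its TP1 fibre count, with
    unchanged distractors.  Model 2: two crossing bundles change by -50% and
    +100%.  Model 3: a central spherical lesion; every bundle whose
    centreline intersects it has a TP2 count of zero.
    """
    if config is None:
        config = PhantomConfig()
    s = float(config.grid_shape[0]) * config.voxel_size
    lo, hi = 3.0, s - 4.0
    q, h, t = s / 4.0, s / 2.0, 3.0 * s / 4.0
    base = config.baseline_count
    r = config.bundle_radius
    lesion = None

    def pt(x, y, z):
        return np.array([x, y, z], dtype=float)

    if model_id == 1:
        segments = [
            (pt(lo, t, t), pt(hi, t, t)),      # manipulated, isolated
            (pt(lo, q, q), pt(hi, q, q)),      # distractor
            (pt(h, lo, q), pt(h, hi, q)),      # distractor, crosses previous
            (pt(q, t - 4, lo), pt(q, t - 4, hi)),
        ]
        counts = [
            (base, base // 4),
            (int(0.8 * base), int(0.8 * base)),
            (int(0.8 * base), int(0.8 * base)),
            (int(0.6 * base), int(0.6 * base)),
        ]
    elif model_id == 2:
        segments = [
            (pt(lo, h, h), pt(hi, h, h)),      # -50%
            (pt(h, lo, h), pt(h, hi, h)),      # +100%, crosses the first
            (pt(lo, q, q - 2), pt(hi, q, q - 2)),
            (pt(t, t, lo), pt(t, t, hi)),
            (pt(q, lo, t + 2), pt(q, hi, t + 2)),
        ]
        counts = [
            (int(0.8 * base), int(0.4 * base)),
            (int(0.4 * base), int(0.8 * base)),
            (int(0.6 * base), int(0.6 * base)),
            (int(0.6 * base), int(0.6 * base)),
            (int(0.5 * base), int(0.5 * base)),
        ]
    elif model_id == 3:
        centre = np.full(3, (s - config.voxel_size) / 2.0)
        lesion = (centre, config.lesion_radius)
        segments = [
            (pt(lo, h, h), pt(hi, h, h)),          # through the lesion
            (pt(h, lo, h - 1), pt(h, hi, h - 1)),  # through the lesion
            (pt(h - 1, h, lo), pt(h - 1, h, hi)),  # through the lesion
            (pt(lo, 5, 5), pt(hi, 5, 5)),
            (pt(t, lo, 6), pt(t, hi, 6)),
            (pt(6, t + 2, lo), pt(6, t + 2, hi)),
        ]
        base_counts = [int(0.9 * base), int(0.7 * base), int(0.5 * base),
                       int(0.8 * base), int(0.6 * base), int(0.5 * base)]
        counts = []
        for (p0, p1), c in zip(segments, base_counts):
            hit = _centreline_intersects_sphere(np.array([p0, p1]), centre,
                                                config.lesion_radius)
            counts.append((c, 0 if hit else c))
    else:
        raise ValueError(f"unknown phantom model id {model_id!r}")

    bundles, centres = _make_bundles(segments, counts, r)
    grid = VoxelGrid(shape=config.grid_shape,
                     voxel_size=(config.voxel_size,) * 3)
    fixels = synthesize_fibre_densities(bundles, grid, config)
    nodes = _node_set(bundles, centres, config.node_radius)
    pair = PhantomPair(bundles=bundles, fixels=fixels, nodes=nodes,
                       config=config, lesion=lesion, rng_seed=config.seed,
                       crossings=find_crossings(bundles))
    logger.info("phantom model %d: %d bundles, %d fixels, %d crossings, seed=%d",
                model_id, len(bundles), fixels.n_fixels, len(pair.crossings),
                config.seed)
    return pair


def build_isolated_pair(
    fc_tp1: int,
    fc_tp2: int,
    config: PhantomConfig | None = None,
) -> PhantomPair:
    """A single isolated bundle with arbitrary per-session fibre counts.

    Used for analytic checks, e.g. full removal (fc_tp2 = 0) drives the
    differential delta coefficients to -1.
    """
    if config is None:
        config = PhantomConfig()
    s = float(config.grid_shape[0]) * config.voxel_size
    h = s / 2.0
    p0 = np.array([3.0, h, h])
    p1 = np.array([s - 4.0, h, h])
    bundles, centres = _make_bundles([(p0, p1)], [(fc_tp1, fc_tp2)],
                                     config.bundle_radius)
    grid = VoxelGrid(shape=config.grid_shape, voxel_size=(config.voxel_size,) * 3)
    fixels = synthesize_fibre_densities(bundles, grid, config)
    nodes = _node_set(bundles, centres, config.node_radius)
    return PhantomPair(bundles=bundles, fixels=fixels, nodes=nodes,
                       config=config, rng_seed=config.seed,
                       crossings=find_crossings(bundles))


# ---------------------------------------------------------------------------
# tractogram synthesis

def _allocate(n: int, counts: np.ndarray) -> np.ndarray:
    """Largest-remainder proportional allocation with a minimum of one."""
    counts = np.asarray(counts, dtype=float)
    k = len(counts)
    if n < k:
        raise ValueError(f"cannot allocate {n} streamlines over {k} bundles "
                         "with a minimum of one each")
    total = counts.sum()
    if total <= 0:
        share = np.full(k, n / k)
    else:
        share = n * counts / total
    alloc = np.floor(share).astype(np.int64)
    rem = n - int(alloc.sum())
    frac = share - np.floor(share)
    for idx in np.argsort(-frac, kind="stable")[:rem]:
        alloc[idx] += 1
    # enforce the minimum of one, taking from the largest allocations
    while np.any(alloc < 1):
        alloc[int(np.argmin(alloc))] += 1
        alloc[int(np.argmax(alloc))] -= 1
    return alloc


def _offset_path(path: np.ndarray, direction: np.ndarray, offset2d: np.ndarray,
                 jitter: float, rng: np.random.Generator) -> np.ndarray:
    n1, n2 = _perp_frame(direction)
    out = path + offset2d[0] * n1 + offset2d[1] * n2
    if jitter > 0 and len(out) > 2:
        out = out.copy()
        out[1:-1] += rng.normal(0.0, jitter, size=(len(out) - 2, 3))
    return out


def synthesize_tractogram(
    pair: PhantomPair,
    n_streamlines: int | None = None,
    fp_fraction: float | None = None,
    jitter: float | None = None,
    seed: int | None = None,
    counts: np.ndarray | None = None,
) -> Tractogram:
    """Draw a synthetic tractogram from the phantom geometry.

    True positives follow one bundle end-to-end with a constant radial
    offset drawn uniformly over the tube cross-section plus Gaussian
    waypoint jitter; they are allocated to bundles proportionally to
    ``counts`` (default: TP1 fibre counts), minimum one per bundle.  False
    positives follow one bundle to a crossing and switch to another, so
    their endpoints span a spurious node pair.
    """
    cfg = pair.config
    if n_streamlines is None:
        n_streamlines = cfg.n_streamlines
    if fp_fraction is None:
        fp_fraction = cfg.fp_fraction
    if jitter is None:
        jitter = cfg.jitter
    if seed is None:
        seed = cfg.seed
    if n_streamlines < 1:
        raise ValueError("need at least one streamline")
    if not 0.0 <= fp_fraction < 1.0:
        raise ValueError("fp_fraction must be in [0, 1)")
    if counts is None:
        counts = pair.counts(0)
    rng = np.random.default_rng(seed)
    n_fp = int(round(n_streamlines * fp_fraction))
    if n_fp > 0 and not pair.crossings:
        raise ValueError("false positives requested but the phantom has no "
                         "bundle crossings")
    n_tp = n_streamlines - n_fp
    alloc = _allocate(n_tp, np.asarray(counts, dtype=float))

    paths = [resample_polyline(b.centreline, cfg.resample_step)
             for b in pair.bundles]
    streamlines: list[np.ndarray] = []
    bundle_ids: list[int] = []
    fp_pairs: dict[int, tuple[int, int]] = {}
    for b, n_b in zip(pair.bundles, alloc):
        for _ in range(int(n_b)):
            rr = b.radius * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            off = np.array([rr * math.cos(th), rr * math.sin(th)])
            streamlines.append(_offset_path(paths[b.id], b.direction, off,
                                            jitter, rng))
            bundle_ids.append(b.id)
    for _ in range(n_fp):
        c = pair.crossings[int(rng.integers(len(pair.crossings)))]
        a, b = pair.bundles[c.bundle_a], pair.bundles[c.bundle_b]
        ia = int(round(c.frac_a * (len(paths[c.bundle_a]) - 1)))
        ib = int(round(c.frac_b * (len(paths[c.bundle_b]) - 1)))
        arm1 = paths[c.bundle_a][: ia + 1]
        if rng.uniform() < 0.5:
            arm1 = paths[c.bundle_a][ia:][::-1]
        arm2 = paths[c.bundle_b][ib:]
        if rng.uniform() < 0.5:
            arm2 = paths[c.bundle_b][: ib + 1][::-1]
        pieces = []
        for arm, bb in ((arm1, a), (arm2, b)):
            if len(arm) < 2:
                arm = np.vstack([arm, arm[-1] + 1e-3 * bb.direction])
            rr = bb.radius * math.sqrt(rng.uniform())
            th = rng.uniform(0.0, 2.0 * math.pi)
            off = np.array([rr * math.cos(th), rr * math.sin(th)])
            pieces.append(_offset_path(arm, bb.direction, off, jitter, rng))
        sl = np.vstack([pieces[0], pieces[1]])
        streamlines.append(sl)
        bundle_ids.append(-1)
        fp_pairs[len(streamlines) - 1] = (c.bundle_a, c.bundle_b)
    logger.info("synthesized tractogram: %d streamlines (%d true, %d false "
                "positive), jitter=%.2f, seed=%d", n_streamlines, n_tp, n_fp,
                jitter, seed)
    return Tractogram(streamlines=streamlines,
                      bundle_ids=np.array(bundle_ids, dtype=np.int64),
                      fp_pairs=fp_pairs)


def perturb_session_tractogram(
    pair: PhantomPair,
    session: int,
    seed: int,
    n_streamlines: int | None = None,
    fp_fraction: float | None = None,
    jitter: float | None = None,
) -> Tractogram:
    """Session-specific tractogram draw (emulating cross-sectional tracking).

    The per-bundle allocation follows that session's fibre counts and the
    false-positive realisation is specific to ``seed``; two sessions drawn
    with different seeds share no streamline objects.
    """
    return synthesize_tractogram(
        pair,
        n_streamlines=n_streamlines,
        fp_fraction=fp_fraction,
        jitter=jitter,
        seed=seed,
        counts=pair.counts(session),
    )
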