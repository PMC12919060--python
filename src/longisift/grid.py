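"""Voxel/fixel geometry and streamline traversal.

A *fixel* is a single fibre population within a voxel, characterised by an
(axial) direction, a model weight ``w_f`` and one fibre-density value per
imaging session.  The central object produced here is the sparse
streamline-by-fixel matrix of intersection lengths ``|s ∩ f|``, which links
the tractogram to the fixel-wise fibre densities in every cost function of
the package.

Coordinate convention: voxel centres sit at ``origin + index * voxel_size``;
voxels are half-open boxes whose faces belong to the voxel with the higher
index.  Streamlines are split *exactly* at voxel faces (no resampling), so
intersection lengths are free of any step-size parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

__all__ = [
    "VoxelGrid",
    "Fixel",
    "FixelSet",
    "TraversalMatrix",
    "Tractogram",
    "voxel_boundary_split",
    "assign_segment_to_fixel",
    "compute_traversal",
    "DEFAULT_ANGLE_THRESHOLD_DEG",
]

logger = logging.getLogger(__name__)

#: Angular acceptance threshold for attributing a segment to a fixel.
#: Fixels are axial (antipodally symmetric), so the test uses |dot|.
DEFAULT_ANGLE_THRESHOLD_DEG = 45.0


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in world (mm) coordinates."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def world_to_frac(self, points: np.ndarray) -> np.ndarray:
        """Map world mm to continuous voxel coordinates where voxel ``i``
        occupies the half-open interval ``[i, i+1)`` per axis."""
        p = np.asarray(points, dtype=np.float64)
        return (p - np.asarray(self.origin)) / np.asarray(self.voxel_size) + 0.5

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int]:
        f = np.floor(self.world_to_frac(point)).astype(np.int64)
        return (int(f[0]), int(f[1]), int(f[2]))

    def contains_voxel(self, voxel) -> bool:
        return all(0 <= int(v) < n for v, n in zip(voxel, self.shape))

    def linear_index(self, voxel) -> int:
        i, j, k = (int(v) for v in voxel)
        return (i * self.shape[1] + j) * self.shape[2] + k


@dataclass(frozen=True)
class Fixel:
    """A single fibre population (directional element) within a voxel."""

    voxel: tuple[int, int, int]
    direction: np.ndarray  # unit 3-vector, axial (d and -d equivalent)
    weight: float = 1.0  # model weight w_f
    fd: np.ndarray = field(default_factory=lambda: np.zeros(0))  # per session

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=np.float64)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(f"fixel direction must be unit-norm, got |d|={np.linalg.norm(d)}")
        if self.weight < 0:
            raise ValueError("fixel weight must be >= 0")
        fd = np.atleast_1d(np.asarray(self.fd, dtype=np.float64))
        if np.any(fd < 0):
            raise ValueError("fibre densities must be >= 0")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "fd", fd)
        object.__setattr__(self, "voxel", tuple(int(v) for v in self.voxel))


class FixelSet:
    """A collection of fixels on a voxel grid, at most ``max_per_voxel`` each.

    Array attributes (all length ``n_fixels``):

    - ``voxels``     (F, 3) integer voxel indices
    - ``directions`` (F, 3) unit direction vectors
    - ``weights``    (F,)   model weights w_f
    - ``fd``         (F, n_sessions) per-session fibre density
    """

    def __init__(
        self,
        grid: VoxelGrid,
        voxels: np.ndarray,
        directions: np.ndarray,
        weights: np.ndarray,
        fd: np.ndarray,
        max_per_voxel: int = 3,
    ) -> None:
        self.grid = grid
        self.voxels = np.atleast_2d(np.asarray(voxels, dtype=np.int64))
        self.directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
        self.weights = np.atleast_1d(np.asarray(weights, dtype=np.float64))
        fd = np.asarray(fd, dtype=np.float64)
        if fd.ndim == 1:
            fd = fd[:, None]
        self.fd = fd
        self.max_per_voxel = int(max_per_voxel)
        self._validate()
        self._voxel_ptr: np.ndarray | None = None
        self._voxel_fixels: np.ndarray | None = None

    def _validate(self) -> None:
        n = len(self.weights)
        if self.voxels.shape != (n, 3) or self.directions.shape != (n, 3):
            raise ValueError("inconsistent fixel array shapes")
        if self.fd.shape[0] != n:
            raise ValueError("fd rows must match number of fixels")
        norms = np.linalg.norm(self.directions, axis=1)
        if n and np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError("fixel directions must be unit-norm")
        if np.any(self.weights < 0):
            raise ValueError("fixel weights must be >= 0")
        for ax in range(3):
            bad = (self.voxels[:, ax] < 0) | (self.voxels[:, ax] >= self.grid.shape[ax])
            if np.any(bad):
                raise ValueError("fixel voxel index outside grid")
        if n:
            lin = self._linear_voxels()
            counts = np.bincount(lin, minlength=self.grid.n_voxels)
            if counts.max() > self.max_per_voxel:
                raise ValueError(
                    f"more than {self.max_per_voxel} fixels in a voxel "
                    f"(max found {counts.max()})"
                )

    def _linear_voxels(self) -> np.ndarray:
        s = self.grid.shape
        return (self.voxels[:, 0] * s[1] + self.voxels[:, 1]) * s[2] + self.voxels[:, 2]

    @property
    def n_fixels(self) -> int:
        return len(self.weights)

    @property
    def n_sessions(self) -> int:
        return self.fd.shape[1]

    def voxel_lookup(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style map linear voxel index -> fixel ids (sorted ascending)."""
        if self._voxel_ptr is None:
            lin = self._linear_voxels()
            order = np.lexsort((np.arange(self.n_fixels), lin))
            sorted_lin = lin[order]
            ptr = np.zeros(self.grid.n_voxels + 1, dtype=np.int64)
            np.add.at(ptr, sorted_lin + 1, 1)
            np.cumsum(ptr, out=ptr)
            self._voxel_ptr = ptr
            self._voxel_fixels = order.astype(np.int64)
        return self._voxel_ptr, self._voxel_fixels

    def fixels_in_voxel(self, voxel) -> np.ndarray:
        if not self.grid.contains_voxel(voxel):
            return np.zeros(0, dtype=np.int64)
        ptr, ids = self.voxel_lookup()
        lin = self.grid.linear_index(voxel)
        return ids[ptr[lin] : ptr[lin + 1]]

    def fd_session(self, session: int) -> np.ndarray:
        return self.fd[:, session]

    def with_fd(self, fd: np.ndarray) -> "FixelSet":
        """Copy of this fixel set with replaced fibre-density table."""
        return FixelSet(self.grid, self.voxels, self.directions, self.weights,
                        fd, self.max_per_voxel)


@dataclass
class Tractogram:
    """Ordered streamlines (world-mm polylines) with optional provenance.

    ``bundle_ids[s]`` is the generating bundle of streamline ``s`` in
    synthetic data (-1 for false positives); ``fp_pairs`` records, for false
    positives, the two bundles the trajectory partially follows.
    """

    streamlines: list[np.ndarray]
    bundle_ids: np.ndarray | None = None
    fp_pairs: dict[int, tuple[int, int]] | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def arc_lengths(self) -> np.ndarray:
        out = np.empty(len(self.streamlines))
        for i, pts in enumerate(self.streamlines):
            out[i] = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        return out

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        starts = np.array([s[0] for s in self.streamlines])
        ends = np.array([s[-1] for s in self.streamlines])
        return starts, ends


class TraversalMatrix:
    """Sparse streamline x fixel matrix of intersection lengths (mm).

    ``dropped_length[s]`` accumulates portions of streamline ``s`` that fell
    outside the grid or matched no fixel within the angular threshold, so
    that per streamline ``row_sum + dropped == arc length``.
    """

    def __init__(self, matrix: sparse.csr_matrix, dropped_length: np.ndarray,
                 n_dropped_segments: int = 0) -> None:
        self.matrix = matrix.tocsr()
        self.dropped_length = np.asarray(dropped_length, dtype=np.float64)
        self.n_dropped_segments = int(n_dropped_segments)
        if self.matrix.nnz and self.matrix.data.min() <= 0:
            raise ValueError("traversal lengths must be > 0")

    @property
    def n_streamlines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_fixels(self) -> int:
        return self.matrix.shape[1]

    def streamline_lengths(self) -> np.ndarray:
        """Total in-model traversal length per streamline (mm)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()


def voxel_boundary_split(
    points: np.ndarray, grid: VoxelGrid
) -> list[tuple[tuple[int, int, int], np.ndarray, np.ndarray, float]]:
    """Split a polyline exactly at voxel faces.

    Returns a list of ``(voxel, start_mm, end_mm, length_mm)`` with
    degenerate (zero-length) pieces discarded.  Faces belong to the voxel
    with the higher index.  Sub-segment lengths sum to the polyline length.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline must be an (N, 3) array with N >= 2")
    frac = grid.world_to_frac(pts)
    parts: list[tuple[tuple[int, int, int], np.ndarray, np.ndarray, float]] = []
    for i in range(len(pts) - 1):
        a, b = frac[i], frac[i + 1]
        seg_len = float(np.linalg.norm(pts[i + 1] - pts[i]))
        if seg_len <= 0.0:
            continue
        ts = [0.0, 1.0]
        for ax in range(3):
            lo, hi = sorted((a[ax], b[ax]))
            first = math.floor(lo) + 1
            last = math.ceil(hi) - 1
            for n in range(first, last + 1):
                if hi > lo:
                    t = (n - a[ax]) / (b[ax] - a[ax])
                    if 0.0 < t < 1.0:
                        ts.append(t)
        ts = sorted(set(ts))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            piece = (t1 - t0) * seg_len
            if piece <= 1e-12:
                continue
            mid = a + 0.5 * (t0 + t1) * (b - a)
            voxel = tuple(int(v) for v in np.floor(mid))
            p0 = pts[i] + t0 * (pts[i + 1] - pts[i])
            p1 = pts[i] + t1 * (pts[i + 1] - pts[i])
            parts.append((voxel, p0, p1, piece))
    return parts


def assign_segment_to_fixel(
    seg_start: np.ndarray,
    seg_end: np.ndarray,
    candidate_directions: np.ndarray,
    candidate_ids: np.ndarray | None = None,
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
) -> int | None:
    """Attribute a within-voxel segment to the best-aligned candidate fixel.

    Alignment is axial (|dot|); returns None if there is no candidate or the
    best |dot| falls below cos(threshold).  Ties break toward the lowest
    fixel id (candidates are scanned in id order).
    """
    d = np.asarray(seg_end, dtype=np.float64) - np.asarray(seg_start, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm <= 0:
        raise ValueError("zero-length segment cannot be assigned to a fixel")
    d /= norm
    dirs = np.atleast_2d(np.asarray(candidate_directions, dtype=np.float64))
    if dirs.shape[0] == 0:
        return None
    if candidate_ids is None:
        candidate_ids = np.arange(dirs.shape[0])
    order = np.argsort(candidate_ids, kind="stable")
    dots = np.abs(dirs[order] @ d)
    best = int(np.argmax(dots))
    if dots[best] < math.cos(math.radians(angle_threshold_deg)):
        return None
    return int(np.asarray(candidate_ids)[order][best])


@njit(cache=False)
def _traverse_kernel(frac, vsize, shape0, shape1, shape2,
                     voxel_ptr, voxel_fixels, fixel_dirs, cos_thresh,
                     out_fixel, out_len):  # pragma: no cover - compiled
    """Split one streamline (in fractional voxel coords) at voxel faces and
    attribute each piece.  Returns (n_entries, dropped_length, n_dropped)."""
    n_out = 0
    dropped = 0.0
    n_dropped = 0
    npts = frac.shape[0]
    for i in range(npts - 1):
        ax_ = frac[i]
        bx_ = frac[i + 1]
        # world-mm length of this polyline segment
        dx = (bx_[0] - ax_[0]) * vsize[0]
        dy = (bx_[1] - ax_[1]) * vsize[1]
        dz = (bx_[2] - ax_[2]) * vsize[2]
        seg_len = math.sqrt(dx * dx + dy * dy + dz * dz)
        if seg_len <= 0.0:
            continue
        # collect parametric crossings of integer planes
        ts = np.empty(2 + 3 * 64, dtype=np.float64)
        nts = 0
        ts[nts] = 0.0
        nts += 1
        ts[nts] = 1.0
        nts += 1
        for ax in range(3):
            a = ax_[ax]
            b = bx_[ax]
            lo = a if a < b else b
            hi = b if a < b else a
            first = int(math.floor(lo)) + 1
            last = int(math.ceil(hi)) - 1
            n = first
            while n <= last:
                if hi > lo:
                    t = (n - a) / (b - a)
                    if 0.0 < t < 1.0:
                        if nts < ts.shape[0]:
                            ts[nts] = t
                            nts += 1
                n += 1
        tarr = np.sort(ts[:nts])
        # unit direction of the segment in world coords
        ux = dx / seg_len
        uy = dy / seg_len
        uz = dz / seg_len
        for j in range(nts - 1):
            t0 = tarr[j]
            t1 = tarr[j + 1]
            piece = (t1 - t0) * seg_len
            if piece <= 1e-12:
                continue
            tm = 0.5 * (t0 + t1)
            vi = int(math.floor(ax_[0] + tm * (bx_[0] - ax_[0])))
            vj = int(math.floor(ax_[1] + tm * (bx_[1] - ax_[1])))
            vk = int(math.floor(ax_[2] + tm * (bx_[2] - ax_[2])))
            if vi < 0 or vi >= shape0 or vj < 0 or vj >= shape1 or vk < 0 or vk >= shape2:
                dropped += piece
                n_dropped += 1
                continue
            lin = (vi * shape1 + vj) * shape2 + vk
            best_f = -1
            best_dot = -1.0
            for q in range(voxel_ptr[lin], voxel_ptr[lin + 1]):
                f = voxel_fixels[q]
                dot = abs(fixel_dirs[f, 0] * ux + fixel_dirs[f, 1] * uy
                          + fixel_dirs[f, 2] * uz)
                if dot > best_dot:
                    best_dot = dot
                    best_f = f
            if best_f < 0 or best_dot < cos_thresh:
                dropped += piece
                n_dropped += 1
                continue
            out_fixel[n_out] = best_f
            out_len[n_out] = piece
            n_out += 1
    return n_out, dropped, n_dropped


def compute_traversal(
    tractogram: Tractogram,
    fixels: FixelSet,
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
) -> TraversalMatrix:
    """Build the sparse intersection-length matrix |s ∩ f|.

    Each streamline is split exactly at voxel faces; each piece is attributed
    to the best axially aligned fixel of its voxel (|dot| >= cos threshold).
    Pieces outside the grid or without an acceptable fixel are dropped and
    tallied in ``dropped_length``.
    """
    grid = fixels.grid
    voxel_ptr, voxel_fixels = fixels.voxel_lookup()
    cos_thresh = math.cos(math.radians(angle_threshold_deg))
    vsize = np.asarray(grid.voxel_size, dtype=np.float64)
    n_s = len(tractogram)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    dropped_length = np.zeros(n_s)
    n_dropped_total = 0
    # generous per-streamline buffer: every segment can cross at most
    # ~3*span voxel faces; resized if a streamline is unusually long
    for s, pts in enumerate(tractogram.streamlines):
        pts = np.ascontiguousarray(pts, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise ValueError(f"streamline {s} must have >= 2 points")
        frac = grid.world_to_frac(pts)
        cap = 8 * (pts.shape[0] + int(np.sum(np.abs(np.diff(frac, axis=0)))) + 4)
        out_fixel = np.empty(cap, dtype=np.int64)
        out_len = np.empty(cap, dtype=np.float64)
        n_out, dropped, n_drop = _traverse_kernel(
            frac, vsize, grid.shape[0], grid.shape[1], grid.shape[2],
            voxel_ptr, voxel_fixels, fixels.directions, cos_thresh,
            out_fixel, out_len)
        dropped_length[s] = dropped
        n_dropped_total += n_drop
        if n_out:
            rows.append(np.full(n_out, s, dtype=np.int64))
            cols.append(out_fixel[:n_out].copy())
            vals.append(out_len[:n_out].copy())
    if n_dropped_total:
        logger.info("traversal: %d sub-segments dropped (outside grid or "
                    "no fixel within angular threshold)", n_dropped_total)
    if rows:
        coo = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_s, fixels.n_fixels),
        )
    else:
        coo = sparse.coo_matrix((n_s, fixels.n_fixels))
    csr = coo.tocsr()
    csr.sum_duplicates()
    return TraversalMatrix(csr, dropped_length, n_dropped_total)
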