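"""Endpoint-to-node assignment, connectome matrices and bundle-wise errors.

Nodes are grey-matter parcels; in the synthetic phantoms each node is a
sphere around a bundle endpoint.  A streamline belongs to edge (i, j) when
its two endpoints map to nodes i and j (containment first, then nearest
node centre within a fallback radius).  Connectivity metrics:

* NoS  — number of streamlines per edge;
* FBC  — Fibre Bundle Capacity, mu * sum of member streamline weights;
* dFBC — longitudinal FBC change (sign-unrestricted).

Estimated changes are compared against ground-truth fibre counts after a
global scaling phi = sum SC / sum FC over the upper triangle (including the
diagonal) of the first-session matrices; the bundle-wise longitudinal error
is eps_diff_ij = |dSC_ij / phi - dFC_ij|.  Dividing by phi brings the
structural-connectivity totals onto the fibre-count scale, so that a
perfect reconstruction yields zero error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .absolute import WeightedTractogram
from .grid import Tractogram

__all__ = [
    "NodeSet",
    "Connectome",
    "StreamlineAssignment",
    "assign_streamlines",
    "nos_connectome",
    "fbc_connectome",
    "scale_to_fibre_count",
    "bundle_error_diff",
    "bundle_error_abs",
    "DEFAULT_ASSIGNMENT_RADIUS_MM",
]

DEFAULT_ASSIGNMENT_RADIUS_MM = 4.0


@dataclass(frozen=True)
class NodeSet:
    """Spherical parcel regions: centres (N, 3) mm, radii (N,), labels."""

    centres: np.ndarray
    radii: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        centres = np.atleast_2d(np.asarray(self.centres, dtype=np.float64))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=np.float64))
        if centres.shape[0] != radii.shape[0] or centres.shape[1] != 3:
            raise ValueError("node centres/radii shape mismatch")
        if len(self.labels) != centres.shape[0]:
            raise ValueError("node labels length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        # regions must not overlap
        n = centres.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(centres[i] - centres[j]) < radii[i] + radii[j]:
                    raise ValueError(f"node regions {i} and {j} overlap")
        object.__setattr__(self, "centres", centres)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n_nodes(self) -> int:
        return self.centres.shape[0]


@dataclass
class Connectome:
    """Symmetric node x node matrix with a metric tag."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    metric: str  # NoS | FBC | dFBC | FC | dFC

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("connectome matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("connectome matrix must be symmetric")
        if self.metric in ("NoS", "FBC", "FC") and m.size and m.min() < 0:
            raise ValueError(f"{self.metric} entries must be >= 0")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def grand_sum(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float(np.sum(np.triu(self.matrix)))


@dataclass
class StreamlineAssignment:
    """Per-streamline node pair; (-1, -1) marks unassigned streamlines."""

    edges: np.ndarray  # (S, 2) int, sorted so edges[:, 0] <= edges[:, 1]
    n_nodes: int

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.edges[:, 0] >= 0))

    @property
    def n_unassigned(self) -> int:
        return len(self.edges) - self.n_assigned

    def edge_members(self, i: int, j: int) -> np.ndarray:
        i, j = min(i, j), max(i, j)
        return np.nonzero((self.edges[:, 0] == i) & (self.edges[:, 1] == j))[0]


def _assign_endpoint(point: np.ndarray, nodes: NodeSet, radius_mm: float) -> int:
    d = np.linalg.norm(nodes.centres - point, axis=1)
    inside = np.nonzero(d <= nodes.radii)[0]
    if inside.size:
        return int(inside[np.argmin(d[inside])])
    best = int(np.argmin(d))
    if d[best] <= radius_mm:
        return best
    return -1


def assign_streamlines(
    tractogram: Tractogram,
    nodes: NodeSet,
    radius_mm: float = DEFAULT_ASSIGNMENT_RADIUS_MM,
) -> StreamlineAssignment:
    """Map each streamline to a node pair via its two endpoints.

    An endpoint inside a node sphere maps to that node; otherwise to the
    nearest node centre within ``radius_mm``; otherwise the streamline is
    unassigned and contributes to no edge.  Both endpoints in the same node
    form a diagonal (self-loop) entry.
    """
    if nodes.n_nodes == 0:
        raise ValueError("empty node set")
    if radius_mm <= 0:
        raise ValueError("assignment radius must be > 0")
    starts, ends = tractogram.endpoints()
    edges = np.full((len(tractogram), 2), -1, dtype=np.int64)
    for s in range(len(tractogram)):
        a = _assign_endpoint(starts[s], nodes, radius_mm)
        b = _assign_endpoint(ends[s], nodes, radius_mm)
        if a >= 0 and b >= 0:
            edges[s] = (min(a, b), max(a, b))
    return StreamlineAssignment(edges=edges, n_nodes=nodes.n_nodes)


def _symmetric_from_upper(upper: np.ndarray) -> np.ndarray:
    return upper + np.triu(upper, 1).T


def nos_connectome(assignment: StreamlineAssignment,
                   labels: tuple[str, ...] | None = None) -> Connectome:
    """Number-of-streamlines connectome (integer counts per edge)."""
    n = assignment.n_nodes
    upper = np.zeros((n, n))
    keep = assignment.edges[:, 0] >= 0
    np.add.at(upper, (assignment.edges[keep, 0], assignment.edges[keep, 1]), 1.0)
    if labels is None:
        labels = tuple(f"node{i:02d}" for i in range(n))
    return Connectome(labels=labels, matrix=_symmetric_from_upper(upper), metric="NoS")


def fbc_connectome(assignment: StreamlineAssignment,
                   weighted: WeightedTractogram,
                   labels: tuple[str, ...] | None = None) -> Connectome:
    """Fibre Bundle Capacity connectome: FBC_ij = mu * sum_{s in ij} e^{F_s}."""
    n = assignment.n_nodes
    upper = np.zeros((n, n))
    keep = assignment.edges[:, 0] >= 0
    np.add.at(upper, (assignment.edges[keep, 0], assignment.edges[keep, 1]),
              weighted.mu * np.exp(weighted.F[keep]))
    if labels is None:
        labels = tuple(f"node{i:02d}" for i in range(n))
    return Connectome(labels=labels, matrix=_symmetric_from_upper(upper), metric="FBC")


def scale_to_fibre_count(sc_tp1: Connectome, fc_tp1: Connectome) -> float:
    """Global scaling factor phi = sum SC_tp1 / sum FC_tp1 (upper triangle
    including the diagonal).  Estimated changes are divided by phi so that
    scaled structural-connectivity totals land on the fibre-count scale."""
    if sc_tp1.labels != fc_tp1.labels:
        raise ValueError("connectomes use different node sets")
    denom = fc_tp1.grand_sum()
    if denom <= 0:
        raise ValueError("ground-truth fibre-count total must be > 0")
    return sc_tp1.grand_sum() / denom


def _check_aligned(a: Connectome, b: Connectome) -> None:
    if a.labels != b.labels:
        raise ValueError("connectomes use different node sets")


def bundle_error_diff(
    delta_sc: Connectome,
    delta_fc: Connectome,
    phi: float,
    bundle_edges: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-bundle longitudinal error eps_diff = |dSC / phi - dFC|.

    Returned only for ground-truth bundle edges when ``bundle_edges`` is
    given, else as a full matrix.
    """
    _check_aligned(delta_sc, delta_fc)
    if phi <= 0:
        raise ValueError("phi must be > 0")
    err = np.abs(delta_sc.matrix / phi - delta_fc.matrix)
    if bundle_edges is None:
        return err
    return np.array([err[i, j] for i, j in bundle_edges])


def bundle_error_abs(
    sc: Connectome,
    fc: Connectome,
    phi: float,
    bundle_edges: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Per-bundle cross-sectional error eps_abs = |SC / phi - FC|."""
    _check_aligned(sc, fc)
    if phi <= 0:
        raise ValueError("phi must be > 0")
    err = np.abs(sc.matrix / phi - fc.matrix)
    if bundle_edges is None:
        return err
    return np.array([err[i, j] for i, j in bundle_edges])
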