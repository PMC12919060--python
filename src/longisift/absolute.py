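"""SIFT2-style absolute streamline-weight optimisation.

Each streamline ``s`` carries a cross-sectional weight ``e^{F_s}``; the
fixel-wise weighted tract density

    TD_f = sum_s |s ∩ f| * e^{F_s}

is matched to the measured fibre density ``FD_f`` in least squares, with a
global proportionality coefficient

    mu = sum_f w_f FD_f / sum_f w_f TD_f

computed once at initialisation and then held fixed.  The optimised
objective is

    sum_f w_f (mu * TD_f - FD_f)^2  +  A * lambda * sum_s l_s (F_s - ref_s)^2

where ``l_s`` is the streamline's total in-model traversal length.  The
regulariser is quadratic in the exponential coefficient (fold-changes are
penalised symmetrically) and length-weighted so each streamline's penalty
scales with its leverage on the data term; ``A`` normalises the penalty to
the magnitude of the data term across grid sizes and streamline counts.

Fibre Bundle Capacity of a node pair (i, j) is ``mu * sum_{s in ij} e^{F_s}``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .grid import FixelSet, TraversalMatrix

__all__ = [
    "RegularisationSpec",
    "WeightedTractogram",
    "compute_scale_A",
    "compute_tract_density",
    "compute_mu",
    "absolute_cost",
    "optimize_absolute",
    "compute_fbc_edge",
]

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_ABS = 0.1


@dataclass
class RegularisationSpec:
    """Regularisation strength, scale factor and per-streamline reference.

    ``reference`` defaults to 0 (penalise deviation from unit weight); the
    symmetric longitudinal mode anchors it at the unbiased coefficients
    instead.
    """

    lambda_: float = DEFAULT_LAMBDA_ABS
    A: float = 1.0
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("regularisation strength must be >= 0")
        if self.A <= 0:
            raise ValueError("regularisation scale A must be > 0")

    def reference_for(self, n_streamlines: int) -> np.ndarray:
        if self.reference is None:
            return np.zeros(n_streamlines)
        ref = np.asarray(self.reference, dtype=np.float64)
        if ref.shape != (n_streamlines,):
            raise ValueError("regularisation reference length mismatch")
        return ref


@dataclass
class WeightedTractogram:
    """Result of an absolute fit: coefficients F_s, weights e^{F_s}, mu."""

    F: np.ndarray
    mu: float
    cost_trace: list[float] = field(default_factory=list)
    n_sweeps: int = 0
    converged: bool = True

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.F)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


def compute_scale_A(fixels: FixelSet, traversal: TraversalMatrix,
                    fd: np.ndarray | None = None) -> float:
    """Regularisation scale A = sum_f w_f FD_f^2 / sum_s l_s.

    Makes a lambda = 1 penalty comparable in magnitude to the data term
    regardless of grid size, density units, or streamline count.
    """
    if fd is None:
        fd = fixels.fd_session(0)
    total_len = float(np.sum(traversal.streamline_lengths()))
    if total_len <= 0:
        raise ValueError("empty traversal: no streamline intersects any fixel")
    return float(np.sum(fixels.weights * fd**2)) / total_len


def compute_tract_density(traversal: TraversalMatrix, F: np.ndarray) -> np.ndarray:
    """Fixel-wise weighted tract density TD_f = sum_s |s ∩ f| e^{F_s}."""
    F = np.asarray(F, dtype=np.float64)
    if not np.all(np.isfinite(F)):
        raise ValueError("streamline coefficients must be finite")
    return traversal.matrix.T @ np.exp(F)


def compute_mu(fixels: FixelSet, td: np.ndarray) -> float:
    """Proportionality coefficient mu = sum_f w_f FD_f / sum_f w_f TD_f."""
    denom = float(np.sum(fixels.weights * td))
    if denom <= 0:
        raise ValueError("all-zero weighted tract density: empty tractogram")
    return float(np.sum(fixels.weights * fixels.fd_session(0))) / denom


def _data_cost(fixels: FixelSet, fd: np.ndarray, td: np.ndarray, mu: float) -> float:
    r = mu * td - fd
    return float(np.sum(fixels.weights * r * r))


def absolute_cost(
    fixels: FixelSet,
    traversal: TraversalMatrix,
    F: np.ndarray,
    mu: float,
    reg: RegularisationSpec,
    fd: np.ndarray | None = None,
    return_parts: bool = False,
):
    """Evaluate the absolute objective (optionally split into data/reg parts)."""
    if fd is None:
        fd = fixels.fd_session(0)
    td = compute_tract_density(traversal, F)
    data = _data_cost(fixels, fd, td, mu)
    ref = reg.reference_for(len(F))
    ell = traversal.streamline_lengths()
    penalty = reg.A * reg.lambda_ * float(np.sum(ell * (F - ref) ** 2))
    if return_parts:
        return data + penalty, data, penalty
    return data + penalty


@njit(cache=False)
def _sweep_abs(indptr, indices, lengths, w, resid, F, expF, mu,
               alam, ell, ref, active):  # pragma: no cover - compiled
    """One cyclic coordinate-descent sweep with per-coordinate Newton steps
    and backtracking halving.  ``resid`` holds mu*TD - FD and is updated in
    place; the sweep never increases the objective."""
    n_s = F.shape[0]
    for s in range(n_s):
        if not active[s]:
            continue
        lo = indptr[s]
        hi = indptr[s + 1]
        u = expF[s]
        # local cost at current point (terms involving s only)
        c0 = alam * ell[s] * (F[s] - ref[s]) ** 2
        g = 2.0 * alam * ell[s] * (F[s] - ref[s])
        h = 2.0 * alam * ell[s]
        for q in range(lo, hi):
            f = indices[q]
            a = mu * lengths[q] * u  # d(mu*TD_f)/dF_s
            c0 += w[f] * resid[f] * resid[f]
            g += 2.0 * w[f] * resid[f] * a
            h += 2.0 * w[f] * a * a + 2.0 * w[f] * resid[f] * a
        if g == 0.0:
            continue
        if h <= 1e-300:
            h = abs(h) + 1e-12
        step = -g / h
        if step > 2.0:
            step = 2.0
        elif step < -2.0:
            step = -2.0
        accepted = False
        for _ in range(20):
            x = F[s] + step
            ux = math.exp(x)
            c = alam * ell[s] * (x - ref[s]) ** 2
            for q in range(lo, hi):
                f = indices[q]
                rn = resid[f] + mu * lengths[q] * (ux - u)
                c += w[f] * rn * rn
            if c < c0:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            continue
        for q in range(lo, hi):
            f = indices[q]
            resid[f] += mu * lengths[q] * (ux - u)
        F[s] = x
        expF[s] = ux


def optimize_absolute(
    fixels: FixelSet,
    traversal: TraversalMatrix,
    init_F: np.ndarray | None = None,
    init_mu: float | None = None,
    reg: RegularisationSpec | None = None,
    fd: np.ndarray | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-6,
) -> WeightedTractogram:
    """Minimise the absolute objective over streamline coefficients F_s.

    Cyclic coordinate descent with per-coordinate Newton steps and
    backtracking halving; the cost is non-increasing per sweep.  ``mu`` is
    computed from the initial coefficients unless ``init_mu`` is given (the
    symmetric longitudinal mode inherits the unbiased tractogram's mu), and
    is held fixed throughout.  Streamlines with zero in-model traversal are
    frozen at their initial coefficient.
    """
    n_s = traversal.n_streamlines
    if fd is None:
        fd = fixels.fd_session(0)
    fd = np.asarray(fd, dtype=np.float64)
    if fd.shape != (fixels.n_fixels,):
        raise ValueError("fibre-density vector does not match the fixel set")
    F = np.zeros(n_s) if init_F is None else np.array(init_F, dtype=np.float64)
    if F.shape != (n_s,):
        raise ValueError("init_F length mismatch")
    if reg is None:
        reg = RegularisationSpec(A=compute_scale_A(fixels, traversal, fd))
    ell = traversal.streamline_lengths()
    active = ell > 0
    td = compute_tract_density(traversal, F)
    mu = compute_mu(fixels.with_fd(fd), td) if init_mu is None else float(init_mu)
    if mu <= 0:
        raise ValueError("mu must be > 0")

    csr = traversal.matrix
    resid = mu * td - fd
    expF = np.exp(F)
    ref = reg.reference_for(n_s)
    alam = reg.A * reg.lambda_
    cost = _data_cost(fixels, fd, td, mu) + alam * float(np.sum(ell * (F - ref) ** 2))
    trace = [cost]
    converged = False
    for sweep in range(max_sweeps):
        _sweep_abs(csr.indptr, csr.indices.astype(np.int64), csr.data,
                   fixels.weights, resid, F, expF, mu, alam, ell, ref, active)
        new_cost = (float(np.sum(fixels.weights * resid * resid))
                    + alam * float(np.sum(ell * (F - ref) ** 2)))
        trace.append(new_cost)
        if cost <= 0 or (cost - new_cost) / cost < tol:
            cost = new_cost
            converged = True
            break
        cost = new_cost
    else:
        sweep = max_sweeps - 1
    if not converged and max_sweeps > 0:
        logger.warning("absolute optimisation did not converge within %d sweeps "
                       "(last relative change %.3e)", max_sweeps,
                       (trace[-2] - trace[-1]) / trace[-2] if trace[-2] else 0.0)
    logger.info("absolute fit: %d sweeps, cost %.6g -> %.6g, mu=%.6g",
                sweep + 1, trace[0], trace[-1], mu)
    return WeightedTractogram(F=F, mu=mu, cost_trace=trace,
                              n_sweeps=sweep + 1, converged=converged)


def compute_fbc_edge(weighted: WeightedTractogram, streamline_ids) -> float:
    """Fibre Bundle Capacity of one edge: mu * sum of member weights."""
    ids = np.asarray(streamline_ids, dtype=np.int64)
    if ids.size == 0:
        return 0.0
    return float(weighted.mu * np.sum(np.exp(weighted.F[ids])))
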