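"""End-to-end validation pipelines on longitudinal phantoms.

Four longitudinal connectome pipelines are compared on phantoms with known
ground-truth fibre-count changes:

1. **NoS cross-sectional** — independent tractogram draw per session,
   number-of-streamlines connectomes, edge-wise difference.
2. **FBC cross-sectional** — the same per-session tractograms, each fitted
   to its own session's fibre densities (session-specific mu), edge-wise
   FBC difference.
3. **FBC symmetric** — one shared (unbiased) tractogram fitted to the
   session-mean densities, warm-started per-session re-fits, FBC
   difference.
4. **FBC differential** — the same unbiased fit, with per-streamline delta
   coefficients fitted directly to the density half-difference.

Bundle-wise errors are the absolute deviations of globally scaled
connectivity changes from the true fibre-count changes; error distributions
are compared across pipelines with a Kruskal-Wallis omnibus test followed
by pairwise Dunn tests with Holm correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .absolute import absolute_cost, compute_scale_A, optimize_absolute, RegularisationSpec
from .connectome import (
    Connectome,
    assign_streamlines,
    bundle_error_abs,
    bundle_error_diff,
    fbc_connectome,
    nos_connectome,
    scale_to_fibre_count,
)
from .grid import Tractogram, compute_traversal
from .longitudinal import (
    _accumulate_edges,
    differential_cost,
    differential_delta_fbc,
    fit_unbiased,
    optimize_differential,
    symmetric_delta_fbc,
    symmetric_optimize,
)
from .phantom import (
    PhantomConfig,
    PhantomPair,
    add_density_noise,
    build_model,
    perturb_session_tractogram,
    synthesize_tractogram,
)

__all__ = [
    "PipelineResult",
    "ErrorComparison",
    "run_pipeline",
    "run_all_pipelines",
    "compare_errors",
    "evaluate_pipelines",
    "false_positive_experiment",
    "PIPELINE_NAMES",
]

logger = logging.getLogger(__name__)

PIPELINE_NAMES = {
    1: "NoS cross-sectional",
    2: "FBC cross-sectional",
    3: "FBC symmetric",
    4: "FBC differential",
}

ALPHA = 0.05


@dataclass
class PipelineResult:
    """Differential connectome and bundle-wise errors for one pipeline run."""

    pipeline_id: int
    delta_connectome: Connectome
    sc_tp1: Connectome
    phi: float
    errors: np.ndarray  # per ground-truth bundle, >= 0
    cost_traces: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pipeline_id not in PIPELINE_NAMES:
            raise ValueError(f"unknown pipeline id {self.pipeline_id}")
        if np.any(self.errors < 0):
            raise ValueError("bundle errors must be >= 0")


@dataclass
class ErrorComparison:
    """Kruskal-Wallis omnibus plus Dunn-Holm pairwise comparisons."""

    groups: list[int]
    medians: dict[int, float]
    kw_statistic: float
    kw_p: float
    pairwise_p: dict[tuple[int, int], float]  # Holm-adjusted
    pairwise_p_raw: dict[tuple[int, int], float]

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple[int, int]]:
        return [pair for pair, p in self.pairwise_p.items() if p < alpha]


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


class _Replicate:
    """Shared per-replicate intermediates across the four pipelines."""

    def __init__(self, pair: PhantomPair, seed: int,
                 lambda_abs: float = 0.1, lambda_diff: float = 0.1) -> None:
        self.pair = pair
        self.seed = int(seed)
        self.lambda_abs = lambda_abs
        self.lambda_diff = lambda_diff
        s = _derive_seeds(seed, 4)
        self._seeds = {"tp1": int(s[0]), "tp2": int(s[1]),
                       "unbiased": int(s[2]), "noise": int(s[3])}
        self._cache: dict[str, object] = {}

    def _get(self, key: str, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    @property
    def fixels(self):
        return self._get("fixels", lambda: add_density_noise(
            self.pair.fixels, self.pair.config.noise_sigma, self._seeds["noise"]))

    def session_tractogram(self, session: int) -> Tractogram:
        key = f"tract_tp{session + 1}"
        return self._get(key, lambda: perturb_session_tractogram(
            self.pair, session, self._seeds[f"tp{session + 1}"]))

    def session_traversal(self, session: int):
        key = f"trav_tp{session + 1}"
        return self._get(key, lambda: compute_traversal(
            self.session_tractogram(session), self.fixels))

    def session_assignment(self, session: int):
        key = f"assign_tp{session + 1}"
        return self._get(key, lambda: assign_streamlines(
            self.session_tractogram(session), self.pair.nodes))

    @property
    def unbiased_tractogram(self) -> Tractogram:
        mean_counts = 0.5 * (self.pair.counts(0) + self.pair.counts(1))
        return self._get("tract_unb", lambda: synthesize_tractogram(
            self.pair, seed=self._seeds["unbiased"], counts=mean_counts))

    @property
    def unbiased_traversal(self):
        return self._get("trav_unb", lambda: compute_traversal(
            self.unbiased_tractogram, self.fixels))

    @property
    def unbiased_assignment(self):
        return self._get("assign_unb", lambda: assign_streamlines(
            self.unbiased_tractogram, self.pair.nodes))

    @property
    def unbiased_fit(self):
        return self._get("fit_unb", lambda: fit_unbiased(
            self.unbiased_tractogram, self.unbiased_traversal, self.fixels,
            lambda_abs=self.lambda_abs))


def _finish(pair: PhantomPair, pipeline_id: int, delta: np.ndarray,
            sc_tp1: np.ndarray, metric: str, traces, seed: int) -> PipelineResult:
    labels = pair.nodes.labels
    delta_c = Connectome(labels=labels, matrix=delta, metric="d" + metric)
    sc_c = Connectome(labels=labels, matrix=sc_tp1, metric=metric)
    phi = scale_to_fibre_count(sc_c, pair.fc_connectome(0))
    errors = bundle_error_diff(delta_c, pair.delta_fc_connectome(), phi,
                               pair.bundle_edges())
    return PipelineResult(pipeline_id=pipeline_id, delta_connectome=delta_c,
                          sc_tp1=sc_c, phi=phi, errors=errors,
                          cost_traces=traces, seed=seed)


def _run_pipeline_on(rep: _Replicate, pipeline_id: int) -> PipelineResult:
    pair = rep.pair
    if pipeline_id == 1:
        nos = [nos_connectome(rep.session_assignment(s), pair.nodes.labels)
               for s in (0, 1)]
        # phantom evaluation: NoS differences are left unscaled by mu, as
        # pipeline comparability comes from the global fibre-count scaling
        return _finish(pair, 1, nos[1].matrix - nos[0].matrix, nos[0].matrix,
                       "NoS", {}, rep.seed)
    if pipeline_id == 2:
        fits = []
        fbcs = []
        for s in (0, 1):
            trav = rep.session_traversal(s)
            fd = rep.fixels.fd_session(s)
            A = compute_scale_A(rep.fixels, trav, fd)
            fit = optimize_absolute(rep.fixels, trav, fd=fd,
                                    reg=RegularisationSpec(lambda_=rep.lambda_abs, A=A))
            fits.append(fit)
            fbcs.append(fbc_connectome(rep.session_assignment(s), fit,
                                       pair.nodes.labels))
        traces = {"abs_tp1": fits[0].cost_trace, "abs_tp2": fits[1].cost_trace}
        return _finish(pair, 2, fbcs[1].matrix - fbcs[0].matrix, fbcs[0].matrix,
                       "FBC", traces, rep.seed)
    if pipeline_id == 3:
        unb = rep.unbiased_fit
        w = [symmetric_optimize(unb, rep.fixels.fd_session(s),
                                lambda_abs=rep.lambda_abs) for s in (0, 1)]
        edges = rep.unbiased_assignment.edges
        delta = symmetric_delta_fbc(w[0], w[1], unb.mu, edges, pair.nodes.n_nodes)
        fbc1 = fbc_connectome(rep.unbiased_assignment, w[0], pair.nodes.labels)
        traces = {"unbiased": unb.fit.cost_trace,
                  "sym_tp1": w[0].cost_trace, "sym_tp2": w[1].cost_trace}
        return _finish(pair, 3, delta, fbc1.matrix, "FBC", traces, rep.seed)
    if pipeline_id == 4:
        unb = rep.unbiased_fit
        delta_coef = optimize_differential(unb, lambda_diff=rep.lambda_diff)
        edges = rep.unbiased_assignment.edges
        delta = differential_delta_fbc(unb, delta_coef, edges, pair.nodes.n_nodes)
        # implied first-session capacity: mu * sum e^F (1 - dF) per edge
        w_tp1 = unb.mu * np.exp(unb.F) * (1.0 - delta_coef.dF)
        sc_tp1 = _accumulate_edges(w_tp1, edges, pair.nodes.n_nodes)
        traces = {"unbiased": unb.fit.cost_trace,
                  "diff": delta_coef.cost_trace}
        return _finish(pair, 4, delta, sc_tp1, "FBC", traces, rep.seed)
    raise ValueError(f"unknown pipeline id {pipeline_id!r}")


def run_pipeline(pair: PhantomPair, pipeline_id: int, seed: int,
                 lambda_abs: float = 0.1, lambda_diff: float = 0.1) -> PipelineResult:
    """Run one longitudinal connectome pipeline on a phantom pair."""
    rep = _Replicate(pair, seed, lambda_abs, lambda_diff)
    return _run_pipeline_on(rep, pipeline_id)


def run_all_pipelines(pair: PhantomPair, seed: int,
                      pipelines: tuple[int, ...] = (1, 2, 3, 4),
                      lambda_abs: float = 0.1,
                      lambda_diff: float = 0.1) -> dict[int, PipelineResult]:
    """Run several pipelines on one replicate, sharing tractograms and fits."""
    rep = _Replicate(pair, seed, lambda_abs, lambda_diff)
    return {p: _run_pipeline_on(rep, p) for p in pipelines}


# ---------------------------------------------------------------------------
# rank statistics

def _dunn_holm(samples: dict[int, np.ndarray]) -> tuple[dict, dict]:
    """Pairwise Dunn z-tests on pooled rank sums with tie correction,
    Holm step-down adjusted over all pipeline pairs."""
    keys = sorted(samples)
    pooled = np.concatenate([samples[k] for k in keys])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = tie_term / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    mean_ranks = {}
    start = 0
    for k in keys:
        n_k = len(samples[k])
        mean_ranks[k] = float(np.mean(ranks[start : start + n_k]))
        start += n_k
    raw: dict[tuple[int, int], float] = {}
    for a, b in itertools.combinations(keys, 2):
        var = (n_total * (n_total + 1) / 12.0 - correction) \
            * (1.0 / len(samples[a]) + 1.0 / len(samples[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var) if var > 0 else 0.0
        raw[(a, b)] = float(2.0 * sps.norm.sf(abs(z)))
    # Holm step-down
    pairs = sorted(raw, key=lambda p: raw[p])
    m = len(pairs)
    adjusted: dict[tuple[int, int], float] = {}
    running = 0.0
    for rank, pair in enumerate(pairs):
        running = max(running, (m - rank) * raw[pair])
        adjusted[pair] = min(1.0, running)
    return adjusted, raw


def compare_errors(samples: dict[int, np.ndarray]) -> ErrorComparison:
    """Kruskal-Wallis omnibus on pooled bundle-wise errors, then pairwise
    Dunn tests with Holm correction (significance at alpha = 0.05)."""
    if len(samples) < 2:
        raise ValueError("need at least two pipelines to compare")
    for k, v in samples.items():
        if len(v) == 0:
            raise ValueError(f"empty error sample for pipeline {k}")
    keys = sorted(samples)
    arrays = [np.asarray(samples[k], dtype=float) for k in keys]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        # identical groups: the omnibus statistic is degenerate
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = sps.kruskal(*arrays)
    adjusted, raw = _dunn_holm({k: np.asarray(v, dtype=float)
                                for k, v in samples.items()})
    return ErrorComparison(
        groups=keys,
        medians={k: float(np.median(samples[k])) for k in keys},
        kw_statistic=float(kw_stat),
        kw_p=float(kw_p),
        pairwise_p=adjusted,
        pairwise_p_raw=raw,
    )


@dataclass
class EvaluationReport:
    """Pooled bundle-wise errors and their statistical comparison."""

    errors: dict[int, np.ndarray]  # pipeline -> pooled errors
    comparison: ErrorComparison
    n_replicates: int
    models: tuple[int, ...]
    master_seed: int


def evaluate_pipelines(
    models: tuple[int, ...] = (1, 2, 3),
    n_replicates: int = 20,
    config: PhantomConfig | None = None,
    master_seed: int = 0,
    pipelines: tuple[int, ...] = (1, 2, 3, 4),
    lambda_abs: float = 0.1,
    lambda_diff: float = 0.1,
) -> EvaluationReport:
    """Multi-seed, multi-model pipeline comparison.

    Bundle-wise errors are pooled across replicates and models within each
    pipeline before the omnibus test, mirroring a per-bundle scatter of
    reconstruction errors.
    """
    if config is None:
        config = PhantomConfig()
    rng = np.random.default_rng(master_seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(len(models), n_replicates))
    pooled: dict[int, list[np.ndarray]] = {p: [] for p in pipelines}
    for mi, model in enumerate(models):
        pair = build_model(model, config)
        for r in range(n_replicates):
            results = run_all_pipelines(pair, int(rep_seeds[mi, r]),
                                        pipelines=pipelines,
                                        lambda_abs=lambda_abs,
                                        lambda_diff=lambda_diff)
            for p, res in results.items():
                pooled[p].append(res.errors)
        logger.info("model %d: %d replicates done", model, n_replicates)
    errors = {p: np.concatenate(v) for p, v in pooled.items()}
    comparison = compare_errors(errors)
    return EvaluationReport(errors=errors, comparison=comparison,
                            n_replicates=n_replicates, models=tuple(models),
                            master_seed=master_seed)


# ---------------------------------------------------------------------------
# false-positive experiment

def _subset_tractogram(tract: Tractogram, keep: np.ndarray) -> Tractogram:
    idx = np.nonzero(keep)[0]
    remap = {int(old): new for new, old in enumerate(idx)}
    fp_pairs = None
    if tract.fp_pairs:
        fp_pairs = {remap[s]: pair for s, pair in tract.fp_pairs.items()
                    if s in remap}
    return Tractogram(
        streamlines=[tract.streamlines[i] for i in idx],
        bundle_ids=None if tract.bundle_ids is None else tract.bundle_ids[idx],
        fp_pairs=fp_pairs,
    )


def false_positive_experiment(
    config: PhantomConfig | None = None,
    seed: int = 0,
    lambda_abs: float = 0.1,
    lambda_diff: float = 0.1,
) -> dict[str, dict[str, float]]:
    """Central-lesion phantom with and without false-positive streamlines.

    One tractogram is drawn with false positives; the 'without' condition is
    its true-positive subset, so the two conditions share every true
    streamline.  For each condition the unbiased tractogram is fitted and
    (a) the first session is reconstructed by absolute optimisation (summed
    bundle-wise eps_abs), (b) inter-session change by differential
    optimisation (summed eps_diff); data-term costs before and after each
    optimisation are recorded.
    """
    if config is None:
        config = PhantomConfig()
    pair = build_model(3, config)
    seeds = _derive_seeds(seed, 2)
    fixels = add_density_noise(pair.fixels, config.noise_sigma, int(seeds[1]))
    mean_counts = 0.5 * (pair.counts(0) + pair.counts(1))
    full = synthesize_tractogram(pair, seed=int(seeds[0]), counts=mean_counts)
    conditions = {
        "with_fp": full,
        "without_fp": _subset_tractogram(full, full.bundle_ids >= 0),
    }
    fc1 = pair.fc_connectome(0)
    bundle_edges = pair.bundle_edges()
    report: dict[str, dict[str, float]] = {}
    for name, tract in conditions.items():
        trav = compute_traversal(tract, fixels)
        assignment = assign_streamlines(tract, pair.nodes)
        unb = fit_unbiased(tract, trav, fixels, lambda_abs=lambda_abs)
        fd1 = fixels.fd_session(0)
        A = unb.scale_A
        reg1 = RegularisationSpec(lambda_=lambda_abs, A=A)
        _, abs_cost_before, _ = absolute_cost(
            fixels, trav, np.zeros(len(tract)),
            mu=_init_mu(fixels, trav, fd1), reg=reg1, fd=fd1,
            return_parts=True)
        fit1 = optimize_absolute(fixels, trav, fd=fd1, reg=reg1)
        _, abs_cost_after, _ = absolute_cost(
            fixels, trav, fit1.F, mu=fit1.mu, reg=reg1, fd=fd1,
            return_parts=True)
        sc1 = fbc_connectome(assignment, fit1, pair.nodes.labels)
        phi1 = scale_to_fibre_count(sc1, fc1)
        eps_abs = bundle_error_abs(sc1, fc1, phi1, bundle_edges)

        _, diff_cost_before, _ = differential_cost(
            fixels, trav, unb.F, np.zeros(len(tract)), unb.mu,
            lambda_diff=lambda_diff, scale_A=A, return_parts=True)
        delta_coef = optimize_differential(unb, lambda_diff=lambda_diff)
        _, diff_cost_after, _ = differential_cost(
            fixels, trav, unb.F, delta_coef.dF, unb.mu,
            lambda_diff=lambda_diff, scale_A=A, return_parts=True)
        delta = differential_delta_fbc(unb, delta_coef, assignment.edges,
                                       pair.nodes.n_nodes)
        delta_c = Connectome(labels=pair.nodes.labels, matrix=delta, metric="dFBC")
        w_tp1 = unb.mu * np.exp(unb.F) * (1.0 - delta_coef.dF)
        sc_tp1_diff = Connectome(
            labels=pair.nodes.labels,
            matrix=_accumulate_edges(w_tp1, assignment.edges, pair.nodes.n_nodes),
            metric="FBC")
        phi_d = scale_to_fibre_count(sc_tp1_diff, fc1)
        eps_diff = bundle_error_diff(delta_c, pair.delta_fc_connectome(),
                                     phi_d, bundle_edges)
        report[name] = {
            "n_streamlines": float(len(tract)),
            "sum_eps_abs": float(np.sum(eps_abs)),
            "sum_eps_diff": float(np.sum(eps_diff)),
            "abs_cost_before": abs_cost_before,
            "abs_cost_after": abs_cost_after,
            "diff_cost_before": diff_cost_before,
            "diff_cost_after": diff_cost_after,
        }
    return report


def _init_mu(fixels, trav, fd):
    from .absolute import compute_mu, compute_tract_density
    td = compute_tract_density(trav, np.zeros(trav.n_streamlines))
    return compute_mu(fixels.with_fd(fd), td)
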