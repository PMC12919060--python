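# Methods

This note documents the models implemented in `longisift`, the numerical
choices behind them, the synthetic phantoms used for validation, and the
limitations of both.

## Fixel geometry and streamline traversal

Voxel centres sit at `origin + index · voxel_size`; voxels are half-open
boxes whose faces belong to the neighbour with the higher index. Streamline
polylines are split *exactly* at voxel faces (no resampling), which removes
any step-size parameter from the intersection lengths `|s ∩ f|`. Each
within-voxel piece is attributed to the candidate fixel of its voxel with
the largest axial alignment `|d·u|`, accepted only above `cos 45°`
(fixels are axial, so antipodal directions are equivalent); ties break
toward the lowest fixel id for determinism. Pieces outside the grid or
without an acceptable fixel are tallied as dropped, so that per streamline
`Σ_f |s ∩ f| + dropped = arc length` to 1e-6. The traversal matrix is
stored sparse (streamline × fixel, CSR); the splitting/attribution kernel
and both optimiser sweeps are numba-compiled.

## Absolute optimisation

The fit minimises

    C(F) = Σ_f w_f (μ·TD_f(F) − FD_f)² + A·λ_abs·Σ_s ℓ_s (F_s − ref_s)²

with `TD_f = Σ_s |s∩f| e^{F_s}` and `ℓ_s` the streamline's total in-model
traversal length. μ is computed once from the initial coefficients
(`μ = Σ w_f FD_f / Σ w_f TD_f`) and held fixed; immediately after
computation, `μ Σ w TD = Σ w FD` holds to 1e-9 relative.

**Regularisation.** `R_abs(F_s) = ℓ_s (F_s − ref_s)²` is quadratic in the
exponential coefficient — fold-changes up and down are penalised
symmetrically — and length-weighted, so a streamline's penalty scales with
its leverage on the data term. The scale factor
`A = Σ_f w_f FD_f² / Σ_s ℓ_s` makes a λ = 1 penalty comparable to the
data term at full misfit regardless of grid size, density units or
streamline count. Default `λ_abs = 0.1`, reference `ref = 0`.

**Optimiser.** Cyclic coordinate descent. Each coordinate takes a Newton
step on its one-dimensional restriction (the data term is quadratic in
`u = e^{F_s}`, the penalty quadratic in `F_s`), clipped to |step| ≤ 2 and
backtracked by halving (≤ 20 times) until the local cost strictly
decreases; the fixel residuals `μ·TD_f − FD_f` are updated incrementally.
The cost is therefore non-increasing per sweep. Convergence is declared
when the relative cost change per sweep falls below 1e-6 (default), capped
at 100 sweeps; hitting the cap emits a warning with the last iterate, not
an error — the residual redistribution among streamlines sharing fixels
has a long, flat tail that does not affect aggregate quantities.
Streamlines with zero in-model traversal are frozen at their initial
coefficient.

Note that the data term constrains only per-fixel *sums* of weights;
where many streamlines traverse identical fixel sets, the split of an
edge's total weight across its individual streamlines is determined only
by the regulariser. Bundle-level quantities (FBC, ΔFBC) are well
determined; individual weights are not, and tests assert accordingly.

## Longitudinal strategies

Both operate on an **unbiased quantitative tractogram**: one streamline
set, traversal matrix, and weights fitted to the session-mean fibre
density `(fd_TP1 + fd_TP2)/2`, emulating reconstruction in a symmetric
within-subject template.

**Symmetric.** The absolute fit is re-run once per session with (i) warm
start at the unbiased coefficients, (ii) μ inherited from the unbiased fit
(the differential connectome formula uses the unbiased μ, so per-session
recomputation is deliberately not implemented), and (iii) the
regularisation reference set to the unbiased coefficients rather than 0 —
weights perturb from the unbiased solution only where the session data
make it worthwhile. With session fd equal to the mean fd and λ = 0 this
is an exact fixed point; at λ > 0 the two identical session runs still
give an exactly zero differential connectome. The differential connectome
is `ΔFBC_ij = μ Σ_{s∈ij} (e^{F^TP2} − e^{F^TP1})`, identical by
construction to the difference of the per-session FBC connectomes.

**Differential.** Delta coefficients `ΔF_s`, initialised at 0, minimise

    Σ_f w_f (μ·TD_f^diff − FD_f^diff)² + A·λ_diff·Σ_s ℓ_s e^{F_s} ΔF_s²

with `TD_f^diff = Σ_s |s∩f| e^{F_s} ΔF_s` and `FD^diff` the half-difference
of session densities. The penalty `R_diff = ℓ_s e^{F_s} ΔF_s²` is even and
anchored at zero (the prior is that most streamlines carry no change) and
scaled by each streamline's unbiased density leverage; `A` and the default
`λ_diff = 0.1` match the absolute module. The objective is a convex
quadratic in ΔF; each coordinate subproblem is solved exactly and then
clamped to [−1, 1] (projection after every update — simple, and monotone
in cost). Because every update is an odd function of the density
difference, swapping the sessions negates the result exactly, to the bit.
The pairing of mean-density weights, half-difference target and delta
definition makes full appearance/disappearance of a bundle land exactly on
the constraint boundary `ΔF_s = ±1`.

## Connectomes, scaling and errors

Endpoints map to spherical nodes by containment, falling back to the
nearest node centre within 4 mm (phantom nodes are well separated, so
results are insensitive to this radius); streamlines with an unmapped
endpoint join no edge; two endpoints in one node form a diagonal entry.
Metrics: NoS (counts), FBC, ΔFBC.

Estimated changes are compared with ground-truth fibre counts after global
scaling by `φ = Σ SC^TP1 / Σ FC^TP1` (upper triangle including diagonal):
the bundle-wise longitudinal error is `ε_ij = |ΔSC_ij/φ − ΔFC_ij|`, i.e.
structural-connectivity totals are brought onto the fibre-count scale so a
perfect reconstruction scores zero; the analogous cross-sectional error is
`ε_ij^abs = |SC_ij/φ − FC_ij|`. Scaled quantities are invariant to any
global rescaling of weights. For pipeline 4, which produces no per-session
connectome, the implied first-session capacity
`μ Σ e^{F_s}(1 − ΔF_s)` per edge defines `SC^TP1` for scaling. In the
phantom evaluation, NoS differences are left unscaled by μ (the
fibre-count normalisation already makes pipelines comparable); μ-scaling
of NoS differences is only meaningful for in-vivo data and is out of
scope here.

## Synthetic phantoms

The generator replaces signal-level simulation (diffusion encoding,
Rician noise, spherical deconvolution) and probabilistic tracking with
direct geometric synthesis, because the optimisation framework consumes
fixel fibre densities, not images.

* **Bundles** are straight tubes (radius 1.5 mm) between spherical
  endpoint nodes (radius 2 mm) on a 32³ grid of 1 mm voxels.
* **Fibre densities**: for each voxel a tube overlaps, the expected
  per-fibre length in the voxel is estimated by a deterministic 64-point
  sunflower quadrature over uniform-disk radial offsets — the same
  distribution streamline offsets are drawn from — and
  `fd = fibre_count · a_fibre · expected_length` with
  `a_fibre = 1e-3 mm²` (an arbitrary global area scale absorbed by μ).
  Bundle contributions within 30° (axially) share a fixel; at most 3
  fixels per voxel; `w_f = 1` in all tissue voxels. fd is exactly linear
  in the fibre counts.
* **Models**: (1) one isolated bundle drops to 25% of its count, plus
  unchanged distractors; (2) two crossing bundles change by −50% and
  +100%; (3) a central spherical lesion (radius 5 mm) zeroes every bundle
  whose centreline intersects it. Unchanged distractor bundles are always
  present so error distributions contain affected and unaffected bundles.
* **Tractograms** (default 2000 streamlines): true positives follow a
  bundle end-to-end with a constant radial offset plus Gaussian waypoint
  jitter (σ = 0.3 mm, a modest trajectory wobble emulating tracking
  dispersion); false positives follow one bundle to a crossing and switch
  to another, creating trajectories with only partial correspondence to
  real bundles. The default false-positive fraction is 0.5 — around half
  the tractogram, matching the regime the validation experiments probe.
  True positives are allocated to bundles proportionally to fibre counts
  (minimum one), using TP1 counts by default, session counts for the
  session-specific draws of the cross-sectional pipelines, and mean
  counts for the unbiased tractogram.
* **Density noise**: `fd ← max(0, fd + N(0, σ·mean fd))`, independent per
  session, σ = 0.05 by default — a 5% relative perturbation emulating the
  density variability of an SNR ≈ 20 acquisition at the fixel level.

What the phantoms do **not** emulate: curved or branching anatomy,
partial-volume model weights below 1, Rician (signal-level) noise
statistics, fixel-correspondence errors between sessions, or realistic
whole-brain bundle counts. Passing tests therefore demonstrate the
correctness and comparative behaviour of the optimisation machinery under
controlled conditions, not in-vivo performance.

## Validation harness

Four pipelines per replicate, sharing intermediates where the designs
share them: (1) NoS from two independent session draws; (2) per-session
absolute SIFT2 fits (session-specific μ) on those same draws; (3)
symmetric re-fits of one shared unbiased fit; (4) differential fit of the
same unbiased fit. Per-replicate sub-seeds (session draws, unbiased draw,
density noise) derive from one replicate seed, and replicate seeds from a
master seed, so entire evaluations are bit-reproducible.

Bundle-wise errors are pooled across 20 replicate seeds and the three
models (each bundle–replicate pair one sample) and compared with a
Kruskal–Wallis omnibus test followed by pairwise Dunn z-tests on pooled
rank sums with tie correction and Holm step-down adjustment (α = 0.05).
Dunn–Holm is implemented in-package from rank sums; the omnibus test is
scipy's.

The false-positive experiment re-runs the central-lesion model with and
without false positives. One tractogram is drawn with false positives and
the "without" condition is its true-positive subset, so both conditions
share every true streamline and the with-FP condition strictly adds
degrees of freedom. Reported per condition: summed cross-sectional error
after an absolute fit to TP1, summed longitudinal error after a
differential fit, and the data-term cost before/after each optimisation.

**Problem sizes.** Evaluations use 32³ grids, 4–6 bundles, 2000
streamlines and 20 replicate seeds per model; the delta-coefficient bound
uses a single-bundle phantom with 400 streamlines and deep convergence
(3000/2000 sweep caps, tolerances 1e-13/1e-14, λ = 1e-6). These sizes are
the package's chosen desk-scale study conditions; all headline behaviours
are scale-stable in our experience (FBC itself is insensitive to
streamline count within 5% under doubling).

## Known limitations

* The regularisation functionals and the scale factor A are this
  package's documented choices; no bit-equivalence with any external
  SIFT2 implementation is claimed, and exact voxel-face splitting differs
  from implementations that resample streamlines.
* Coordinate descent leaves the within-edge split of weights close to its
  warm start (see above); only aggregate quantities should be interpreted.
* φ is defined as ΣSC/ΣFC and estimated changes are *divided* by it, so
  scaled totals land on the fibre-count scale.
* Fixel sets are assumed identical across sessions (no fixel
  correspondence problem), and node regions are non-overlapping spheres.
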