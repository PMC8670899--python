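# Methods

## Model

A diffusion MRI dataset assigns a signal S_{i,j} to each sampling point of the
joint spatioangular domain: voxel center x_i ∈ ℝ³ (mm), unit gradient
direction q̂_j and diffusion weighting b_j (s/mm²). We place a node at every
(i, j) and connect nodes with the separable Gaussian affinity

w = exp(−‖Δx‖²/2σₓ²) · exp(−(1−⟨q̂,q̂′⟩²)/2σ_q²) · exp(−(Δb̃)²/2σ_b²).

Conventions worth making explicit:

- **Denominators.** All three kernels use the standard 2σ² Gaussian form.
  With σₓ = 8 mm and 2 mm voxels, the largest per-axis squared separation
  inside a 5×5×5 patch is (4·2)² = 64 mm², so the worst-case spatial exponent
  argument is 64/128 = 0.5 — the bandwidth is matched to the patch size.
- **Angular term.** 1 − ⟨q̂,q̂′⟩² is used, not (1 − ⟨q̂,q̂′⟩)². Diffusion
  sensitization along q̂ and −q̂ is physically identical, so the angular
  similarity must be antipodally symmetric; the squared inner product is, the
  alternative reading is not.
- **b normalization.** b̃ = b/max(b), so the b-term exponent argument lies in
  [0, 1]. For single-shell data the term is identically 1.
- **Spatial coordinates** are voxel centers in mm (index × voxel size);
  distances inside the kernel are Euclidean.

Sparsity comes from the neighborhood system, not from thresholding: node
(i, j) connects to (i′, j′) only if the voxel indices differ by at most
`spatial_radius` in Chebyshev distance (default 1: the 27-voxel cube) and j′
is among the `angular_k` directions nearest to j by squared inner product
(default 5, self included, symmetrized so the relation is mutual; ties break
toward the lower volume index for determinism). An optional `weight_floor`
drops weaker edges; the default keeps all. For a 5×5×5 patch with 30
directions this yields 3 750 nodes and ~1.7×10⁵ edges — far below the ~7×10⁶
pairs of a dense graph.

b = 0 volumes have no defined direction and are excluded from the
spatioangular graph; the pipeline denoises them on a spatial-only graph
(angular and b factors ≡ 1).

## Objective and solver

Denoising minimizes

F(s) = ½‖s − y‖₂² + λ‖Ls‖₁,

where L is the weighted incidence operator: row e = (a, b), a < b in node
order, equals w_e(δ_a − δ_b). Each unordered edge is counted **once**; a
formulation that sums over ordered pairs counts every edge twice, which is
equivalent to doubling λ. Users comparing λ values across conventions should
keep this factor in mind. λ is also signal-scale dependent (the fidelity is
quadratic, the penalty linear): rescaling the data by c while keeping λ fixed
changes the effective regularization by 1/c. The default λ = 0.1 is mild at
the phantom's s0 = 1000 scale; values of order 1–2 denoise much more
aggressively there.

The minimizer is computed by the Condat–Vũ forward–backward primal–dual
iteration with primal variable s (initialized at y) and dual variable
v ∈ ℝ^E (initialized at 0):

1. s⁺ = s − τ(∇f(s) + Lᵀv), with ∇f(s) = s − y;
2. v⁺ = prox of the conjugate of λ‖·‖₁ at v + σ L(2s⁺ − s), which by the
   Moreau identity is componentwise clipping to [−λ, λ].

Step sizes: τ = 1/β with β = 1 (the fidelity gradient is 1-Lipschitz), and
σ = 0.99·(1/τ − β/2)/‖L‖², which satisfies the convergence condition
τ(β/2 + σ‖L‖²) < 1. ‖L‖ is estimated by 50 power iterations on LᵀL from a
fixed pseudo-random start, so the whole solve is deterministic.
User-supplied steps violating the condition are rejected.

**Stopping.** The objective is monitored every iteration; the solver stops
when its relative change stays below `rel_tol` (default 10⁻³) on two
consecutive iterations, or at `max_iter` (default 200). Two consecutive
checks are required because (a) the first iteration cannot move — the
fidelity gradient vanishes at s = y and the dual is still zero — and (b) the
objective of a primal–dual method is not monotone, and single-step
coincidences occur (we observed an exact objective tie on a 3-node instance).
Transient objective increases of a few percent of the total decrease are
normal for this class of method; the iterates, and hence the objective,
still converge.

**Batching.** The iteration is columnwise separable, so many signals sharing
one graph solve as a single matrix iteration. Each column's output is frozen
at its own stopping iteration, making results independent of how columns are
grouped — this is what makes multi-worker execution bit-identical to serial.

**Oracle.** For verification, `oracle_solve` computes the exact optimum on
graphs of ≤ 8 nodes by a different route entirely: the Fenchel dual of F is
the smooth box-constrained quadratic program min_v ½‖Lᵀv‖² − vᵀLy over
v ∈ [−λ, λ]^E, solved with L-BFGS-B; strong duality gives s\* = y − Lᵀv\*.
The primal–dual solver matches this oracle to better than 10⁻⁴ relative
objective gap on randomized instances (measured ~10⁻⁹).

## Pipeline

Volumes are tiled into 5×5×5 patches with overlap step 2; the final origin on
each axis is forced to touch the boundary, guaranteeing coverage. All patches
of the same shape share one graph (affinities depend only on index
differences), so a 16³ volume's 343 patches solve as one batch. Overlapping
estimates are merged by an unweighted average in fixed patch order —
deterministic and extension-friendly; tapered windows were deliberately
rejected to keep the merge order-independent. Patches larger than the volume
are clipped with a warning.

Optional pre-processing:

- `estimate_noise_sigma`: MAD of first-order voxel differences along the
  longest axis, scaled by 1/√2 and 1.4826 (normal-consistent). Accurate to
  well under 5% on pure-Gaussian volumes of 32³; offset-invariant; biased
  upward when genuine fine-scale structure dominates noise.
- `stabilize_variance`: m → √max(m² − 2σ², 0), from the Rician second moment
  E[M²] = S² + 2σ². It is exactly unbiased for the squared signal at every
  SNR, and reduces the magnitude-domain bias only at low SNR (≲ 1): at high
  SNR the √ concavity makes the corrected mean undershoot by ≈ σ²/2S, the
  mirror image of the raw Rician overshoot. It is a simple moment-matching
  stage, pluggable if a more refined stabilizer is available; it defaults to
  off and is meant for Rician-noise inputs.

## Phantom

The generator emulates a single-shell acquisition: 30 noncollinear directions
at b = 1000 s/mm² plus one b = 0 image, isotropic 2 mm voxels. Directions are
a Fibonacci spiral on the upper hemisphere under a seeded random rotation —
deterministic, approximately uniform, pairwise noncollinear by construction.
The geometry is a block phantom: cuboid regions each carrying 1–2 tensor
principal directions; overlapping regions mix compartments with equal
weights. The default layout is two orthogonal slabs whose intersection is a
90° crossing, surrounded by isotropic background, providing the features a
spatioangular denoiser must respect: piecewise-constant regions, sharp edges,
single fibers and crossings. Signals follow the multi-tensor model
S = s0·mean_t exp(−b q̂ᵀD_t q̂) with axially symmetric tensors (defaults:
axial 1.7×10⁻³, radial 0.3×10⁻³ mm²/s; isotropic background 0.7×10⁻³ mm²/s,
a gray-matter-like mean diffusivity). Noise is additive Gaussian or Rician
magnitude noise, seeded.

Scale conventions: s0 = 1000, so noise deviations of 100–300 correspond to
10–30% of the baseline signal. The default volume is 16³ voxels — large
enough for 343 overlapping patches and meaningful SSIM windows, small enough
that the full three-noise-level experiment runs in about a minute; larger
volumes are reachable through `PhantomConfig(dims=...)`.

What the phantom does **not** emulate: realistic anatomy and curved fiber
geometry, spatially varying (parallel-imaging) noise fields, multi-shell
sampling, partial-volume fractions other than equal-weight mixing. Passing
results therefore demonstrate the mechanics of spatioangular denoising —
edge- and crossing-preservation under i.i.d. noise — not clinical
performance.

## Metrics

PSNR = 20 log₁₀(peak/RMSE) with peak = max(reference); identical images
report +∞ rather than erroring so metric sweeps stay total. SSIM uses the
standard windowed 3-D computation (7³ windows), with the stabilizing
constants derived from the joint min/max range of the two inputs — derived
from the pair rather than one image so the metric stays symmetric in its
arguments; 4-D data are scored per volume and averaged. Both metrics are
invariant to a common positive rescaling of both inputs. RMSE maps reduce
over the volume dimension; residual maps are the plain difference
noisy − denoised (structure visible there indicates structure was removed).

## Numerical notes and limitations

- Everything is float64; no unseeded randomness exists anywhere, and repeated
  runs are bit-identical (including across worker counts).
- The graph for a patch shape is cached and reused; memory per patch batch is
  O(edges + nodes × patches).
- Degenerate inputs: single-node graphs and λ = 0 return the input signal;
  empty patches, non-unit directions at b > 0, negative σ and mismatched
  lengths raise errors rather than guessing.
- `angular_k` is clamped to the number of available directions in the
  pipeline so few-direction data remain usable.
- The solver is first-order: for very large λ or very tight tolerances it
  needs many iterations; the defaults (ε = 10⁻³, N = 200) favor throughput.
- Runtime scales linearly in patches × iterations × edges; a 16³ volume with
  31 volumes denoises in roughly 10–15 s on one CPU.
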