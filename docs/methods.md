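# Methods

## The imaging model

A multicore fiber feeding a photonic lantern projects one multimode light
pattern per excited core onto the object; a single-pixel detector records
the total returned light. With `M` patterns stacked as the rows of
`Φ ∈ R^{M×N}` and the vectorized object `x̄ ∈ R^N`, the measurements are

    y = Φ x̄ + w,      ‖w‖₂ ≤ ε,

with noise known only through its energy bound. The reference instrument
has 121 single-mode cores in an 11×11 array; rotating the fiber nine times
by 40° about the optical axis multiplies the pattern count to 1,089. We
treat the inverse problem in Morozov (constrained) form — data fidelity as
the constraint `‖Φx − y‖ ≤ ε` — which makes ε the only data-fit
hyperparameter and ties it directly to the noise level.

### Synthetic patterns

The package does not simulate optics. Each core's pattern is the squared
magnitude of a complex Gaussian random field low-pass filtered at a
`correlation_length` of 2 px (the speckle grain), weighted by a broad
Gaussian envelope centred on the core's position; rotated copies use
bilinear interpolation about the image centre with zero padding. This
reproduces the statistical features that matter for the reconstruction
problem — nonnegative, speckle-like, mutually weakly correlated rows —
without any mode-propagation physics. Patterns are normalized to unit
energy by default (`normalization="energy"`); the raw-intensity convention
is available since the physical normalization of measured patterns is
instrument-specific.

What the generator does **not** emulate: core-to-core crosstalk, bending
deformation between calibration and acquisition, detector nonlinearity,
and the true modal structure of lantern outputs. Tests passing on these
synthetic patterns therefore validate the algorithms, not instrument
robustness.

### Simulated noise

`simulate_measurements` draws i.i.d. Gaussian noise and rescales the
realization so the input SNR `20·log₁₀(‖Φx̄‖/‖w‖)` is hit exactly (default
30 dB). The default ε is the realized `‖w‖₂` — the oracle bound — so the
constraint set always contains the truth; a χ²-based bound
`ε = σ√(M + 2√(2M))` is provided for the unknown-realization case.

## Variational route: SARA

The sparsity-averaging prior measures the image in the concatenation
`Ψ ∈ R^{9N×N}` of the first eight orthonormal Daubechies bases (db1–db8,
decimated, periodic boundary, 4 decomposition levels) and the Dirac basis,
each scaled by 1/3 so that `ΨᵀΨ = Id` (Parseval frame, `S = 9N`). The
log-sum prior `Σ_s log(|v_s| + α)` is handled by majorize–minimize: a
sequence of weighted problems

    min_{x ≥ 0} ‖Δ Ψ x‖₁   s.t.  ‖Φx − y‖₂ ≤ ε,

with weights `δ_s = α/(α + |v̂_s|) ∈ (0,1]` refreshed from the current
coefficients. α defaults to the largest coefficient magnitude of the first
(unweighted) solution and decays by a factor 0.5 per reweight, floored at
the coefficient-domain noise scale `ε/√S`; 5 reweights, warm-started.

Each weighted problem is solved by Condat–Vũ primal–dual splitting with
two dual blocks (Ψ- and Φ-images), primal prox = nonnegativity projection,
dual proxes by Moreau decomposition of the weighted soft-threshold and of
the ε-ball projection. The stacked operator norm satisfies
`‖[Φ;Ψ]‖² ≤ ‖Φ‖² + 1`, and steps are chosen as
`τ = σ = √safety / ‖L‖` with safety 0.99, which enforces the convergence
condition `τσ‖L‖² < 1`. Stopping: relative change of the full primal–dual
iterate (max over the primal and dual blocks — the primal alone can stall
at 0 while a thresholding prox holds it there) below `rel_tol` (default
1e−5, simulations) or `max_iter` (default 5,000).

For images up to 32×32 the frame is materialized as a dense matrix
(`densify`), which is substantially faster inside iterative solvers than
repeated wavelet transforms; the operator form is used at larger sizes.

## Plug-and-play route

The regularizer's proximity step is replaced by a learned denoiser
`J = (Id + Q)/2`. When Q is 1-Lipschitz, J is firmly nonexpansive and is
exactly the resolvent of a maximally monotone operator `B = J⁻¹ − Id`.
The iteration

    x̃ₖ = xₖ − τ Φᵀuₖ
    xₖ₊₁ = J(x̃ₖ)
    ũₖ = uₖ + σ Φ(2xₖ₊₁ − xₖ)
    uₖ₊₁ = ũₖ − σ proj_{B₂(y,ε)}(ũₖ/σ)

converges for `τσ‖Φ‖² < 1` to a point satisfying

    0 ∈ Φᵀ N_{B₂(y,ε)}(Φx̂) + τ⁻¹ B(x̂),

so the primal step τ rescales the learned regularizer and is in general
part of the model. One consequence specific to the Morozov form is worth
stating: because `Φᵀ N_{B₂(y,ε)}(Φx)` is a cone (closed under positive
scaling), multiplying the inclusion by τ absorbs the τ⁻¹ factor, so the
solution set is actually τ-invariant for *constraint-type* data terms —
τ shapes the trajectory and convergence speed, not the limit. (With a
smooth or penalty-type data term this invariance disappears, which is the
regime where the τ-rescaling of B matters; the `(t, τ) → (2t, 2τ)`
invariance of the soft-threshold instance is verified in the tests.)
`check_inclusion_residual` certifies a returned point numerically via
`‖x̂ − J(x̂ − τΦᵀû)‖ / max(1, ‖x̂‖)`.

Design notes:

* The dual update is the standard Moreau decomposition of the ε-ball
  indicator — the unique choice under which the identity denoiser reduces
  the scheme to the pure feasibility problem (a useful sanity limit).
* No nonnegativity projection is applied inside the loop: composing two
  resolvents has no monotone-operator interpretation. A display clamp is
  applied only when computing metrics, and is recorded in reports.
* Initialization is `x₀ = 0, u₀ = 0`; stopping as in the SARA solver.

## Denoiser: architecture, training, certification

Q is parameterized as `Q(z) = z − N(z)` with N a compact DnCNN-style
stack: 4 convolution layers (3×3, zero padding), 16 features, ReLU
activations, operating on grey levels in [0, 255]. The network is
implemented directly in numpy with hand-written forward, backward, and
forward/reverse directional derivatives (JVP/VJP); the 3×3 gathers are
numba-compiled and the GEMMs go through BLAS. This keeps the Jacobian
machinery self-contained and fast enough for CPU training. Training
computes in float32; every certificate is evaluated on a float64 copy of
the weights.

Training pairs are `(x̄ᵢ, zᵢ = x̄ᵢ + υ wᵢ)` with standard-normal `wᵢ` and
noise level υ = 10 grey levels by default (υ ∈ {5, 10, 20} supported).
The loss per sample is

    ‖J(zᵢ) − x̄ᵢ‖²/n_pix + λ · max(‖∇Q(zᵢ)‖_S², 1 − δ),      δ = 0.05,

i.e. a per-pixel mean data term plus a hinged Jacobian spectral-norm
penalty that only pushes once `‖∇Q‖_S² > 1 − δ`. The spectral norm is
computed by a power method on `∇Qᵀ∇Q` (10 iterations during training, 50
for certification) whose JVP/VJP passes are differentiated with respect to
the weights at the converged singular vector (the eigenvector's own
θ-dependence is second order). To keep CPU steps cheap the penalty term is
evaluated on a random half of each mini-batch — an unbiased estimator of
the same empirical objective. Optimizer: Adam, lr 1e−3, batch 25, 5
epochs over 2,000 synthetic 32×32 patches.

λ is selected by doubling until the held-out maximum `‖∇Q(z)‖_S` is ≤ 1:
with the per-pixel mean data term the natural starting weight is of order
1 (equivalently, 1e−3 per pixel of a 32×32 patch under a summed loss);
each doubling round fine-tunes for one epoch from the
previous weights, screened by a quick float32 sweep (64 held-out patches,
30 power iterations), with the full float64 certificate (200 patches, 50
iterations) recorded whenever the screen passes. The final spec stores
the λ schedule, the certified held-out maximum, and the FNE pairwise check
(`‖J(x)−J(y)‖² ≤ ⟨x−y, J(x)−J(y)⟩ + 1e−8` on 10⁴ seeded pairs drawn near
the training distribution).

The training corpus is synthetic — smoothed Gaussian fields, geometric
shapes, oriented gratings — so certified Lipschitz behaviour is only
guaranteed near that distribution; this is the same locality caveat as in
any penalty-based (non-architectural) Lipschitz control. Training on a
natural-image corpus is a config change, not a code change.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is bitwise-deterministic per seed.
* Operator norms come from power iteration on `ΦᵀΦ` (relative tolerance
  1e−9, ≤ 500 iterations), validated against dense SVD in tests.
* `ε ≥ ‖y‖` makes x = 0 feasible and optimal for the sparsity objective;
  solvers return it quickly. ε must be strictly positive; noiseless data
  uses a tiny explicit bound.
* Division guards use `max(‖·‖, 1e−300)`; relative iterate change is
  measured against the previous iterate's norm.
* The iterate-change stop can trigger while the data residual still sits
  slightly outside the ε-ball (primal stalls before dual feasibility on
  near-tangent instances); `SolverConfig.feas_tol` optionally defers
  stopping until `‖Φx−y‖ ≤ ε(1+feas_tol)` as well. The `converged` flag
  always demands feasibility to `ε(1+1e−6)`.
* The ADMM reference solver (tests only) solves the identical problems by
  consensus splitting with an exact Cholesky x-update; it is kept dense
  and small (N ≤ 400) by design.

## Desk-scale problem sizes

The package's test and acceptance runs use 16×16 images with M = 64
patterns for oracle comparisons, and 64×64 images with M = 576 patterns
(8×8 core grid × 9 rotations, 14% sampling) for the SARA-vs-PnP
comparison on 10 geometric phantoms; denoiser training uses 2,000 32×32
patches. These sizes preserve every structural property of the method —
constraint geometry, frame redundancy, resolvent calculus — at a scale a
single CPU core handles in minutes. Headline numbers from full-scale
(377×377, ImageNet-trained, GPU) experiments are out of scope and are not
claimed or reproduced.

A consequence of the desk scale should be stated plainly: on piecewise-
constant geometric phantoms — which are exactly sparse in the SARA frame,
and where SARA's in-loop nonnegativity is a strong extra prior — the
compact 4-layer denoiser does not overtake the variational solver; the
acceptance script reports both mean PSNRs so the ordering and its
magnitude are visible. Overtaking it at full scale requires the much
larger denoiser and natural-image training corpus that are out of scope
here.

## Known limitations

* Bilinear rotation with zero padding loses mass near corners; rotated
  patterns are exact only up to interpolation error (tested < 5% on
  smooth compactly supported fields).
* The power-method spectral norm is a lower bound at finite iteration
  count; certification uses 50 iterations in float64, and the hinge margin
  δ = 0.05 provides slack against this bias.
* Lipschitz certification is empirical (held-out sweep), not a global
  architectural guarantee.
* The reweighted-ℓ1 outer loop has no global convergence theory; the
  per-subproblem primal-dual solves do.
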