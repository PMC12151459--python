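# Methods

## Model and assumptions

The package infers a gene regulatory network A (N×N, signed, weighted;
entry (i, j) is the effect of regulator j on target i, edges run columns →
rows everywhere in the code and file formats) from steady-state
perturbation data. The modelling assumptions are:

- the system is observed near steady state, so the nonlinear dynamics are
  adequately described by their linearization dỹ/dt = Aỹ + p̃, giving the
  measurement model Y = −A⁻¹P + E;
- the perturbation design P is known (here: single-gene knockdowns, one
  column per gene per replicate, fold-change magnitude −1 on the diagonal
  of each replicate block — the scale is arbitrary in a linear model);
- measurement noise is additive, i.i.d. Gaussian, homoscedastic across
  genes and experiments;
- A is sparse: most candidate links do not exist.

Inference is row-decoupled: with H = −Yᵀ (M×N, M = r·N measurements), row a
of A solves p = Ha + e independently of the other rows. Each row problem is
a sparse Bayesian linear model: independent zero-mean Gaussian priors with
per-link precisions α, Gaussian noise with precision β, exact Gaussian
posterior N(μ, Σ) with Σ = (diag(α) + βHᵀH)⁻¹ and μ = βΣHᵀp, and type-2
maximum-likelihood (evidence) updates

    γ_n = 1 − α_n Σ_nn,  α_n ← γ_n/μ_n²,  1/β ← ‖p − Hμ‖²/(M − Σγ_n).

The identity matrix in the likelihood and the evidence covariance
C = β⁻¹I + H diag(α)⁻¹Hᵀ has dimension M (the measurement count), which
coincides with N in the common one-replicate square case; the denominator
of the β update is likewise M. The full network posterior stacks the N row
posteriors; the point estimate is the mean matrix, and the per-link
marginal variances are reported alongside it.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_iter` | 35 | learning iterations per row; the method's only real knob. 10–50 is a sensible range — larger networks benefit from more iterations; results in this package use 35. |
| `tol` | off | optional early stop on max \|Δ ln α\| < tol; off by default so runs use the fixed budget. |
| α cap / floor | 1e12 / 1e-12 | precision bounds. A link whose μ underflows jumps to the cap (soft pruning); capped links are kept in Σ rather than removed, so the posterior bookkeeping stays exact. β shares the 1e12 cap (on noiseless data the residual underflows). |
| `SimulationConfig.snr` | 1.0 | target signal-to-noise ratio; benchmark levels are 1, 0.1, 0.01. |
| `avg_links_per_gene` | 3.0 | exact off-diagonal link count round(avg·N); 3/gene reflects typical biological sparsity (the density analysis uses 5/gene). |
| `confidence_level` | 0.05 | chi-square confidence in the SNR definition. |
| `weight_low`/`weight_high` | 0.1 / 1.0 | link magnitude range, random sign; diagonal fixed at −1 (self-degradation). |

## Initialization

α starts at 1 for every link. β starts at the data-driven relevance-vector-
machine convention β₀ = 1/(0.1·var(p)) — the noise variance is provisionally
guessed at a tenth of the response variance. This choice is load-bearing:
starting β far below the response scale (e.g. β₀ = 1 when var(p) ≈ 1/N)
lets the prior prune well-supported links in the first iterations, and the
evidence ascent then stalls in a poor local optimum on low-noise data
(observed on the majority of noiseless 10-gene instances, where recovery
error jumped from ~1e-11 to order 0.5). On noisy data the two starts give
statistically indistinguishable accuracy.

Update ordering per iteration: posterior at the current hyperparameters
(recording the evidence), then the hyperparameter re-estimates. With
`max_iter = 1` the result is exactly one posterior at the initial
hyperparameters plus one hyperparameter update.

## Numerical choices

- Σ is obtained from a symmetric-positive-definite Cholesky solve with
  escalating diagonal jitter (1e-12, ×10, up to 1e-6) before a failure is
  declared; Σ is re-symmetrized after the solve.
- γ is clipped to [0, 1]: finite-precision solves can push α_nΣ_nn slightly
  past 1, which would otherwise yield a negative precision. The clip is
  inactive at interior fixed points (verified by the stationarity tests).
- If the β-update denominator M − Σγ is not positive (near-interpolation),
  β keeps its previous value and a warning is logged.
- The evidence is evaluated through the M×M covariance C directly; the
  Woodbury/determinant-lemma N×N route exists in the test suite as an
  independent oracle (agreement to 1e-8).
- Evaluation ranks on |weight| with truth binarized at exactly zero; ties
  are admitted simultaneously in the sweep and midranked in the AUROC, so
  the rank-formula AUROC equals the sweep trapezoid exactly. Self-loops
  (diagonal) are excluded by default, as they are comparatively easy to
  predict. Signed evaluation (a sign-mismatched detection counts as a false
  positive) is available behind a flag, off by default since unsigned
  ranking is the common denominator across methods.
- Density comparison: both weight samples are min-max normalized with the
  *true* network's min/max and shifted back to their own pre-normalization
  mean; Gaussian KDEs (Silverman bandwidth) are compared by L1 distance on
  a shared 512-point grid spanning both supports ± 3 bandwidths.

## Synthetic data: what it does and does not emulate

`simulator` generates directed scale-free topologies by preferential
attachment (regulators drawn proportionally to current out-degree, so hub
regulators emerge), exact link counts round(avg·N), uniform link magnitudes
in [0.1, 1] with random sign, diagonal −1, and enforces dynamical stability
(all eigenvalue real parts < 0) and invertibility (σ_min > 1e-6) by damping
the off-diagonal part by 0.9 until both hold. Noise is calibrated to the
target SNR on the noise-free response Y₀ (using the noisy Y would be
circular at generation time); the SNR definition is
σ_min/√(λ·q) with q the (1−0.05) chi-square quantile at N·M degrees of
freedom. A single integer seed drives three independent substreams
(topology, weights, noise), so every artefact is bit-reproducible.

Not emulated: kinetic/nonlinear simulation (GeneNetWeaver-style),
time-series data, correlated or heteroscedastic noise, indirect or combined
perturbations, and missing perturbation knowledge. Passing benchmarks here
therefore demonstrates correctness and robustness *within* the linear
steady-state, known-design regime; they do not certify performance on real
expression data, where model mismatch dominates.

## Baselines

- **LSCO** (least squares): minimum-norm pseudo-inverse solution per row;
  thresholding is deferred to the evaluation sweep. The normalized LSCON
  variant is out of scope.
- **Zscore**: each gene's expression row standardized by its population
  mean/sd across all experiments; weight(i, j) is gene i's mean
  standardized response over experiments perturbing gene j. (Knockdown
  z-score definitions vary in the literature; this convention is fixed
  for testability.)
- **LASSO**: per-row ℓ₁ regression minimizing ½‖p − Ha‖² + λ‖a‖₁ via
  scikit-learn coordinate descent; λ chosen per row by seeded 5-fold CV
  over a grid (fallback: fixed first grid value when the data are too
  small to fold). λ = 0 falls back to the pseudo-inverse.

GENIE3 and SVM-based inference are external tools' contributions and are
not reimplemented.

## Problem sizes used in the checks

The simulated benchmark in the acceptance tests uses 10 networks of 50
genes at SNR 1 and 0.1 with one replicate (the full study grid — 20
networks and three SNR levels — is the `BenchmarkSpec` default and runs in
a few minutes); oracle-agreement checks use 100 random row problems with
N ≤ 8; stationarity checks use 20 row problems run to convergence. The
density analysis uses one 50-gene network at 5 links/gene, SNR 0.1, one
replicate.

## Known limitations

- Evidence maximization is non-convex; the iteration can end in local
  optima, and the evidence trace is not guaranteed monotone (empirically it
  rises on essentially all tested problems).
- At SNR 0.01 no method, this one included, beats chance meaningfully —
  consistent with the noise swamping σ_min-scaled signal.
- Homoscedastic noise is assumed across genes; real data violate this.
- The β update assumes M > Σγ; exactly interpolating systems rely on the
  keep-previous-β fallback and the 1e12 cap.
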