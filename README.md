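# bigsm

Sparse Bayesian inference of gene regulatory networks (GRNs) from
perturbation-design expression data, with closed-form per-link posterior
distributions, plus everything needed to benchmark it end to end with no
external data: a GeneSPIDER-style synthetic data generator, baseline
comparator methods (least squares, knockdown z-score, LASSO), and a
threshold-sweep evaluation suite (AUPR, AUROC, maximum F1, weight-density
comparison).

## The problem and the model

A GRN over N genes is a sparse, signed, weighted adjacency matrix
A ∈ ℝ^(N×N): A\_ij is the regulatory effect of gene j (regulator, column) on
gene i (target, row). Near steady state the dynamics linearize to
dỹ/dt = Aỹ + p̃, so a panel of single-gene knockdown experiments with
perturbation matrix P and measured fold changes Y obeys

    Y = −A⁻¹P + E,

with E i.i.d. Gaussian measurement noise. Inference decouples over rows of
A: with H = −Yᵀ, each row a satisfies p = Ha + e.

Each row is treated as a sparse Bayesian linear model in the relevance
vector machine family. Every candidate link a\_n gets a zero-mean Gaussian
prior with its own precision α\_n; the noise has precision β. At fixed
hyperparameters the posterior is Gaussian:

    Σ = (diag(α) + βHᵀH)⁻¹,   μ = βΣHᵀp,

and (α, β) are learned by type-2 maximum likelihood (evidence
approximation) with the classic re-estimates

    γ_n = 1 − α_n Σ_nn,   α_n ← γ_n/μ_n²,   1/β ← ‖p − Hμ‖² / (M − Σ_n γ_n).

Links the data do not support have α\_n driven to a large cap, pinning their
posterior sharply at zero — the inferred network is sparse by construction,
and the per-link posterior variance quantifies the confidence of every
prediction. The point-estimate network is the stacked posterior means.

The simulator calibrates noise to a target signal-to-noise ratio defined
through the smallest singular value of the response matrix:
SNR = σ\_min(Y₀)/√(λ·q), where λ is the noise variance and q is the upper
chi-square quantile (confidence 0.05) with N·M degrees of freedom.

## Worked example

```python
import numpy as np
from bigsm import SimulationConfig, simulate_dataset, infer_grn, evaluate

config = SimulationConfig(n_genes=50, avg_links_per_gene=3.0, snr=0.1, seed=1)
network, design, data = simulate_dataset(config)
print(f"true network: {network.n_links} links, noise variance {data.noise_variance:.3e}")

posterior = infer_grn(data.Y, design.values, max_iter=35)
result = evaluate(posterior.mean, network)          # self-loops excluded
print(f"AUROC {result.auroc:.3f}  AUPR {result.aupr:.3f}  max F1 {result.max_f1:.3f}")

off = ~np.eye(50, dtype=bool)
links = (network.weights != 0) & off
print(f"mean posterior sd: non-links {np.sqrt(posterior.variance[~links & off]).mean():.4f}, "
      f"links {np.sqrt(posterior.variance[links]).mean():.4f}")
```

prints

```
true network: 150 links, noise variance 5.474e-03
AUROC 0.874  AUPR 0.634  max F1 0.622
mean posterior sd: non-links 0.0124, links 0.0295
```

A 50-gene network with 150 regulatory links was simulated at a noisy
setting (SNR 0.1, one replicate per knockdown). Ranking candidate links by
the absolute posterior mean recovers the true topology far above chance
(AUROC 0.874 vs 0.5), and true non-links carry visibly sharper posteriors
(smaller standard deviation) than true links — the Bayesian output
separates confident zeros from genuine edges.

The same pipeline is scriptable from the shell:

```sh
bigsm simulate --n-genes 50 --snr 0.1 --seed 1 --out bundle/
bigsm infer --expression bundle/expression.tsv --perturbation bundle/perturbation.tsv \
            --method bigsm --out inferred/
bigsm evaluate --prediction inferred/network.tsv --truth bundle/network.tsv
bigsm benchmark --spec spec.yaml --out results.tsv
```

All files are labelled TSV matrices (or a `regulator⟨TAB⟩target⟨TAB⟩weight`
edge list for gold standards); values round-trip bit-exactly.

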