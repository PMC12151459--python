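"""Synthetic gene-regulatory-network benchmark generation.

Emulates the GeneSPIDER simulation protocol: a sparse, scale-free,
dynamically stable network ``A`` (N x N, regulator on the column, target on
the row), a single-gene knockdown perturbation design ``P``, the noise-free
steady-state fold-change response ``Y0 = -A^-1 P`` of the linearized
dynamics ``dy/dt = A y + p``, and additive i.i.d. Gaussian measurement
noise whose variance is calibrated so the dataset attains a requested
signal-to-noise ratio

    SNR = sigma_min(Y0) / sqrt(lambda * q),

where ``lambda`` is the noise variance and ``q`` is the upper chi-square
quantile at the configured confidence level with N*M degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GRNMatrix",
    "PerturbationDesign",
    "ExpressionDataset",
    "SimulationConfig",
    "ConfigError",
    "GenerationError",
    "SingularMatrixError",
    "generate_network",
    "make_knockdown_design",
    "steady_state_response",
    "snr_from_noise_variance",
    "noise_variance_for_snr",
    "simulate_dataset",
]

#: smallest singular value below which a network is treated as singular
SINGULARITY_TOL = 1e-6


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """Network generation failed to reach a stable, invertible matrix."""


class SingularMatrixError(np.linalg.LinAlgError):
    """The network matrix is numerically singular."""


def default_gene_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


@dataclass
class GRNMatrix:
    """Signed, weighted adjacency matrix of a gene regulatory network.

    ``weights[i, j]`` is the regulatory effect of gene ``j`` (regulator,
    column) on gene ``i`` (target, row); edges run columns -> rows.
    """

    weights: np.ndarray
    gene_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"adjacency matrix must be square, got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("adjacency matrix contains non-finite entries")
        if self.gene_names is None:
            self.gene_names = default_gene_names(self.weights.shape[0])
        if len(self.gene_names) != self.weights.shape[0]:
            raise ValueError("gene_names length does not match matrix size")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("duplicate gene names")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_links(self) -> int:
        """Number of off-diagonal nonzero entries."""
        off = self.weights.copy()
        np.fill_diagonal(off, 0.0)
        return int(np.count_nonzero(off))

    def smallest_singular_value(self) -> float:
        return float(np.linalg.svd(self.weights, compute_uv=False)[-1])

    def is_stable(self) -> bool:
        """All eigenvalues in the open left half-plane (stable dynamics)."""
        return bool(np.all(np.linalg.eigvals(self.weights).real < 0.0))


@dataclass
class PerturbationDesign:
    """Perturbation design matrix P (N x r*N), fold-change scale.

    Each block of N columns holds one experiment per gene, with the
    perturbation on the block diagonal (single-gene knockdowns).
    """

    values: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if self.replicates < 1 or m != self.replicates * n:
            raise ValueError(
                f"design shape {self.values.shape} inconsistent with replicates={self.replicates}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionDataset:
    """Measured fold-change matrix Y with its simulation metadata."""

    Y: np.ndarray
    snr_target: float
    noise_variance: float
    seed: int
    replicates: int = 1

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if math.isfinite(self.snr_target) and not self.noise_variance > 0:
            raise ValueError("noise_variance must be positive for finite SNR")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic benchmark.

    Defaults mirror the main benchmark conditions: 50 genes, an average of
    three regulatory links per gene, single knockdown per gene with one
    technical replicate, and chi-square confidence level 0.05 in the SNR
    definition.
    """

    n_genes: int = 50
    avg_links_per_gene: float = 3.0
    snr: float = 1.0
    replicates: int = 1
    seed: int = 0
    weight_low: float = 0.1
    weight_high: float = 1.0
    confidence_level: float = 0.05

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.avg_links_per_gene < 0:
            raise ConfigError("avg_links_per_gene must be >= 0")
        if round(self.avg_links_per_gene * self.n_genes) > self.n_genes * (self.n_genes - 1):
            raise ConfigError(
                f"requested {round(self.avg_links_per_gene * self.n_genes)} links exceeds "
                f"the {self.n_genes * (self.n_genes - 1)} available off-diagonal entries"
            )
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        if not (0.0 < self.confidence_level < 1.0):
            raise ConfigError("confidence_level must lie in (0, 1)")
        if not (0.0 < self.weight_low <= self.weight_high):
            raise ConfigError("need 0 < weight_low <= weight_high")


def _stream(seed: int, key: int) -> np.random.Generator:
    """Independent named substream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


_TOPOLOGY, _WEIGHTS, _NOISE = 0, 1, 2


def _preferential_edges(n: int, n_links: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw ``n_links`` distinct directed off-diagonal edges (target, regulator).

    Regulators are chosen with probability proportional to (current
    out-degree + 1) so a few hub regulators accumulate many targets — a
    heavy-tailed degree distribution in the spirit of preferential
    attachment; targets are chosen uniformly.
    """
    edges: set[tuple[int, int]] = set()
    out_degree = np.ones(n)  # +1 smoothing so every gene can seed a hub
    stall = 0
    while len(edges) < n_links and stall < 50 * n_links + 1000:
        target = int(rng.integers(n))
        weight_vec = out_degree.copy()
        weight_vec[target] = 0.0
        regulator = int(rng.choice(n, p=weight_vec / weight_vec.sum()))
        if (target, regulator) in edges:
            stall += 1
            continue
        edges.add((target, regulator))
        out_degree[regulator] += 1.0
    if len(edges) < n_links:
        # dense regime: fill from the remaining free slots uniformly
        free = [
            (i, j)
            for i in range(n)
            for j in range(n)
            if i != j and (i, j) not in edges
        ]
        idx = rng.choice(len(free), size=n_links - len(edges), replace=False)
        edges.update(free[k] for k in idx)
    return sorted(edges)


def generate_network(config: SimulationConfig) -> GRNMatrix:
    """Generate a sparse, scale-free, stable ground-truth network.

    Exactly ``round(avg_links_per_gene * n_genes)`` off-diagonal entries are
    nonzero; link magnitudes are uniform on [weight_low, weight_high] with
    random sign and the diagonal is -1 (self-degradation). If the matrix is
    unstable or near-singular the off-diagonal part is damped by 0.9 until
    both invariants hold (at most 50 dampings per candidate, with fresh
    topology redraws before giving up).
    """
    config.validate()
    n = config.n_genes
    n_links = int(round(config.avg_links_per_gene * n))
    top_rng = _stream(config.seed, _TOPOLOGY)
    w_rng = _stream(config.seed, _WEIGHTS)

    for _attempt in range(20):
        A = np.zeros((n, n))
        if n_links:
            edges = _preferential_edges(n, n_links, top_rng)
            rows, cols = zip(*edges)
            magnitudes = w_rng.uniform(config.weight_low, config.weight_high, size=n_links)
            signs = w_rng.choice([-1.0, 1.0], size=n_links)
            A[rows, cols] = magnitudes * signs
        np.fill_diagonal(A, -1.0)

        for _damping in range(51):
            net = GRNMatrix(A.copy())
            if net.is_stable() and net.smallest_singular_value() > SINGULARITY_TOL:
                return net
            off = A - np.diag(np.diag(A))
            A = 0.9 * off + np.diag(np.diag(A))
    raise GenerationError(
        f"no stable invertible network after 20 redraws (seed={config.seed})"
    )


def make_knockdown_design(
    n_genes: int, replicates: int = 1, magnitude: float = -1.0
) -> PerturbationDesign:
    """Single-gene knockdown design: r horizontal copies of magnitude * I."""
    if n_genes < 1 or replicates < 1:
        raise ConfigError("n_genes and replicates must be >= 1")
    if magnitude == 0:
        raise ConfigError("perturbation magnitude must be nonzero")
    block = magnitude * np.eye(n_genes)
    return PerturbationDesign(np.hstack([block] * replicates), replicates=replicates)


def steady_state_response(A: GRNMatrix | np.ndarray, P: PerturbationDesign | np.ndarray) -> np.ndarray:
    """Noise-free steady-state fold-change response Y0 = -A^-1 P."""
    Aw = A.weights if isinstance(A, GRNMatrix) else np.asarray(A, dtype=float)
    Pv = P.values if isinstance(P, PerturbationDesign) else np.asarray(P, dtype=float)
    if Pv.shape[0] != Aw.shape[0]:
        raise ValueError(f"P has {Pv.shape[0]} rows but A is {Aw.shape[0]}x{Aw.shape[1]}")
    smin = float(np.linalg.svd(Aw, compute_uv=False)[-1])
    if smin <= SINGULARITY_TOL:
        raise SingularMatrixError(
            f"network matrix is numerically singular (smallest singular value {smin:.3e})"
        )
    return -np.linalg.solve(Aw, Pv)


def _chi2_quantile(confidence_level: float, dof: int) -> float:
    return float(stats.chi2.ppf(1.0 - confidence_level, dof))


def snr_from_noise_variance(
    Y: np.ndarray, noise_variance: float, confidence_level: float = 0.05
) -> float:
    """SNR of an expression matrix at a given noise variance.

    SNR = sigma_min(Y) / sqrt(lambda * q) with q the (1 - confidence_level)
    chi-square quantile at N*M degrees of freedom.
    """
    if not noise_variance > 0:
        raise ValueError("noise_variance must be positive")
    if not (0.0 < confidence_level < 1.0):
        raise ValueError("confidence_level must lie in (0, 1)")
    Y = np.asarray(Y, dtype=float)
    smin = float(np.linalg.svd(Y, compute_uv=False)[-1])
    q = _chi2_quantile(confidence_level, Y.size)
    return smin / math.sqrt(noise_variance * q)


def noise_variance_for_snr(
    Y0: np.ndarray, snr_target: float, confidence_level: float = 0.05
) -> float:
    """Noise variance lambda that calibrates Y0 to the target SNR.

    Inverts the SNR definition: lambda = sigma_min(Y0)^2 / (snr^2 * q).
    """
    if not snr_target > 0:
        raise ValueError("snr_target must be positive")
    Y0 = np.asarray(Y0, dtype=float)
    smin = float(np.linalg.svd(Y0, compute_uv=False)[-1])
    if smin <= 0.0:
        raise ValueError("response matrix is degenerate (smallest singular value is 0)")
    q = _chi2_quantile(confidence_level, Y0.size)
    return smin**2 / (snr_target**2 * q)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GRNMatrix, PerturbationDesign, ExpressionDataset]:
    """Full benchmark instance: network, knockdown design, noisy expression.

    Y = -A^-1 P + E with E i.i.d. N(0, lambda), lambda calibrated to
    ``config.snr`` on the noise-free response. ``config.snr = inf`` disables
    the noise entirely. Same seed, same bytes.
    """
    config.validate()
    net = generate_network(config)
    design = make_knockdown_design(config.n_genes, config.replicates)
    Y0 = steady_state_response(net, design)
    if math.isinf(config.snr):
        lam = 0.0
        Y = Y0.copy()
    else:
        lam = noise_variance_for_snr(Y0, config.snr, config.confidence_level)
        noise = _stream(config.seed, _NOISE).normal(0.0, math.sqrt(lam), size=Y0.shape)
        Y = Y0 + noise
    data = ExpressionDataset(
        Y=Y,
        snr_target=config.snr,
        noise_variance=lam if lam > 0 else float("nan"),
        seed=config.seed,
        replicates=config.replicates,
    )
    return net, design, data
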