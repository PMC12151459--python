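import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---- independent oracles (dense, brute-force routes kept deliberately
# ---- different from the package's solver paths) ----------------------


def posterior_oracle(H, p, alpha, beta):
    """Posterior of a Bayesian linear model by conditioning the joint
    Gaussian of (a, p) with explicit dense inversion."""
    H = np.asarray(H, float)
    lam_inv = np.diag(1.0 / np.asarray(alpha, float))
    m = H.shape[0]
    C = H @ lam_inv @ H.T + np.eye(m) / beta  # cov(p)
    Cinv = np.linalg.inv(C)
    K = lam_inv @ H.T  # cov(a, p)
    mu = K @ Cinv @ np.asarray(p, float)
    Sigma = lam_inv - K @ Cinv @ K.T
    return mu, Sigma


def log_evidence_woodbury(H, p, alpha, beta):
    """Marginal log-likelihood via the matrix-determinant lemma / Woodbury
    identity (N x N route), independent of the M x M covariance route."""
    H = np.asarray(H, float)
    p = np.asarray(p, float).ravel()
    alpha = np.asarray(alpha, float)
    m = H.shape[0]
    S = np.diag(alpha) + beta * H.T @ H
    _, logdet_s = np.linalg.slogdet(S)
    logdet_c = logdet_s - float(np.sum(np.log(alpha))) - m * np.log(beta)
    Cinv = beta * np.eye(m) - beta**2 * H @ np.linalg.inv(S) @ H.T
    quad = float(p @ Cinv @ p)
    return -0.5 * (m * np.log(2.0 * np.pi) + logdet_c + quad)


def sweep_auroc(scores, labels):
    """Trapezoid area under the ROC sweep (threshold enumeration route)."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels, bool).ravel()
    npos = labels.sum()
    nneg = labels.size - npos
    thresholds = np.unique(scores)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & labels).sum() / npos)
        fpr.append((pred & ~labels).sum() / nneg)
    return float(np.trapezoid(tpr, fpr))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_row_problem(rng, n=5, m=None, noise=0.1):
    """Small random row problem with a sparse true coefficient vector."""
    from bigsm.core import RowProblem

    m = m or n
    H = rng.normal(size=(m, n))
    a_true = np.zeros(n)
    k = max(1, n // 3)
    a_true[rng.choice(n, size=k, replace=False)] = rng.normal(size=k)
    p = H @ a_true + noise * rng.normal(size=m)
    return RowProblem(H, p), a_true
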