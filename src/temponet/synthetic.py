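"""Synthetic ground-truth systems for validating the network inference.

The generator builds a sparse time-varying linear system: K x K transition
matrices with a fixed count of nonzero entries drawn uniformly from
[-1, +1], adjacent matrices differing only by the random perturbation of a
small number of entry positions.  Observations are independent trajectories
(fresh standard-normal initial state, propagated through the true matrices)
with entrywise Gaussian noise whose standard deviation is a fraction of the
local signal magnitude.

Also provides planted-cluster profile data for exercising the consensus
clustering stage, and support/sign/magnitude recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import helmert

from .config import get_logger
from .inference import TransitionSeries

__all__ = [
    "SyntheticProblem",
    "RecoveryMetrics",
    "generate_synthetic",
    "evaluate_recovery",
    "planted_cluster_profiles",
]

logger = get_logger("synthetic")


@dataclass
class SyntheticProblem:
    """A ground-truth sparse linear system with noisy trajectory observations."""

    truth: TransitionSeries
    n_templates: int
    n_times: int
    density: float
    n_perturb: int
    noise_frac: float
    n_samples: int
    seed: int
    observations: np.ndarray  # (n_samples, K, T)
    noiseless: np.ndarray  # (n_samples, K, T) clean trajectories

    def observation_list(self) -> list[np.ndarray]:
        return [self.observations[i] for i in range(self.n_samples)]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Support-recovery and magnitude-error metrics for an estimated series."""

    precision: float
    recall: float
    f1: float
    sign_accuracy: float
    frobenius_rmse: float


def generate_synthetic(
    n_templates: int = 9,
    n_times: int = 4,
    density: float = 0.1,
    n_perturb: int = 10,
    noise_frac: float = 0.1,
    n_samples: int = 20,
    seed: int = 0,
) -> SyntheticProblem:
    """Generate a sparse time-varying linear system and noisy observations.

    The first transition matrix receives exactly ``round(density * K^2)``
    nonzero entries uniform in [-1, +1].  Each later matrix copies its
    predecessor and resamples ``n_perturb`` uniformly chosen entry positions
    (fresh uniform value with probability ``density``, zero otherwise, so the
    expected density is preserved).  Each observation is an independent
    trajectory: initial state ~ N(0, I), propagated through the true
    matrices, plus Gaussian noise with sd ``noise_frac * |clean value|``
    (zero-signal entries use ``noise_frac`` times the trajectory-wide RMS).
    Deterministic given ``seed``.

    When the nonzero budget allows (``nnz >= K``) the sparsity pattern is
    seeded with a random permutation backbone -- one nonzero (magnitude at
    least 0.1) in every row and column, never touched by the perturbation --
    so every truth matrix is nonsingular and the propagated state keeps full
    rank: otherwise a singular transition collapses state dimensions and
    later transitions become unidentifiable even from noiseless data.  The
    densest-regime default (K=9, density 0.1, 8 nonzeros) is below that
    budget and uses plain uniform placement.
    """
    k, t = n_templates, n_times
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    if n_perturb > k * k:
        raise ValueError("n_perturb cannot exceed K^2")
    nnz = int(round(density * k * k))
    if nnz < 1:
        raise ValueError("density * K^2 must round to at least one nonzero entry")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)

    w = np.zeros(k * k)
    if nnz >= k:
        perm = rng.permutation(k)
        backbone = np.ravel_multi_index((np.arange(k), perm), (k, k))
        w[backbone] = rng.choice([-1.0, 1.0], size=k) * rng.uniform(0.1, 1.0, size=k)
        free = np.setdiff1d(np.arange(k * k), backbone)
        extra = rng.choice(free, size=nnz - k, replace=False)
        w[extra] = rng.uniform(-1.0, 1.0, size=nnz - k)
    else:
        backbone = np.empty(0, dtype=int)
        free = np.arange(k * k)
        pos = rng.choice(k * k, size=nnz, replace=False)
        w[pos] = rng.uniform(-1.0, 1.0, size=nnz)
    mats = [w.reshape(k, k).copy()]
    n_pert = min(n_perturb, free.size)
    for _ in range(t - 2):
        w = w.copy()
        pert = rng.choice(free, size=n_pert, replace=False)
        for p in pert:
            w[p] = rng.uniform(-1.0, 1.0) if rng.random() < density else 0.0
        mats.append(w.reshape(k, k).copy())
    truth = TransitionSeries(mats)

    clean = np.empty((n_samples, k, t))
    clean[:, :, 0] = rng.standard_normal((n_samples, k))
    for s in range(t - 1):
        clean[:, :, s + 1] = clean[:, :, s] @ mats[s].T
    obs = clean.copy()
    if noise_frac > 0:
        rms = float(np.sqrt(np.mean(clean**2)))
        sd = noise_frac * np.abs(clean)
        sd[clean == 0] = noise_frac * rms
        obs = clean + rng.standard_normal(clean.shape) * sd
    logger.info(
        "synthetic system: K=%d, T=%d, %d nonzeros/matrix, %d samples, "
        "noise_frac=%g (seed=%d)", k, t, nnz, n_samples, noise_frac, seed,
    )
    return SyntheticProblem(
        truth=truth,
        n_templates=k,
        n_times=t,
        density=density,
        n_perturb=n_perturb,
        noise_frac=noise_frac,
        n_samples=n_samples,
        seed=seed,
        observations=obs,
        noiseless=clean,
    )


def evaluate_recovery(
    truth: TransitionSeries,
    estimate: TransitionSeries,
    threshold: float = 1e-3,
) -> RecoveryMetrics:
    """Score an estimated series against the truth.

    Support is the set of entries with magnitude above ``threshold``.
    Precision is defined as 1 when nothing is predicted; sign accuracy is
    computed over true-positive entries (1 when there are none).
    """
    a = truth.as_array()
    b = estimate.as_array()
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: truth {a.shape} vs estimate {b.shape}")
    true_sup = np.abs(a) > threshold
    est_sup = np.abs(b) > threshold
    tp = int((true_sup & est_sup).sum())
    n_pred = int(est_sup.sum())
    n_true = int(true_sup.sum())
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    mask = true_sup & est_sup
    sign_acc = float(np.mean(np.sign(a[mask]) == np.sign(b[mask]))) if tp else 1.0
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        sign_accuracy=sign_acc,
        frobenius_rmse=rmse,
    )


def planted_cluster_profiles(
    n_clusters: int = 4,
    n_per_cluster: int = 10,
    n_times: int = 4,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Profiles with a planted cluster structure for testing the clustering.

    Cluster centres are the vertices of a regular simplex embedded in the
    zero-mean subspace of R^T and z-scored, so any two centres have Pearson
    correlation exactly -1/(K-1); members are centre + N(0, noise_sd^2)
    perturbations, which keeps within-cluster correlations high for small
    ``noise_sd``.  Requires K <= T.

    Returns ``(profiles, labels)`` with profiles shaped (K*n_per_cluster, T).
    """
    k, t = n_clusters, n_times
    if k > t:
        raise ValueError("planted construction needs n_clusters <= n_times")
    if k < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    # K simplex points in R^{K-1}, embedded into the centered subspace of R^T
    simplex = np.eye(k) - 1.0 / k  # rows: K points, pairwise dot -1/K
    basis = helmert(t)  # (T-1, T) orthonormal rows orthogonal to ones
    coords = np.zeros((k, t - 1))
    coords[:, : k - 1] = simplex @ _simplex_basis(k)
    centres = coords @ basis  # (K, T), zero row means
    centres = (centres - centres.mean(axis=1, keepdims=True)) / centres.std(
        axis=1, keepdims=True
    )
    labels = np.repeat(np.arange(k), n_per_cluster)
    profiles = centres[labels] + rng.standard_normal((k * n_per_cluster, t)) * noise_sd
    return profiles, labels


def _simplex_basis(k: int) -> np.ndarray:
    """Orthonormal basis (k x (k-1)) of the zero-sum subspace of R^k."""
    return helmert(k).T
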