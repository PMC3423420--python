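"""Consensus clustering of temporal profiles into templates.

Profiles are grouped by k-means under the correlation distance
(1 - Pearson correlation between a profile and a centroid).  Stability is
assessed by consensus clustering: many k-means runs on random subsamples of
the transcripts, accumulated into a consensus matrix whose entry (i, j) is
the fraction of co-sampled runs in which i and j landed in the same cluster.
The number of clusters is chosen from the area under the empirical CDF of
consensus values as it changes with the candidate K.

Each cluster's representative temporal profile (its "template") is the
standardized mean of its member profiles; pseudo-replicate matrices for the
downstream regression are built by sampling one member per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import get_logger

__all__ = [
    "ClusterAssignment",
    "ConsensusResult",
    "TemplateMatrix",
    "standardize_rows",
    "kmeans_correlation",
    "consensus_cluster",
    "select_k",
    "build_templates",
    "sample_pseudo_matrices",
]

logger = get_logger("cluster")

_MAX_KMEANS_ITER = 100


def standardize_rows(x: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    """Z-score each row across time (population variance).

    Raises ``ValueError`` naming the offending transcript if a row has zero
    variance, since the correlation distance is undefined there.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        name = ids[flat[0]] if ids is not None else f"row {flat[0]}"
        raise ValueError(f"profile {name} has zero variance across time")
    return (x - mu) / sd


@dataclass
class ClusterAssignment:
    """Cluster labels (0-based) for a set of profiles."""

    labels: np.ndarray
    n_clusters: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.n_clusters)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")
        self.member_counts = counts

    @property
    def n_items(self) -> int:
        return self.labels.size

    def members(self, k: int) -> np.ndarray:
        return np.nonzero(self.labels == k)[0]


@dataclass
class ConsensusResult:
    """Consensus matrices and CDF summaries for a range of candidate K."""

    k_values: list[int]
    consensus: dict[int, np.ndarray]
    co_sampled: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    delta_areas: dict[int, float]

    def cdf(self, k: int, grid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of off-diagonal consensus values for candidate ``k``."""
        vals = _offdiag(self.consensus[k])
        if grid is None:
            grid = np.linspace(0.0, 1.0, 101)
        cdf = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
        return grid, cdf


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangle consensus values."""
    vals = np.sort(_offdiag(consensus))
    n = vals.size
    if n == 0:
        return 0.0
    # CDF is a step function: area = sum over steps of (x_{i+1}-x_i) * F(x_i),
    # with the final segment running to 1.
    xs = np.concatenate(([0.0], vals, [1.0]))
    cdf = np.concatenate(([0.0], np.arange(1, n + 1) / n, [1.0]))
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def _init_centroids(z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(z.shape[0], size=k, replace=False)
    return z[idx].copy()


def kmeans_correlation(
    profiles: np.ndarray,
    n_clusters: int,
    seed: int,
    ids: list[str] | None = None,
) -> ClusterAssignment:
    """Lloyd-style k-means under the correlation distance.

    Rows are z-scored, so 1 - correlation reduces to a monotone function of
    the dot product with a z-scored centroid; centroids are member means
    re-standardized after every update (the usual 'correlation' k-means
    convention).  An emptied cluster is reseeded with the point farthest
    from its current centroid.  Deterministic given ``seed``.
    """
    z = standardize_rows(profiles, ids)
    g, t = z.shape
    if n_clusters < 1 or n_clusters > g:
        raise ValueError(f"need 1 <= K <= {g}, got {n_clusters}")
    rng = np.random.default_rng(seed)
    cent = _init_centroids(z, n_clusters, rng)
    labels = np.full(g, -1)
    for _ in range(_MAX_KMEANS_ITER):
        # correlation(profile, centroid) = dot(z_row, z_centroid) / T
        sim = z @ cent.T
        new_labels = np.argmax(sim, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(n_clusters):
            mask = labels == k
            if not mask.any():
                # reseed with the globally worst-fit point
                worst = int(np.argmin(sim[np.arange(g), labels]))
                labels[worst] = k
                mask = labels == k
            c = z[mask].mean(axis=0)
            sd = c.std()
            if sd == 0:  # degenerate centroid: keep a member instead
                c = z[np.nonzero(mask)[0][0]]
                sd = c.std()
            cent[k] = (c - c.mean()) / sd
    return ClusterAssignment(labels=labels, n_clusters=n_clusters)


def consensus_cluster(
    profiles: np.ndarray,
    k_range: list[int],
    n_runs: int = 1000,
    sample_rate: float = 0.8,
    seed: int = 0,
    ids: list[str] | None = None,
) -> ConsensusResult:
    """Resampled consensus clustering over a range of candidate cluster counts.

    For each candidate K, ``n_runs`` k-means runs are performed on random
    subsamples of the profiles (fraction ``sample_rate``, without
    replacement); the consensus matrix records, for every pair, the fraction
    of runs in which both were sampled and co-clustered.  Run ``r`` for
    candidate K uses seed ``seed + r`` offset by the candidate index so each
    run is individually reproducible.
    """
    if not (0 < sample_rate <= 1):
        raise ValueError("sample_rate must lie in (0, 1]")
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    k_range = sorted(set(int(k) for k in k_range))
    z = standardize_rows(profiles, ids)
    g = z.shape[0]
    n_sub = max(2, int(round(sample_rate * g)))

    consensus: dict[int, np.ndarray] = {}
    co_sampled: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for ki, k in enumerate(k_range):
        together = np.zeros((g, g))
        sampled = np.zeros((g, g))
        base = int((seed + ki * n_runs) % (2**31))
        for r in range(n_runs):
            run_seed = (base + r) % (2**31)
            rng = np.random.default_rng(run_seed)
            idx = np.sort(rng.choice(g, size=n_sub, replace=False))
            sub = z[idx]
            ca = kmeans_correlation(sub, min(k, n_sub), seed=run_seed)
            same = ca.labels[:, None] == ca.labels[None, :]
            sampled[np.ix_(idx, idx)] += 1.0
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
        never = int(np.sum((sampled == 0)[np.triu_indices(g, k=1)]))
        if never:
            logger.warning(
                "K=%d: %d pairs were never co-sampled; their consensus is 0", k, never
            )
        np.fill_diagonal(cons, 1.0)
        consensus[k] = cons
        co_sampled[k] = sampled.astype(int)
        areas[k] = _cdf_area(cons)

    deltas: dict[int, float] = {}
    prev = None
    for k in k_range:
        if prev is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else 0.0
        prev = k
    return ConsensusResult(
        k_values=k_range,
        consensus=consensus,
        co_sampled=co_sampled,
        cdf_areas=areas,
        delta_areas=deltas,
    )


def select_k(cr: ConsensusResult, delta_threshold: float = 0.1) -> int:
    """Pick the cluster count from the consensus-CDF area curve.

    Returns the largest candidate K whose relative area increase Delta(K)
    exceeds ``delta_threshold`` (the first candidate uses its absolute area).
    A flat curve falls back to the smallest candidate with a warning.
    """
    ks = cr.k_values
    if len(ks) == 1:
        return ks[0]
    passing = [k for k in ks[1:] if cr.delta_areas[k] > delta_threshold]
    if not passing:
        logger.warning(
            "consensus CDF area curve is flat (no Delta(K) > %g); "
            "falling back to K=%d", delta_threshold, ks[0],
        )
        return ks[0]
    return max(passing)


@dataclass
class TemplateMatrix:
    """K standardized template profiles over T time points (the V matrix)."""

    values: np.ndarray  # (K, T)
    template_ids: list[str]
    time_points: np.ndarray
    membership: ClusterAssignment | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time_points = np.asarray(self.time_points, dtype=float)
        if self.values.shape != (len(self.template_ids), len(self.time_points)):
            raise ValueError("template matrix shape mismatch")

    @property
    def n_templates(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:g}h" for t in self.time_points]
        return pd.DataFrame(self.values, index=self.template_ids, columns=cols)


def build_templates(
    profiles: np.ndarray,
    assignment: ClusterAssignment,
    time_points: np.ndarray | None = None,
) -> TemplateMatrix:
    """Average each cluster's member profiles and standardize across time."""
    profiles = np.asarray(profiles, dtype=float)
    if assignment.n_items != profiles.shape[0]:
        raise ValueError("assignment does not cover the profile rows")
    k, t = assignment.n_clusters, profiles.shape[1]
    means = np.empty((k, t))
    for c in range(k):
        means[c] = profiles[assignment.members(c)].mean(axis=0)
    v = standardize_rows(means, [f"template_{c + 1}" for c in range(k)])
    if time_points is None:
        time_points = np.arange(1, t + 1, dtype=float)
    return TemplateMatrix(
        values=v,
        template_ids=[f"template_{c + 1}" for c in range(k)],
        time_points=np.asarray(time_points, dtype=float),
        membership=assignment,
    )


def sample_pseudo_matrices(
    profiles: np.ndarray,
    assignment: ClusterAssignment,
    n_matrices: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Draw pseudo-replicate K x T data matrices, one random member per cluster.

    Members of a cluster share a temporal signature but keep individual
    variation; sampling one standardized member profile per cluster yields
    replicate data matrices for the regression (up to the product of the
    cluster sizes distinct matrices exist).  Deterministic given ``seed``.
    """
    if n_matrices < 1:
        raise ValueError("n_matrices must be at least 1")
    z = standardize_rows(np.asarray(profiles, dtype=float))
    rng = np.random.default_rng(seed)
    logger.info("sampling %d pseudo-replicate matrices (seed=%d)", n_matrices, seed)
    member_lists = [assignment.members(c) for c in range(assignment.n_clusters)]
    out = []
    for _ in range(n_matrices):
        rows = [m[rng.integers(len(m))] for m in member_lists]
        out.append(z[rows].copy())
    return out
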