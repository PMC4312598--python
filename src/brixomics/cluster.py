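"""Profile clustering with a Spearman-correlation distance.

Significant transcripts are grouped on their condition-mean profiles
(8 values per gene on the default design).  k-means uses the rank-based
distance ``1 - rho_spearman`` for assignment with arithmetic-mean centroids
(the MeV-style approximation under a non-Euclidean metric), a greedy
D^2-weighted seeding from the seeded stream, and a bounded iteration count.
The number of clusters is advised by a leave-one-condition-out Figure of
Merit curve; agglomerative (average-linkage) clustering over the same
distance is provided for smaller families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series            # gene -> cluster id (0-based)
    centroids: np.ndarray             # k x n_conditions, log2 units
    sizes: np.ndarray
    metric: str
    iterations: int
    seed: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the number of genes")


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def spearman_distance(profile_a, profile_b) -> float:
    """``1 - rho_spearman`` (average ranks for ties), in [0, 2]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("profiles must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman distance undefined for a constant profile")
    rho = stats.spearmanr(a, b).statistic
    return float(1.0 - rho)


def _rank_z(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centred and scaled to unit norm.

    The Spearman correlation of two rows is then the dot product of their
    rank-z vectors, and ``1 - rho`` the distance.  Constant rows raise.
    """
    if (np.ptp(X, axis=1) == 0).any():
        raise ValueError("constant profile: Spearman ranks undefined")
    R = stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(R, axis=1, keepdims=True)
    return R / norms


def spearman_distance_matrix(X: np.ndarray) -> np.ndarray:
    Z = _rank_z(np.asarray(X, dtype=float))
    D = 1.0 - Z @ Z.T
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _member_means(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Per-cluster mean profiles; a (degenerate) empty cluster is NaN."""
    out = np.full((k, X.shape[1]), np.nan)
    for c in range(k):
        members = labels == c
        if members.any():
            out[c] = X[members].mean(axis=0)
    return out


def _seed_centroids(Z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy D^2-weighted (k-means++-style) seeding on rank-z rows."""
    n = Z.shape[0]
    first = int(rng.integers(n))
    chosen = [first]
    d2 = (1.0 - Z @ Z[first]) ** 2
    for _ in range(1, k):
        total = d2.sum()
        if total <= 0:
            nxt = int(rng.integers(n))
        else:
            nxt = int(rng.choice(n, p=d2 / total))
        chosen.append(nxt)
        d2 = np.minimum(d2, (1.0 - Z @ Z[nxt]) ** 2)
    return np.array(chosen)


def kmeans_cluster(profiles: pd.DataFrame | np.ndarray,
                   k: int,
                   max_iter: int = 50,
                   seed: int = 0,
                   n_init: int = 5) -> ClusterModel:
    """Lloyd iteration with Spearman-distance assignment and mean centroids.

    Runs ``n_init`` seeded restarts and keeps the lowest-objective model.
    Each run stops when assignments converge or after ``max_iter`` sweeps;
    an emptied cluster is re-seeded from the point farthest from its
    centroid, and the objective (sum of member-to-centroid distances) is
    non-increasing across recorded iterations.
    """
    index = None
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        profiles = profiles.to_numpy(dtype=float)
    X = np.asarray(profiles, dtype=float)
    best: ClusterModel | None = None
    for sub in range(max(1, n_init)):
        model = _kmeans_once(X, k, max_iter, seed, sub, index)
        if best is None or model.objective < best.objective:
            best = model
    return best


def _kmeans_once(X: np.ndarray, k: int, max_iter: int, seed: int,
                 restart: int, index) -> ClusterModel:
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n_profiles]")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(restart,)))
    Z = _rank_z(X)

    if k == 1:
        centroids = X.mean(axis=0, keepdims=True)
        labels = np.zeros(n, dtype=int)
        obj = float((1.0 - Z @ _rank_z(centroids)[0]).sum())
        return ClusterModel(k=1,
                            assignments=pd.Series(labels, index=index),
                            centroids=centroids, sizes=np.array([n]),
                            metric="spearman", iterations=0, seed=seed,
                            objective=obj, objective_trace=[obj])

    centroid_rows = _seed_centroids(Z, k, rng)
    centroids = X[centroid_rows].copy()
    labels = np.full(n, -1, dtype=int)
    prev_labels = labels
    trace: list[float] = []
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        D = 1.0 - Z @ _rank_z(centroids).T          # n x k
        new_labels = np.argmin(D, axis=1)
        # re-seed emptied clusters from the globally farthest point
        dist_to_own = D[np.arange(n), new_labels].copy()
        for c in range(k):
            if not (new_labels == c).any():
                far = int(np.argmax(dist_to_own))
                new_labels[far] = c
                dist_to_own[far] = -np.inf
        obj = float(D[np.arange(n), new_labels].sum())
        if trace and obj > trace[-1] + 1e-9:
            # mean centroids are not the metric's minimizers, so an update
            # can raise the objective; stop at the last improving state to
            # keep the recorded trace non-increasing
            labels = prev_labels
            iterations = it - 1
            break
        trace.append(obj)
        converged = (new_labels == labels).all()
        prev_labels = new_labels
        labels = new_labels
        if converged:
            break
        centroids = _member_means(X, labels, k)
    centroids = _member_means(X, labels, k)
    sizes = np.bincount(labels, minlength=k)
    return ClusterModel(k=k, assignments=pd.Series(labels, index=index),
                        centroids=centroids, sizes=sizes, metric="spearman",
                        iterations=iterations, seed=seed,
                        objective=trace[-1], objective_trace=trace)


# ---------------------------------------------------------------------------
# Figure of Merit
# ---------------------------------------------------------------------------

def estimate_k_fom(profiles: pd.DataFrame | np.ndarray,
                   k_range=range(2, 11),
                   seed: int = 0,
                   max_iter: int = 50,
                   elbow_drop: float = 0.10) -> tuple[pd.DataFrame, int]:
    """Leave-one-condition-out Figure of Merit curve and an advisory k.

    For each held-out condition the remaining columns are clustered; the
    FOM is the root mean squared deviation of the held-out value from its
    cluster's held-out mean, adjusted by ``sqrt(n / (n - k))`` and summed
    over conditions.  Profiles are centred per gene first: the rank-based
    clustering groups shapes irrespective of a gene's overall level, so the
    merit must score shape prediction, not baseline recovery.  The advisory
    k is the elbow of the curve: the k reached by the steepest relative
    drop, provided that drop exceeds ``elbow_drop`` (otherwise the curve is
    considered structureless and the smallest k is suggested).  The value
    is advisory; the final cluster count is a judgement call.
    """
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles.to_numpy(dtype=float)
    X = np.asarray(profiles, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    n, m = X.shape
    if m < 3:
        raise ValueError("FOM needs at least 3 conditions")
    ks = list(k_range)
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n_profiles - 1]")
    rows = []
    for k in ks:
        total = 0.0
        for held in range(m):
            keep = [j for j in range(m) if j != held]
            model = kmeans_cluster(X[:, keep], k, max_iter=max_iter, seed=seed)
            labels = model.assignments.to_numpy()
            held_vals = X[:, held]
            cluster_means = np.array([held_vals[labels == c].mean()
                                      for c in range(k)])
            dev = held_vals - cluster_means[labels]
            fom = np.sqrt(np.mean(dev ** 2))
            total += fom * np.sqrt(n / (n - k))
        rows.append((k, total))
    curve = pd.DataFrame(rows, columns=["k", "fom"])
    fom = curve["fom"].to_numpy()
    suggested = ks[0]
    if len(ks) > 1:
        drops = np.where(fom[:-1] > 0, (fom[:-1] - fom[1:]) /
                         np.where(fom[:-1] > 0, fom[:-1], 1.0), 0.0)
        best = int(np.argmax(drops))
        if drops[best] >= elbow_drop:
            suggested = ks[best + 1]
    return curve, suggested


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

def hierarchical_cluster(profiles: pd.DataFrame | np.ndarray,
                         n_clusters: int) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage agglomeration on the Spearman distance.

    Returns (assignments, scipy linkage matrix); the tree is cut to
    ``n_clusters`` groups.
    """
    index = None
    if isinstance(profiles, pd.DataFrame):
        index = profiles.index
        profiles = profiles.to_numpy(dtype=float)
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if not 1 <= n_clusters <= X.shape[0]:
        raise ValueError("n_clusters must lie in [1, n_profiles]")
    D = spearman_distance_matrix(X)
    link = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust") - 1
    return pd.Series(labels, index=index), link


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = walk(node.left), walk(node.right)
        ld = node.dist - node.left.dist
        rd = node.dist - node.right.dist
        return f"({left}:{ld:.6g},{right}:{rd:.6g})"

    return walk(tree) + ";"


# ---------------------------------------------------------------------------
# Cluster summaries
# ---------------------------------------------------------------------------

def summarize_clusters(model: ClusterModel,
                       profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster, per-condition mean and standard error over member genes.

    Singleton clusters have undefined SE, reported as NaN.
    """
    labels = model.assignments
    if not labels.index.equals(profiles.index):
        raise ValueError("assignments do not cover the profile index")
    rows = []
    for c in range(model.k):
        members = profiles[labels.to_numpy() == c]
        mean = members.mean(axis=0)
        if len(members) > 1:
            se = members.std(axis=0, ddof=1) / np.sqrt(len(members))
        else:
            se = pd.Series(np.nan, index=profiles.columns)
        for cond in profiles.columns:
            rows.append((c, cond, mean[cond], se[cond], len(members)))
    return pd.DataFrame(rows, columns=["cluster", "condition", "mean",
                                       "se", "size"])
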