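"""Fold-change trajectories, clusterability, and behaviour clustering.

Each retained contig's behaviour is its vector of log2 fold changes of
CPM at the post-stimulation timepoints relative to the lentiviral
baseline, with a pseudo-CPM to keep ratios finite.  Minimally detected
contigs — below the detection floor at every post-stimulation timepoint —
are excluded.  Clusterability is assessed with the Hopkins statistic
(nearest-neighbour contrast between real points and uniform probes in
the data's bounding box; Beta(m, m) null), and behaviours are grouped by
Ward hierarchical clustering with the cluster number chosen by mean
silhouette.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .alphabet import SelectionThresholds
from .quantify import ContigCountMatrix

DEFAULT_TIMEPOINTS = ("t24", "t48", "t72", "restim")


@dataclass
class TrajectorySet:
    """Per-contig log2 fold-change trajectories versus the baseline."""

    log2fc: pd.DataFrame  # rows contig, columns timepoints
    baseline_freq: pd.Series
    detect_mask: pd.Series  # True -> retained for clustering
    pseudo_cpm: float
    baseline: str

    @property
    def retained(self) -> pd.DataFrame:
        return self.log2fc.loc[self.detect_mask]


def build_trajectories(
    matrix: ContigCountMatrix,
    thresholds: SelectionThresholds = SelectionThresholds(),
    baseline: str = "virus",
    timepoints: Optional[Sequence[str]] = None,
    pseudo_cpm: float = 0.5,
    detect_mode: str = "any",
) -> TrajectorySet:
    """log2((cpm_t + c) / (cpm_baseline + c)) per contig and timepoint.

    ``detect_mode='any'`` (default) discards only contigs below the
    detection floor at *every* post-stimulation timepoint; ``'all'``
    additionally requires the floor to be met at every timepoint.
    """
    if baseline not in matrix.samples:
        raise ValueError(f"baseline column {baseline!r} missing")
    if timepoints is None:
        timepoints = [s for s in DEFAULT_TIMEPOINTS if s in matrix.samples]
    missing = set(timepoints) - set(matrix.samples)
    if missing:
        raise ValueError(f"timepoint column(s) missing: {sorted(missing)}")
    cpm = matrix.cpm
    base = cpm[baseline] + pseudo_cpm
    log2fc = pd.DataFrame(
        {tp: np.log2((cpm[tp] + pseudo_cpm) / base) for tp in timepoints}
    )
    detected = cpm[list(timepoints)] >= thresholds.min_cpm_detect
    if detect_mode == "any":
        mask = detected.any(axis=1)
    elif detect_mode == "all":
        mask = detected.all(axis=1)
    else:
        raise ValueError("detect_mode must be 'any' or 'all'")
    return TrajectorySet(
        log2fc=log2fc,
        baseline_freq=matrix.freq[baseline],
        detect_mask=mask,
        pseudo_cpm=pseudo_cpm,
        baseline=baseline,
    )


@dataclass
class HopkinsResult:
    H: float
    m: int
    n: int
    p_value: float
    seed: Optional[int]


def hopkins(
    data: "pd.DataFrame | np.ndarray",
    m: Optional[int] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> HopkinsResult:
    """Hopkins clusterability statistic with a Beta(m, m) null.

    ``m`` probe points are drawn uniformly over the data's bounding box
    and ``m`` data points are sampled without replacement; with u_i the
    probe-to-nearest-data distances and w_i the sampled-point-to-nearest-
    other-data distances, H = sum(u^d) / (sum(u^d) + sum(w^d)) where d is
    the dimension.  H near 0.5 indicates spatial uniformity, H near 1
    clustered structure; the one-sided p-value is P(Beta(m, m) >= H).

    Distances are computed on the torus obtained by wrapping the bounding
    box (periodic boundary conditions).  This standard edge correction
    removes the boundary truncation of nearest-neighbour balls that would
    otherwise make d-th-power distances non-exponential, so the
    Beta(m, m) null holds at finite n.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < 10:
        raise ValueError("Hopkins statistic is unstable below n = 10")
    if m is None:
        m = max(1, int(np.ceil(0.1 * n)))
    if not 1 <= m < n:
        raise ValueError("need 1 <= m < n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    boxsize = np.where(span > 0, span, 1.0)
    shifted = (X - lo) % boxsize  # wrap points sitting exactly on the far face
    probes = rng.uniform(0.0, span, size=(m, d))
    sample_idx = rng.choice(n, size=m, replace=False)

    tree = cKDTree(shifted, boxsize=boxsize)
    u, _ = tree.query(probes, k=1)
    w, _ = tree.query(shifted[sample_idx], k=2)
    w = w[:, 1]  # nearest *other* data point
    su = float(np.sum(u**d))
    sw = float(np.sum(w**d))
    H = su / (su + sw) if su + sw > 0 else 0.5
    p = float(stats.beta.sf(H, m, m))
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return HopkinsResult(H=float(H), m=m, n=n, p_value=p, seed=seed_out)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # contig -> cluster id (1..k)
    k: int
    silhouettes: dict[int, float]
    method: str
    degenerate: bool = False


def cluster_trajectories(
    traj: "TrajectorySet | pd.DataFrame",
    k_range: Sequence[int] = range(2, 16),
    method: str = "ward",
    seed: Optional[int] = None,
) -> ClusterAssignment:
    """Cluster retained trajectories; the cluster number is chosen by
    maximal mean silhouette over ``k_range``.

    ``method='ward'`` (default) is hierarchical agglomerative clustering
    with Ward linkage on Euclidean distances and is fully deterministic;
    ``'kmeans'`` is the seeded alternative.  If all trajectories are
    identical the silhouette is undefined and a single cluster is
    returned with ``degenerate=True``.
    """
    data = traj.retained if isinstance(traj, TrajectorySet) else traj
    X = data.to_numpy(dtype=float)
    n = X.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("fewer trajectories than the smallest cluster count")
    if np.allclose(X, X[0]):
        labels = pd.Series(1, index=data.index, name="cluster")
        return ClusterAssignment(labels, k=1, silhouettes={}, method=method, degenerate=True)

    def labels_for(k: int) -> np.ndarray:
        if method == "ward":
            return hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if method == "kmeans":
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            return km.fit_predict(X) + 1
        raise ValueError(f"unknown clustering method {method!r}")

    Z = hierarchy.linkage(X, method="ward") if method == "ward" else None
    silhouettes: dict[int, float] = {}
    best_k, best_s, best_labels = None, -np.inf, None
    for k in k_range:
        lab = labels_for(k)
        if len(np.unique(lab)) < 2:
            continue
        s = float(silhouette_score(X, lab))
        silhouettes[k] = s
        if s > best_s:
            best_k, best_s, best_labels = k, s, lab
    assert best_k is not None and best_labels is not None
    labels = pd.Series(best_labels, index=data.index, name="cluster")
    return ClusterAssignment(
        labels=labels, k=best_k, silhouettes=silhouettes, method=method
    )


def trajectory_projection(
    matrix: ContigCountMatrix,
    timepoints: Optional[Sequence[str]] = None,
    retained: Optional[pd.Index] = None,
) -> pd.DataFrame:
    """Tidy per-contig frequency coordinates for the multi-timepoint
    scatter (x/y/z = 24/48/72 h frequency, colour = post-restimulation
    frequency)."""
    if timepoints is None:
        timepoints = [s for s in DEFAULT_TIMEPOINTS if s in matrix.samples]
    freq = matrix.freq[list(timepoints)]
    out = freq.add_prefix("freq_")
    if retained is not None:
        out = out.loc[out.index.intersection(retained)]
    return out
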