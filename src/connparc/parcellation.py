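"""Fingerprint clustering and silhouette-based model selection.

The group fingerprint matrix (seed voxels x GM voxels, correlation units)
is clustered by average-linkage hierarchical clustering under a
correlation distance between rows.  The dendrogram is cut at many uniform
height levels; for each level the resulting labeling is scored on every
individual subject's own fingerprint matrix with the mean silhouette, and
a one-sample t-statistic across subjects rates how well that cut level
generalises.  Local maxima of the t profile are the candidate cluster
numbers.  Single-subject solutions re-cluster each subject's matrix and
cut at the chosen K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

__all__ = [
    "Dendrogram",
    "ParcelSolution",
    "SilhouetteProfile",
    "build_dendrogram",
    "cut_uniform_levels",
    "subject_silhouette",
    "silhouette_profile",
    "subject_solution",
    "FingerprintParcellation",
]


def _fingerprint_distance(x, metric: str = "corrdist") -> np.ndarray:
    """Condensed pairwise distance between fingerprint rows."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("fingerprints contain non-finite values")
    if metric == "corrdist":
        return pdist(x, metric="correlation")
    if metric == "euclidean":
        return pdist(x, metric="euclidean")
    raise ValueError(f"unknown fingerprint metric {metric!r}")


@dataclass
class Dendrogram:
    """Average-linkage merge tree over seed-mask voxels."""

    linkage: np.ndarray        # scipy linkage matrix
    metric: str
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class ParcelSolution:
    """Integer labeling of seed-mask voxels into K clusters."""

    labels: np.ndarray
    k: int
    cut_level: float
    source: str = "group"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.k = int(self.k)


@dataclass
class SilhouetteProfile:
    """Across-subject silhouette t-scores along the dendrogram cut levels."""

    levels: np.ndarray            # cut heights
    k_per_level: np.ndarray
    subject_values: np.ndarray    # (n_levels, n_subjects) mean silhouettes
    t_scores: np.ndarray          # nan where undefined
    local_maxima: list            # level indices
    flags: list = field(default_factory=list)


def build_dendrogram(fingerprints, metric: str = "corrdist") -> Dendrogram:
    """Average-linkage tree over fingerprint rows (correlation units)."""
    x = np.asarray(fingerprints, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 seed voxels")
    d = _fingerprint_distance(x, metric)
    z = hierarchy.linkage(d, method="average")
    return Dendrogram(linkage=z, metric=metric, n_leaves=x.shape[0])


def cut_dendrogram(dend: Dendrogram, height: float) -> np.ndarray:
    """Labels from cutting at ``height`` (merges with height <= cut apply)."""
    return hierarchy.fcluster(dend.linkage, t=height, criterion="distance")


def cut_uniform_levels(dend: Dendrogram, n_levels: int = 100):
    """Cut the dendrogram at ``n_levels`` uniformly spaced heights.

    Heights are uniform over (0, max merge height], so the scan runs from
    the all-singletons end of the tree to the single-cluster root; each
    level yields one :class:`ParcelSolution` and duplicate labelings are
    retained because they index different levels.  A degenerate tree with
    a single distinct merge height triggers a warning.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 cut levels")
    h = dend.heights
    if np.ptp(h) < 1e-15:
        warnings.warn("degenerate dendrogram: all merge heights equal; "
                      "only trivial cuts available", RuntimeWarning)
    heights = np.linspace(0.0, h.max(), n_levels + 1)[1:]
    out = []
    for t in heights:
        labels = hierarchy.fcluster(dend.linkage, t=t, criterion="distance")
        out.append(ParcelSolution(labels=labels, k=labels.max(),
                                  cut_level=float(t), source="group"))
    return out


def subject_silhouette(solution: ParcelSolution, subject_matrix,
                       metric: str = "corrdist") -> float:
    """Mean silhouette of a labeling evaluated on one subject's own
    fingerprint distances; singleton clusters contribute s = 0."""
    values = getattr(subject_matrix, "values", subject_matrix)
    labels = solution.labels
    if len(labels) != np.asarray(values).shape[0]:
        raise ValueError("labels do not cover the subject's seed voxels")
    if solution.k < 2:
        raise ValueError("silhouette undefined for a single cluster")
    d = squareform(_fingerprint_distance(values, metric))
    s = silhouette_samples(d, labels, metric="precomputed")
    return float(s.mean())


def _runs(solutions):
    """Group consecutive levels carrying identical labelings."""
    runs = []
    for i, sol in enumerate(solutions):
        if runs and np.array_equal(solutions[runs[-1][0]].labels, sol.labels):
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def silhouette_profile(solutions, subject_matrices,
                       metric: str = "corrdist") -> SilhouetteProfile:
    """Across-subject one-sample t of the mean silhouette, per cut level.

    Levels with K = 1 or zero across-subject variance get t = nan and a
    flag.  Local maxima are computed over runs of identical labelings (a
    run is one candidate solution even if it spans many levels) and
    require the run's t to strictly exceed both neighbouring runs'; a flat
    profile yields no maxima and a warning.
    """
    if len(subject_matrices) < 2:
        raise ValueError("need at least 2 subjects")
    n_lev = len(solutions)
    n_sub = len(subject_matrices)
    # distances per subject are reused across levels
    dists = [squareform(_fingerprint_distance(
        getattr(m, "values", m), metric)) for m in subject_matrices]
    vals = np.full((n_lev, n_sub), np.nan)
    t = np.full(n_lev, np.nan)
    flags = []
    runs = _runs(solutions)
    for run in runs:
        i0 = run[0]
        sol = solutions[i0]
        if sol.k < 2 or sol.k >= len(sol.labels):
            # all-merged or all-singleton labelings carry no information
            flags.append((i0, "silhouette undefined at this level"))
            continue
        row = np.array([silhouette_samples(d, sol.labels,
                                           metric="precomputed").mean()
                        for d in dists])
        sd = row.std(ddof=1)
        if sd < 1e-15:
            flags.append((i0, "zero across-subject variance"))
            tval = np.nan
        else:
            tval = row.mean() / (sd / np.sqrt(n_sub))
        for i in run:
            vals[i] = row
            t[i] = tval

    run_t = np.array([t[r[0]] for r in runs])
    finite = np.isfinite(run_t)
    cmp = np.where(finite, run_t, -np.inf)
    maxima = []
    for j in range(1, len(runs) - 1):
        if finite[j] and cmp[j] > cmp[j - 1] and cmp[j] > cmp[j + 1]:
            maxima.append(runs[j][0])
    if not maxima and (not finite.any()
                       or np.ptp(run_t[finite]) < 1e-12):
        warnings.warn("flat or undefined silhouette-t profile: no local "
                      "maxima", RuntimeWarning)
    return SilhouetteProfile(
        levels=np.array([s.cut_level for s in solutions]),
        k_per_level=np.array([s.k for s in solutions]),
        subject_values=vals, t_scores=t, local_maxima=maxima, flags=flags)


def subject_solution(subject_matrix, k: int,
                     metric: str = "corrdist") -> ParcelSolution:
    """Re-cluster one subject's fingerprints and cut at exactly K."""
    values = getattr(subject_matrix, "values", subject_matrix)
    values = np.asarray(values, dtype=float)
    if not 1 <= k <= values.shape[0]:
        raise ValueError(f"K={k} invalid for {values.shape[0]} voxels")
    z = hierarchy.linkage(_fingerprint_distance(values, metric),
                          method="average")
    labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
    sid = getattr(subject_matrix, "subject_id", "")
    return ParcelSolution(labels=labels, k=labels.max(), cut_level=float(k),
                          source=sid or "subject")


class FingerprintParcellation(BaseEstimator, ClusterMixin):
    """Connectivity-based parcellation as a scikit-learn clusterer.

    ``fit(X)`` takes the group fingerprint matrix (seed voxels x targets,
    correlation units).  With ``n_clusters`` set, the dendrogram is cut to
    that K.  Otherwise pass the per-subject fingerprint matrices via the
    ``subject_matrices`` fit parameter and the cut level is selected at
    the silhouette-t local maximum with the highest t.

    Attributes
    ----------
    labels_ : chosen cluster label per seed voxel (1..K).
    n_clusters_ : chosen K.
    dendrogram_ : the group merge tree.
    profile_ : the silhouette t profile (when model selection ran).
    """

    def __init__(self, n_clusters=None, n_levels=100, metric="corrdist"):
        self.n_clusters = n_clusters
        self.n_levels = n_levels
        self.metric = metric

    def fit(self, X, y=None, *, subject_matrices=None):
        X = np.asarray(X, dtype=float)
        self.dendrogram_ = build_dendrogram(X, metric=self.metric)
        if self.n_clusters is not None:
            labels = hierarchy.fcluster(self.dendrogram_.linkage,
                                        t=self.n_clusters,
                                        criterion="maxclust")
            self.labels_ = labels
            self.n_clusters_ = int(labels.max())
            self.solution_ = ParcelSolution(
                labels=labels, k=self.n_clusters_,
                cut_level=float(self.n_clusters), source="group")
            return self
        if subject_matrices is None:
            raise ValueError("either set n_clusters or pass subject_matrices "
                             "for silhouette-based selection")
        solutions = cut_uniform_levels(self.dendrogram_, self.n_levels)
        self.profile_ = silhouette_profile(solutions, subject_matrices,
                                           metric=self.metric)
        if not self.profile_.local_maxima:
            raise RuntimeError("no silhouette-t local maxima found")
        best = max(self.profile_.local_maxima,
                   key=lambda i: self.profile_.t_scores[i])
        self.solution_ = solutions[best]
        self.labels_ = self.solution_.labels
        self.n_clusters_ = self.solution_.k
        self.selected_level_ = best
        return self
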