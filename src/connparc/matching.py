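"""Group-to-subject cluster matching, replication rates, probabilistic atlas.

Group-level clusters are matched to each subject's clusters by clustering
the Dice-overlap matrix itself: all group and subject clusters enter an
average-linkage dendrogram under distance 1 - Dice (within-set pairs held
at 1), every distinct cut height is scanned, and the cut producing the
most two-element {group, subject} pairs wins.  No minimal-overlap cutoff
is enforced; matching favours a globally optimal pairing instead.

Matched subject clusters are binarised and summed into per-cluster
probability maps; thresholding (default 25%) and winner-take-all
assignment produce the final atlas partition, with exact probability ties
recorded explicitly and broken toward the lower cluster index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

__all__ = [
    "ClusterMatch",
    "ClusterMatchReport",
    "ProbabilisticAtlas",
    "dice",
    "dice_matrix",
    "match_clusters",
    "match_from_dice",
    "replication_rates",
    "build_probability_maps",
    "winner_take_all",
]


def _as_voxel_set(a):
    a = np.asarray(a)
    if a.dtype == bool:
        return {tuple(v) for v in np.argwhere(a)}
    return {tuple(v) for v in a.reshape(-1, a.shape[-1])}


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two voxel sets (index arrays or
    boolean masks).  Two empty sets give 0 with a warning."""
    sa, sb = _as_voxel_set(a), _as_voxel_set(b)
    denom = len(sa) + len(sb)
    if denom == 0:
        warnings.warn("Dice of two empty sets defined as 0", RuntimeWarning)
        return 0.0
    return 2.0 * len(sa & sb) / denom


@dataclass
class ClusterMatch:
    group_cluster: int
    subject_cluster: int
    dice: float


@dataclass
class ClusterMatchReport:
    """Matches between one subject's clusters and the group clusters."""

    matches: list                 # list of ClusterMatch
    group_clusters: list          # all group cluster labels considered
    subject_id: str = ""

    def matched_group_clusters(self):
        return {m.group_cluster for m in self.matches}

    def dice_for(self, group_cluster):
        for m in self.matches:
            if m.group_cluster == group_cluster:
                return m.dice
        return None


def _clusters_from_labels(labels, voxel_index):
    """Map label -> voxel-coordinate set, dropping empty clusters."""
    labels = np.asarray(labels)
    voxel_index = np.asarray(voxel_index)
    out = {}
    for lab in np.unique(labels):
        vox = voxel_index[labels == lab]
        if len(vox):
            out[int(lab)] = {tuple(v) for v in vox}
    return out


def dice_matrix(group_sets: dict, subject_sets: dict) -> np.ndarray:
    g = list(group_sets)
    s = list(subject_sets)
    m = np.zeros((len(g), len(s)))
    for i, gl in enumerate(g):
        for j, sl in enumerate(s):
            a, b = group_sets[gl], subject_sets[sl]
            m[i, j] = 2.0 * len(a & b) / (len(a) + len(b))
    return m


def match_from_dice(dmat, group_ids=None, subject_ids=None,
                    min_dice: float = 0.0):
    """Match group and subject clusters given their Dice matrix.

    Builds the joint element set (rows then columns), assigns pairwise
    distance 1 - Dice between group/subject pairs and 1 within each side,
    runs average linkage, scans every distinct merge height as a cut, and
    keeps the cut maximising the number of two-element clusters that pair
    one group with one subject cluster (ties -> lowest cut height).

    No minimal-overlap cutoff applies by default; ``min_dice`` > 0
    optionally discards matches below that overlap after the fact.
    """
    dmat = np.asarray(dmat, dtype=float)
    ng, ns = dmat.shape
    if group_ids is None:
        group_ids = list(range(1, ng + 1))
    if subject_ids is None:
        subject_ids = list(range(1, ns + 1))
    n = ng + ns
    full = np.ones((n, n))
    np.fill_diagonal(full, 0.0)
    full[:ng, ng:] = 1.0 - dmat
    full[ng:, :ng] = (1.0 - dmat).T
    z = hierarchy.linkage(squareform(full, checks=False), method="average")
    heights = np.unique(z[:, 2])
    best = (-1, None, None)  # (count, height, assignment)
    for h in heights:
        labels = hierarchy.fcluster(z, t=h, criterion="distance")
        count = 0
        pairs = []
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) == 2:
                a, b = members
                if a < ng <= b:
                    count += 1
                    pairs.append((a, b - ng))
        if count > best[0]:
            best = (count, h, pairs)
    matches = [ClusterMatch(group_cluster=group_ids[i],
                            subject_cluster=subject_ids[j],
                            dice=float(dmat[i, j]))
               for i, j in (best[2] or [])
               if dmat[i, j] >= min_dice]
    return matches


def match_clusters(group_solution, subject_solution, voxel_index,
                   subject_id: str = "",
                   min_dice: float = 0.0) -> ClusterMatchReport:
    """Match a subject's parcel solution against the group solution.

    Both solutions must label the same ordered seed voxels
    (``voxel_index``, shape (n, 3)).  Empty clusters are excluded with a
    warning.
    """
    gsets = _clusters_from_labels(group_solution.labels, voxel_index)
    ssets = _clusters_from_labels(subject_solution.labels, voxel_index)
    if len(gsets) < len(np.unique(group_solution.labels)) or \
            len(ssets) < len(np.unique(subject_solution.labels)):
        warnings.warn("empty clusters excluded from matching", RuntimeWarning)
    dmat = dice_matrix(gsets, ssets)
    matches = match_from_dice(dmat, list(gsets), list(ssets),
                              min_dice=min_dice)
    return ClusterMatchReport(matches=matches, group_clusters=list(gsets),
                              subject_id=subject_id)


def replication_rates(reports, groups=None):
    """Per-group-cluster replication percentage across subjects.

    Returns ``(rates, chi2_table)``: ``rates`` maps group cluster label to
    the percentage of subjects with a match; when per-subject ``groups``
    labels are given, ``chi2_table`` maps cluster label to the p-value of
    a chi-squared test for a group difference in match frequency.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one subject report")
    clusters = reports[0].group_clusters
    rates = {}
    pvals = {}
    for c in clusters:
        hits = np.array([c in r.matched_group_clusters() for r in reports])
        rates[c] = 100.0 * hits.mean()
        if groups is not None:
            groups_arr = np.asarray(groups)
            table = []
            for g in np.unique(groups_arr):
                sel = hits[groups_arr == g]
                table.append([sel.sum(), (~sel).sum()])
            table = np.asarray(table)
            if (table.sum(axis=0) > 0).all():
                pvals[c] = float(chi2_contingency(table)[1])
            else:
                pvals[c] = 1.0
    return rates, (pvals if groups is not None else None)


@dataclass
class ProbabilisticAtlas:
    """Per-cluster probability volumes plus the winner-take-all partition."""

    probabilities: np.ndarray     # (n_clusters, *grid) in [0, 1]
    cluster_labels: list
    threshold: float = 0.25
    wta_labels: np.ndarray = None  # 0 = unassigned, else cluster label
    tie_mask: np.ndarray = None


def build_probability_maps(subject_cluster_masks, n_subjects: int,
                           cluster_labels=None) -> ProbabilisticAtlas:
    """Binarise and sum matched subject clusters into probability maps.

    ``subject_cluster_masks`` maps group-cluster label -> list of boolean
    volumes (one per subject in which that cluster matched); unmatched
    subjects simply contribute nothing.  probability = matched-subject
    coverage count / total subjects.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if cluster_labels is None:
        cluster_labels = sorted(subject_cluster_masks)
    grids = [m for masks in subject_cluster_masks.values() for m in masks]
    if not grids:
        raise ValueError("no matched clusters supplied")
    shape = grids[0].shape
    probs = np.zeros((len(cluster_labels),) + shape)
    for i, lab in enumerate(cluster_labels):
        for m in subject_cluster_masks.get(lab, []):
            probs[i] += np.asarray(m, dtype=float)
    probs /= n_subjects
    return ProbabilisticAtlas(probabilities=probs,
                              cluster_labels=list(cluster_labels))


def winner_take_all(atlas: ProbabilisticAtlas,
                    threshold: float = 0.25) -> ProbabilisticAtlas:
    """Threshold and resolve overlaps by highest probability.

    A voxel is labeled iff its maximum cluster probability strictly
    exceeds ``threshold``; exact ties between the top clusters are
    recorded in ``tie_mask`` and broken toward the lowest cluster index.
    """
    probs = atlas.probabilities
    maxp = probs.max(axis=0)
    arg = probs.argmax(axis=0)   # argmax takes the lowest index on ties
    labeled = maxp > threshold
    n_at_max = (probs == maxp[None]).sum(axis=0)
    ties = labeled & (n_at_max > 1)
    labels = np.zeros(maxp.shape, dtype=int)
    lab_values = np.asarray(atlas.cluster_labels)
    labels[labeled] = lab_values[arg[labeled]]
    return ProbabilisticAtlas(probabilities=probs,
                              cluster_labels=atlas.cluster_labels,
                              threshold=threshold,
                              wta_labels=labels, tie_mask=ties)
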