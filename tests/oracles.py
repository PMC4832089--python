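"""Independent brute-force oracles shared across test modules.

Everything here is deliberately naive (exhaustive enumeration, textbook
formulas) and independent of the package's implementation paths.
"""

import itertools

import numpy as np


def brute_force_silhouette(dist, labels):
    """Textbook silhouette from the full distance matrix."""
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        if same.sum() == 1:
            continue  # singleton: s = 0
        a = dist[i, same & (np.arange(n) != i)].mean()
        b = min(dist[i, labels == lab].mean()
                for lab in np.unique(labels) if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    return s.mean()


def tree_cut_oracle(linkage, height, n):
    """Independent recursive cut: apply merges with height <= cut."""
    parent = list(range(n + len(linkage)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for k, (a, b, h, _) in enumerate(linkage):
        if h <= height + 1e-12:
            node = n + k
            parent[find(int(a))] = node
            parent[find(int(b))] = node
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots) + 1)
    return labels


def exhaustive_match_oracle(dmat):
    """Re-derive Dice-dendrogram matching with a naive O(n^3) average
    linkage and an exhaustive scan over every cut height."""
    dmat = np.asarray(dmat, dtype=float)
    ng, ns = dmat.shape
    n = ng + ns
    full = np.ones((n, n))
    np.fill_diagonal(full, 0.0)
    full[:ng, ng:] = 1.0 - dmat
    full[ng:, :ng] = (1.0 - dmat).T

    active = list(range(n))
    dist = {(i, j): full[i, j] for i in range(n) for j in range(n) if i < j}
    members = {i: [i] for i in range(n)}
    nxt = n
    heights = []
    snapshots = []
    while len(active) > 1:
        h, a, b = min(((dist[tuple(sorted((x, y)))], x, y)
                       for x, y in itertools.combinations(active, 2)))
        members[nxt] = members.pop(a) + members.pop(b)
        active = [x for x in active if x not in (a, b)] + [nxt]
        for other in active[:-1]:
            pairs = [(u, v) for u in members[nxt] for v in members[other]]
            dist[tuple(sorted((nxt, other)))] = np.mean(
                [full[u, v] for u, v in pairs])
        heights.append(h)
        snapshots.append({k: list(v) for k, v in members.items()
                          if k in active})
        nxt += 1

    best_count, best_pairs = -1, []
    for h in heights:
        idx = max(i for i, hh in enumerate(heights) if hh <= h + 1e-12)
        snap = snapshots[idx]
        count, pairs = 0, []
        for mem in snap.values():
            if len(mem) == 2:
                lo, hi = sorted(mem)
                if lo < ng <= hi:
                    count += 1
                    pairs.append((lo, hi - ng))
        if count > best_count:
            best_count, best_pairs = count, pairs
    return {(i + 1, j + 1) for i, j in best_pairs}
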