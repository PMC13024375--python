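"""Independent brute-force oracles used by the test suite.

Deliberately naive: cluster distances are recomputed from scratch at every
agglomeration step (no Lance-Williams recursion), cophenetic entries come
from explicit LCA climbs, and permutation p-values from direct enumeration.
"""

import itertools
import math

import numpy as np


def naive_agglomerate(D, labels, linkage, points=None):
    """O(n^3) agglomeration recomputing inter-cluster distances from scratch.

    single/complete/average read the original pairwise matrix directly;
    ward needs the point coordinates (centroid formula
    sqrt(2 |A||B| / (|A|+|B|)) * ||mean_A - mean_B||).
    Ties break on the lexicographically smallest (min leaf, min leaf) pair.
    Returns a list of (member frozenset, height) per merge.
    """
    n = len(labels)
    members = {i: frozenset([i]) for i in range(n)}
    minleaf = {i: labels[i] for i in range(n)}
    active = set(range(n))
    nid = n
    out = []

    def cluster_dist(a, b):
        if linkage == "ward":
            pa = np.mean([points[i] for i in members[a]], axis=0)
            pb = np.mean([points[i] for i in members[b]], axis=0)
            na, nb = len(members[a]), len(members[b])
            return math.sqrt(2.0 * na * nb / (na + nb)) * float(np.linalg.norm(pa - pb))
        vals = [D[i][j] for i in members[a] for j in members[b]]
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        return sum(vals) / len(vals)

    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                d = cluster_dist(a, b)
                key = (d, tuple(sorted((minleaf[a], minleaf[b]))))
                if best is None or key < best[0]:
                    best = (key, (a, b))
        (d, _), (i, j) = best
        members[nid] = members[i] | members[j]
        minleaf[nid] = min(minleaf[i], minleaf[j])
        out.append((frozenset(labels[x] for x in members[nid]), d))
        active -= {i, j}
        active.add(nid)
        nid += 1
    return out


def lca_cophenetic(dendro):
    """Cophenetic matrix via explicit parent-pointer LCA climbs."""
    n = dendro.n_leaves
    parent = {}
    height = {i: 0.0 for i in range(n)}
    for k, (a, b, h) in enumerate(dendro.merges):
        nid = n + k
        parent[int(a)] = nid
        parent[int(b)] = nid
        height[nid] = float(h)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc = set()
            x = i
            while x in parent:
                x = parent[x]
                anc.add(x)
            x = j
            while x not in anc:
                x = parent[x]
            C[i, j] = C[j, i] = height[x]
    return C


def enumerate_spearman_p(x, y):
    """Two-sided exact permutation p for Spearman rho by full enumeration.

    Uses np.corrcoef on midranks — a different computational route from the
    implementation under test.  Same >= |obs| - 1e-12 counting convention.
    """
    from scipy.stats import rankdata

    rx = rankdata(np.asarray(x, dtype=float))
    ry = rankdata(np.asarray(y, dtype=float))
    obs = abs(float(np.corrcoef(rx, ry)[0, 1]))
    count = total = 0
    for perm in itertools.permutations(ry):
        rho = float(np.corrcoef(rx, np.array(perm))[0, 1])
        total += 1
        if abs(rho) >= obs - 1e-12:
            count += 1
    return count / total


def random_dendrogram(n, rng):
    """A random dendrogram: average-linkage tree of random points."""
    from scipy.spatial.distance import pdist, squareform

    from lipisign import hierarchical_cluster

    pts = rng.normal(size=(n, 3))
    D = squareform(pdist(pts))
    labels = [f"L{i:02d}" for i in range(n)]
    return hierarchical_cluster(D, labels=labels, linkage="average")
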