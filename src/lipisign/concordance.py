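"""Species-level dendrograms, cophenetic correlation, tanglegram entanglement.

The comparative endpoint of the pipeline: per tissue (or per sex) the
species x probe matrix of mean methylation is clustered hierarchically on
Euclidean distance, and pairs of dendrograms are compared by

* the cophenetic correlation — Pearson correlation between the two
  condensed cophenetic-distance vectors (the merge height at which each
  leaf pair first joins one cluster), and
* the tanglegram entanglement — normalised L1 rank displacement between
  the two leaf orders (0 = parallel, 1 = fully crossed), minimised by a
  greedy subtree-rotation sweep that never changes merge heights.

The agglomeration is a Lance-Williams implementation with a deterministic
tie-break (among equal-minimum distances, merge the pair whose clusters
have the lexicographically smallest minimum leaf labels), so runs are
bit-reproducible and a naive from-scratch oracle can reproduce them merge
by merge.  scipy.cluster.hierarchy would compute the same heights but owns
its own tie-breaking and offers no rotatable leaf order, which the
untangling step requires; it serves as an independent cross-check in the
test suite instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datasets import MammalDataset

__all__ = [
    "Dendrogram",
    "TanglegramResult",
    "species_mean_matrix",
    "euclidean_distances",
    "hierarchical_cluster",
    "cophenetic_matrix",
    "cophenetic_correlation",
    "entanglement",
    "untangle",
    "robinson_foulds",
    "tissue_concordance",
    "sex_concordance",
    "tanglegram_text",
]

LINKAGES = ("average", "single", "complete", "ward")


# ---------------------------------------------------------------------------
# Dendrogram container


@dataclass
class Dendrogram:
    """Agglomerative tree: leaves 0..n-1, merge k creates cluster id n+k.

    ``merges[k] = [a, b, height]`` records the two child cluster ids and the
    merge height.  The displayed leaf order is the left-to-right traversal
    of the root; flipping a merge swaps its children, which is the only
    rearrangement a planar dendrogram drawing allows.
    """

    leaves: tuple[str, ...]
    merges: list  # list of [int, int, float]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(set(self.leaves)) != n:
            raise ValueError("leaf labels must be unique")
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}")
        self.merges = [list(m) for m in self.merges]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_id(self) -> int:
        return 2 * self.n_leaves - 2

    def copy(self) -> "Dendrogram":
        return Dendrogram(self.leaves, [list(m) for m in self.merges])

    def _order_ids(self, node: int) -> list[int]:
        n = self.n_leaves
        if node < n:
            return [node]
        a, b, _ = self.merges[node - n]
        return self._order_ids(int(a)) + self._order_ids(int(b))

    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in self._order_ids(self.root_id)]

    def flip(self, k: int) -> None:
        """Swap the children of merge k (a subtree rotation)."""
        self.merges[k][0], self.merges[k][1] = self.merges[k][1], self.merges[k][0]

    def members(self, node: int) -> frozenset[str]:
        return frozenset(self.leaves[i] for i in self._order_ids(node))

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        return {self.members(self.n_leaves + k) for k in range(len(self.merges))}

    def to_newick(self) -> str:
        """Rooted Newick with branch lengths parent height - child height.

        Labels containing Newick metacharacters are single-quoted.
        """
        n = self.n_leaves

        def height(node: int) -> float:
            return 0.0 if node < n else float(self.merges[node - n][2])

        def render(node: int, parent_h: float | None) -> str:
            if node < n:
                s = _quote(self.leaves[node])
            else:
                a, b, _ = self.merges[node - n]
                h = height(node)
                s = f"({render(int(a), h)},{render(int(b), h)})"
            if parent_h is not None:
                s += f":{max(parent_h - height(node), 0.0):.10g}"
            return s

        return render(self.root_id, None) + ";"


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]:;,']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Building blocks


def species_mean_matrix(ds: MammalDataset, probes, tissue: str | None = None,
                        sex: str | None = None, min_samples: int = 1) -> pd.DataFrame:
    """Species x probe matrix of mean beta within a tissue/sex stratum."""
    if isinstance(probes, str):
        probes = [probes]
    sheet = ds.samples
    if tissue is not None:
        sheet = sheet[sheet["tissue"] == tissue]
    if sex is not None:
        sheet = sheet[sheet["sex"] == sex]
    if sheet.empty:
        raise ValueError(f"empty stratum (tissue={tissue!r}, sex={sex!r})")
    rows = {}
    for sp in sorted(sheet["species"].unique()):
        ids = list(sheet.index[sheet["species"] == sp])
        if len(ids) < min_samples:
            continue
        rows[sp] = ds.betas.loc[list(probes), ids].mean(axis=1)
    return pd.DataFrame(rows).T


def euclidean_distances(matrix) -> np.ndarray:
    """Pairwise Euclidean distance matrix between the rows of ``matrix``."""
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("missing values in input matrix; impute or exclude upstream")
    return squareform(pdist(X, metric="euclidean"))


def _validate_dist(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    return D


def hierarchical_cluster(dist, labels=None, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering via Lance-Williams updates.

    Supports average (UPGMA, the default), single, complete and ward
    linkage.  Ward maintains squared distances internally (the standard
    Lance-Williams recursion) and records sqrt heights, matching the
    centroid formulation on Euclidean input.  Ties are broken by merging
    the pair whose (min leaf label, min leaf label) key is lexicographically
    smallest, which makes runs deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    D = _validate_dist(dist)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError("labels length must match distance matrix size")

    squared = linkage == "ward"
    # working inter-cluster distances keyed on (id_a, id_b), id_a < id_b
    work: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            work[(i, j)] = D[i, j] ** 2 if squared else D[i, j]
    size = {i: 1 for i in range(n)}
    minleaf = {i: labels[i] for i in range(n)}
    active = set(range(n))
    merges: list[list] = []

    for step in range(n - 1):
        best_key = None
        best_d = np.inf
        for (a, b), d in work.items():
            key = tuple(sorted((minleaf[a], minleaf[b])))
            if d < best_d or (d == best_d and key < best_key):
                best_d, best_key, best = d, key, (a, b)
        i, j = best
        new = n + step
        height = float(np.sqrt(best_d)) if squared else float(best_d)
        for c in list(active - {i, j}):
            d_ic = work.pop(tuple(sorted((i, c))))
            d_jc = work.pop(tuple(sorted((j, c))))
            if linkage == "single":
                d_new = min(d_ic, d_jc)
            elif linkage == "complete":
                d_new = max(d_ic, d_jc)
            elif linkage == "average":
                d_new = (size[i] * d_ic + size[j] * d_jc) / (size[i] + size[j])
            else:  # ward, squared distances
                tot = size[i] + size[j] + size[c]
                d_new = ((size[i] + size[c]) * d_ic + (size[j] + size[c]) * d_jc
                         - size[c] * work.get((min(i, j), max(i, j)), best_d)) / tot
            work[(c, new)] = d_new
        work.pop((min(i, j), max(i, j)), None)
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
        minleaf[new] = min(minleaf[i], minleaf[j])
        # orient children so the smaller min-leaf-label cluster sits left
        left, right = (i, j) if minleaf[i] <= minleaf[j] else (j, i)
        merges.append([left, right, height])

    return Dendrogram(tuple(labels), merges)


def cophenetic_matrix(dendro: Dendrogram) -> np.ndarray:
    """Entry (i, j) = merge height first uniting leaves i and j."""
    n = dendro.n_leaves
    C = np.zeros((n, n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, h) in enumerate(dendro.merges):
        ma, mb = members[int(a)], members[int(b)]
        for x in ma:
            for y in mb:
                C[x, y] = C[y, x] = h
        members[n + k] = ma + mb
    return C


def _condensed(dendro: Dendrogram, leaf_index: dict[str, int]) -> np.ndarray:
    """Condensed cophenetic vector in a caller-specified leaf ordering."""
    C = cophenetic_matrix(dendro)
    perm = [leaf_index[lab] for lab in dendro.leaves]
    n = len(perm)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[perm[i], perm[j]] = C[i, j]
    return squareform(out, checks=False)


def cophenetic_correlation(d1: Dendrogram, d2: Dendrogram, method: str = "pearson") -> float:
    """Pearson (or Spearman) correlation of the two condensed cophenetic vectors."""
    if set(d1.leaves) != set(d2.leaves):
        raise ValueError("dendrograms have different leaf sets")
    if d1.n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    index = {lab: i for i, lab in enumerate(sorted(d1.leaves))}
    v1 = _condensed(d1, index)
    v2 = _condensed(d2, index)
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant cophenetic vector (all merges at equal height)")
    if method == "spearman":
        from scipy.stats import rankdata

        v1, v2 = rankdata(v1), rankdata(v2)
    return float(np.corrcoef(v1, v2)[0, 1])


def entanglement(order1, order2) -> float:
    """Normalised L1 rank displacement between two leaf orders.

    E = sum_i |rank1(i) - rank2(i)| / M where M is the same sum for the
    reversal permutation (the maximum possible); 0 for parallel orders,
    1 for fully crossed.
    """
    if set(order1) != set(order2):
        raise ValueError("leaf sets differ")
    n = len(order1)
    if len(set(order1)) != n:
        raise ValueError("duplicate leaves in order")
    r2 = {lab: i for i, lab in enumerate(order2)}
    disp = sum(abs(i - r2[lab]) for i, lab in enumerate(order1))
    M = sum(abs(i - (n - 1 - i)) for i in range(n))
    return disp / M if M else 0.0


@dataclass
class TanglegramResult:
    cophenetic_r: float
    entanglement_before: float
    entanglement_after: float
    order1: list[str]
    order2: list[str]
    tree1: Dendrogram
    tree2: Dendrogram

    @property
    def rank_pairs(self) -> list[tuple[str, int, int]]:
        r2 = {lab: i for i, lab in enumerate(self.order2)}
        return [(lab, i, r2[lab]) for i, lab in enumerate(self.order1)]


def untangle(d1: Dendrogram, d2: Dendrogram, max_iter: int = 20) -> TanglegramResult:
    """Greedy alternating subtree-rotation sweep minimising entanglement.

    Each sweep visits every internal node of tree 1 then tree 2 and flips
    its children iff the entanglement strictly decreases; sweeps repeat
    until none flips or ``max_iter`` is reached.  Merge heights are never
    touched, so the cophenetic correlation is invariant.
    """
    a, b = d1.copy(), d2.copy()
    e_before = entanglement(a.leaf_order(), b.leaf_order())
    e = e_before
    for _ in range(max_iter):
        changed = False
        for tree in (a, b):
            for k in range(len(tree.merges)):
                tree.flip(k)
                e_new = entanglement(a.leaf_order(), b.leaf_order())
                if e_new < e:
                    e = e_new
                    changed = True
                else:
                    tree.flip(k)
        if not changed:
            break
    coph = cophenetic_correlation(a, b) if a.n_leaves >= 3 else float("nan")
    return TanglegramResult(
        cophenetic_r=coph,
        entanglement_before=e_before,
        entanglement_after=e,
        order1=a.leaf_order(),
        order2=b.leaf_order(),
        tree1=a,
        tree2=b,
    )


def robinson_foulds(d1: Dendrogram, d2: Dendrogram) -> int:
    """Symmetric clade-set difference between two rooted trees on one leaf set."""
    if set(d1.leaves) != set(d2.leaves):
        raise ValueError("dendrograms have different leaf sets")
    full = frozenset(d1.leaves)
    c1 = {c for c in d1.clades() if c != full}
    c2 = {c for c in d2.clades() if c != full}
    return len(c1 ^ c2)


# ---------------------------------------------------------------------------
# High-level comparisons


def _stratum_tree(ds: MammalDataset, probes, linkage: str, tissue=None, sex=None
                  ) -> Dendrogram:
    M = species_mean_matrix(ds, probes, tissue=tissue, sex=sex)
    if M.isna().any().any():
        M = M.dropna(axis=1)  # drop probes missing in any species
    D = euclidean_distances(M)
    return hierarchical_cluster(D, labels=list(M.index), linkage=linkage)


def tissue_concordance(ds: MammalDataset, probes, reference: str = "Blood",
                       others=("Liver", "Adipose", "Muscle"),
                       linkage: str = "average", species=None) -> pd.DataFrame:
    """Reference-tissue tree vs each other tissue: cophenetic r + entanglement.

    ``species`` optionally restricts to a representative species subset.
    Returns one row per comparison with the Newick of both (untangled) trees.
    """
    if species is not None:
        keep = ds.samples.index[ds.samples["species"].isin(list(species))]
        ds = ds.subset_samples(list(keep))
    ref_tree = _stratum_tree(ds, probes, linkage, tissue=reference)
    rows = []
    for tissue in others:
        other_tree = _stratum_tree(ds, probes, linkage, tissue=tissue)
        res = untangle(ref_tree, other_tree)
        rows.append({
            "reference": reference, "tissue": tissue,
            "cophenetic_r": res.cophenetic_r,
            "entanglement_before": res.entanglement_before,
            "entanglement_after": res.entanglement_after,
            "rf_distance": robinson_foulds(ref_tree, other_tree),
            "newick_reference": res.tree1.to_newick(),
            "newick_tissue": res.tree2.to_newick(),
        })
    return pd.DataFrame(rows)


def sex_concordance(ds: MammalDataset, probes, tissue: str | None = None,
                    linkage: str = "average") -> TanglegramResult:
    """Female-tree vs male-tree tanglegram on species mean methylation."""
    t_f = _stratum_tree(ds, probes, linkage, tissue=tissue, sex="F")
    t_m = _stratum_tree(ds, probes, linkage, tissue=tissue, sex="M")
    if set(t_f.leaves) != set(t_m.leaves):
        shared = sorted(set(t_f.leaves) & set(t_m.leaves))
        raise ValueError(f"sexes cover different species; shared = {shared}")
    return untangle(t_f, t_m)


def tanglegram_text(result: TanglegramResult, width: int = 60) -> str:
    """Two-column text tanglegram: left/right leaf orders + connection map."""
    left = result.order1
    r2 = {lab: i for i, lab in enumerate(result.order2)}
    w = max(len(s) for s in left) + 2
    lines = [
        f"cophenetic r = {result.cophenetic_r:.4f}   "
        f"entanglement {result.entanglement_before:.3f} -> {result.entanglement_after:.3f}",
        "-" * width,
    ]
    for i, lab in enumerate(left):
        j = r2[lab]
        marker = "──" if i == j else f"→{j - i:+d}"
        lines.append(f"{lab:<{w}}{marker:>6}  {result.order2[i]}")
    return "\n".join(lines)
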