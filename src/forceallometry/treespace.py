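"""Phylogenetic uncertainty in tree space.

An ensemble of candidate phylogenies (for example a Bayesian posterior
sample) is mapped into a Euclidean space with the Kendall-Colijn encoding:
for every unordered tip pair the root-to-MRCA depth, either counted in edges
(topology) or summed in branch lengths, plus one pendant-edge entry per tip.
A mixing parameter ``mix`` in [0, 1] interpolates between the purely
topological (0) and purely branch-length (1) encodings. Pairwise Euclidean
distances between encodings are projected onto principal coordinates,
clustered (partitioning around medoids), and each cluster is summarised by
its geometric-median tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform


def normalise_label(label: str) -> str:
    """Newick/Nexus tip labels: underscores and spaces are interchangeable."""
    return label.strip().replace(" ", "_")


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

@dataclass
class TreeEnsemble:
    """Rooted trees with branch lengths sharing one tip-label set."""

    trees: list[dendropy.Tree]
    source: str = ""
    subsample_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("empty tree ensemble")
        ref = self.tip_labels
        for i, t in enumerate(self.trees):
            labels = frozenset(normalise_label(x.taxon.label)
                               for x in t.leaf_node_iter())
            if labels != ref:
                diff = labels.symmetric_difference(ref)
                raise ValueError(
                    f"tree {i} tip set differs from tree 0: {sorted(diff)}")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(normalise_label(x.taxon.label)
                         for x in self.trees[0].leaf_node_iter())

    @classmethod
    def from_file(cls, path, schema: Optional[str] = None,
                  subsample_rate: float = 1.0) -> "TreeEnsemble":
        """Load a Newick or Nexus multi-tree file (schema from extension)."""
        path = str(path)
        if schema is None:
            schema = ("nexus" if path.lower().endswith((".nex", ".nexus", ".trees"))
                      else "newick")
        trees = dendropy.TreeList.get(path=path, schema=schema,
                                      rooting="default-rooted")
        kept = list(trees)
        if subsample_rate < 1.0:
            step = max(1, round(1.0 / subsample_rate))
            kept = kept[::step]
        return cls(kept, source=path, subsample_rate=subsample_rate)

    def pruned_to(self, species: Sequence[str]) -> "TreeEnsemble":
        """Restrict every tree to ``species`` (normalised label match)."""
        wanted = {normalise_label(s) for s in species}
        missing = wanted - self.tip_labels
        if missing:
            raise ValueError(f"species absent from trees: {sorted(missing)}")
        pruned = []
        for t in self.trees:
            c = t.clone(depth=1)
            keep = [lf.taxon for lf in c.leaf_node_iter()
                    if normalise_label(lf.taxon.label) in wanted]
            c.retain_taxa(keep)
            pruned.append(c)
        return TreeEnsemble(pruned, source=self.source,
                            subsample_rate=self.subsample_rate)


# ---------------------------------------------------------------------------
# depth tables shared by the KC encoding and phylogenetic covariances
# ---------------------------------------------------------------------------

def depth_tables(tree: dendropy.Tree):
    """Root-to-MRCA depth matrices for all tip pairs of a rooted tree.

    Returns ``(labels, topo, length, pendant)`` where ``labels`` is the
    lexicographically sorted tip-label list, ``topo[i, j]``/``length[i, j]``
    the edge-count/branch-length depth of the MRCA of tips i and j (diagonal:
    the tip's own depth) and ``pendant[i]`` the tip's pendant edge length.
    """
    if tree.is_rooted is not True:
        raise ValueError("Kendall-Colijn encoding requires a rooted tree")
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 tips")
    labels = sorted(normalise_label(lf.taxon.label) for lf in leaves)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)

    topo = np.zeros((n, n))
    length = np.zeros((n, n))
    pendant = np.zeros(n)

    depth_t: dict[int, int] = {}
    depth_l: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth_t[id(node)] = 0
            depth_l[id(node)] = 0.0
        else:
            el = node.edge.length or 0.0
            depth_t[id(node)] = depth_t[id(node.parent_node)] + 1
            depth_l[id(node)] = depth_l[id(node.parent_node)] + el
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[normalise_label(node.taxon.label)]
            below[id(node)] = [i]
            topo[i, i] = depth_t[id(node)]
            length[i, i] = depth_l[id(node)]
            pendant[i] = node.edge.length or 0.0
        else:
            kids = [below[id(c)] for c in node.child_nodes()]
            dt, dl = depth_t[id(node)], depth_l[id(node)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            topo[i, j] = topo[j, i] = dt
                            length[i, j] = length[j, i] = dl
            below[id(node)] = [i for kid in kids for i in kid]
    return labels, topo, length, pendant


def kc_vector(tree: dendropy.Tree, mix: float = 0.0) -> np.ndarray:
    """Kendall-Colijn encoding of a rooted tree at mixing parameter ``mix``."""
    if not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    labels, topo, length, pendant = depth_tables(tree)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    pair_part = (1.0 - mix) * topo[iu] + mix * length[iu]
    pend_part = (1.0 - mix) * np.ones(n) + mix * pendant
    return np.concatenate([pair_part, pend_part])


def kc_distance(t1: dendropy.Tree, t2: dendropy.Tree, mix: float = 0.0) -> float:
    """Euclidean distance between the KC encodings of two trees."""
    l1 = frozenset(normalise_label(x.taxon.label) for x in t1.leaf_node_iter())
    l2 = frozenset(normalise_label(x.taxon.label) for x in t2.leaf_node_iter())
    if l1 != l2:
        raise ValueError(
            f"tip sets differ: {sorted(l1.symmetric_difference(l2))}")
    return float(np.linalg.norm(kc_vector(t1, mix) - kc_vector(t2, mix)))


# ---------------------------------------------------------------------------
# projection, clustering, median trees
# ---------------------------------------------------------------------------

@dataclass
class TreespaceProjection:
    coordinates: np.ndarray            # (n_trees, n_axes)
    variance_fractions: np.ndarray     # per retained axis
    cluster_labels: np.ndarray         # (n_trees,) int
    median_tree_ids: dict[int, int] = field(default_factory=dict)
    k: int = 1


def _pam(D: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic: greedy BUILD initialisation followed by full SWAP passes.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.array([np.minimum(current, D[:, c]).sum()
                          if c not in medoids else np.inf for c in range(n)])
        medoids.append(int(np.argmin(gains)))
    cost = D[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = D[:, trial].min(axis=1).sum()
                if c < cost - 1e-12:
                    medoids, cost, improved = trial, c, True
        if not improved:
            break
    return np.argmin(D[:, medoids], axis=1)


def project_and_cluster(ensemble: TreeEnsemble, mix: float = 0.0,
                        n_axes: int = 2, k: Optional[int] = None,
                        k_range: Sequence[int] = range(2, 7),
                        ) -> TreespaceProjection:
    """Principal-coordinate projection and PAM clustering of an ensemble.

    ``k=None`` selects the cluster count by silhouette width over
    ``k_range``, preferring 4 on exact ties. A degenerate (all-identical)
    ensemble yields one cluster and zero variance, without error.
    """
    vectors = np.array([kc_vector(t, mix) for t in ensemble.trees])
    n = len(ensemble)
    D = squareform(pdist(vectors))

    if not np.any(D > 1e-12):
        return TreespaceProjection(
            coordinates=np.zeros((n, n_axes)),
            variance_fractions=np.zeros(n_axes),
            cluster_labels=np.zeros(n, dtype=int),
            median_tree_ids={0: 0}, k=1)

    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa
    ord_res = pcoa(DistanceMatrix(D), number_of_dimensions=max(n_axes, 2))
    coords = np.asarray(ord_res.samples.iloc[:, :n_axes])
    var_frac = np.asarray(ord_res.proportion_explained[:n_axes])

    if k is None:
        from sklearn.metrics import silhouette_score
        scores: dict[int, float] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        for kk in k_range:
            if kk >= n:
                continue
            lab = _pam(D, kk)
            if len(np.unique(lab)) < 2:
                continue
            labels_by_k[kk] = lab
            scores[kk] = silhouette_score(D, lab, metric="precomputed")
        if not scores:
            k, labels = 1, np.zeros(n, dtype=int)
        else:
            best = max(scores.values())
            tied = [kk for kk, s in scores.items() if abs(s - best) < 1e-12]
            k = 4 if 4 in tied else tied[0]
            labels = labels_by_k[k]
    else:
        labels = _pam(D, k) if k > 1 else np.zeros(n, dtype=int)

    medians = {}
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        within = D[np.ix_(members, members)].sum(axis=1)
        medians[int(g)] = int(members[np.argmin(within)])
    return TreespaceProjection(coordinates=coords, variance_fractions=var_frac,
                               cluster_labels=labels, median_tree_ids=medians,
                               k=int(k))


def topological_diff(tree: dendropy.Tree, reference: dendropy.Tree,
                     ) -> set[frozenset[str]]:
    """Clades (tip subsets) present in exactly one of the two rooted trees."""
    l1 = frozenset(normalise_label(x.taxon.label) for x in tree.leaf_node_iter())
    l2 = frozenset(normalise_label(x.taxon.label)
                   for x in reference.leaf_node_iter())
    if l1 != l2:
        raise ValueError(
            f"tip sets differ: {sorted(l1.symmetric_difference(l2))}")
    n = len(l1)

    def clades(t: dendropy.Tree) -> set[frozenset[str]]:
        out = set()
        below: dict[int, frozenset[str]] = {}
        for node in t.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = frozenset([normalise_label(node.taxon.label)])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
                below[id(node)] = s
                if 1 < len(s) < n:
                    out.add(s)
        return out

    return clades(tree).symmetric_difference(clades(reference))
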