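"""Comparing distance matrices: site aggregation, Mantel tests, UPGMA trees.

The site-level immunological matrix is the mean mouse-pair distance between
sites. Mantel tests correlate two distance matrices over their unique
off-diagonal pairs, with significance from seeded label permutations
(one-tailed by default, add-one p so p > 0 always). Geographic distances may
be log(d + 1)-transformed before testing, since inter-site distances are
right-skewed. UPGMA trees (average-linkage, ultrametric, node heights half
the merge distance) support tanglegram-style comparison of the immune,
genetic and geographic structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n_entities: int
    tail: str
    transform: str


def among_site_distance(
    dm_mice: DistanceMatrix,
    sites: Mapping[str, str],
) -> DistanceMatrix:
    """Mean between-site mouse-pair distance, as a site x site matrix."""
    by_site: dict[str, list[int]] = {}
    for i, m in enumerate(dm_mice.ids):
        if m not in sites:
            raise KeyError(f"mouse {m!r} has no site label")
        by_site.setdefault(sites[m], []).append(i)
    names = sorted(by_site)
    if any(len(v) == 0 for v in by_site.values()):
        raise ValueError("empty site")
    k = len(names)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            block = dm_mice.data[np.ix_(by_site[names[i]], by_site[names[j]])]
            out[i, j] = out[j, i] = float(block.mean())
    return DistanceMatrix(out, ids=names)


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    transform: str = "none",
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    ``transform='log1p'`` applies log(d + 1) element-wise to ``b`` (the
    convention for a skewed geographic matrix). ``tail`` is 'greater'
    (one-tailed on r, the default) or 'two-sided' (on |r|). Permutations
    relabel the entities of ``b``; p uses the add-one convention
    (1 + hits) / (n_perm + 1).
    """
    if list(a.ids) != list(b.ids):
        raise ValueError("matrices must share labels in the same order")
    n = len(a.ids)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 entities")
    if transform not in ("none", "log1p"):
        raise ValueError("transform must be 'none' or 'log1p'")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    av = a.data
    bv = np.log1p(b.data) if transform == "log1p" else b.data
    x = _offdiag(av)
    y = _offdiag(bv)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = _offdiag(bv[np.ix_(perm, perm)])
        r_perm = float(np.corrcoef(x, y_perm)[0, 1])
        if tail == "greater":
            if r_perm >= r_obs - 1e-12:
                hits += 1
        else:
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                hits += 1
    return MantelResult(
        r=r_obs,
        p=(hits + 1) / (n_perm + 1),
        n_perm=n_perm,
        n_entities=n,
        tail=tail,
        transform=transform,
    )


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree; ultrametric, heights = merge distance / 2.

    Ties are broken deterministically by the smallest-index order of the
    underlying linkage algorithm over the label-sorted input.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 taxa")
    order = sorted(range(n), key=lambda i: ids[i])
    data = dm.data[np.ix_(order, order)]
    labels = [ids[i] for i in order]
    if n == 2:
        h = data[0, 1] / 2.0
        tree = TreeNode(children=[
            TreeNode(name=labels[0], length=h),
            TreeNode(name=labels[1], length=h),
        ])
        return tree
    Z = _average_linkage(squareform(data, checks=False))
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=labels[i]), 0.0) for i in range(n)
    }
    for step, (left, right, dist, _count) in enumerate(Z):
        height = dist / 2.0
        l_node, l_h = nodes.pop(int(left))
        r_node, r_h = nodes.pop(int(right))
        l_node.length = height - l_h
        r_node.length = height - r_h
        nodes[n + step] = (TreeNode(children=[l_node, r_node]), height)
    root, _ = nodes.popitem()[1]
    return root


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a tree, as a DistanceMatrix."""
    return tree.tip_tip_distances()


def leaf_order_mismatch(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Count of shared leaves whose rank order differs between two trees.

    A cheap tanglegram summary: 0 means the untangled leaf orders already
    agree; larger values mean more crossings are unavoidable.
    """
    order_a = [t.name for t in tree_a.tips()]
    order_b = [t.name for t in tree_b.tips()]
    shared = set(order_a) & set(order_b)
    a_rank = {name: i for i, name in enumerate(n for n in order_a if n in shared)}
    b_rank = {name: i for i, name in enumerate(n for n in order_b if n in shared)}
    return sum(a_rank[n] != b_rank[n] for n in shared)
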