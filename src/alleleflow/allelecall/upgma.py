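"""UPGMA dendrograms and column-bootstrap clade support."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distance import encode, pdist_arrays, _valid_mask
from .types import AlignmentError, DistanceMatrix


@dataclass
class TreeNode:
    """Node of a rooted ultrametric dendrogram (leaf iff no children)."""

    height: float
    children: list["TreeNode"] = field(default_factory=list)
    name: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])  # type: ignore[list-item]
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.leaves()
        return out

    def walk(self):
        """Yield every node, preorder."""
        yield self
        for child in self.children:
            yield from child.walk()

    def to_newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.is_leaf:
            return f"{self.name}:{length:.6g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{length:.6g}"


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Agglomerate a distance matrix with UPGMA.

    The closest pair of clusters is merged at each step (ties broken by the
    lexicographically smallest pair of cluster keys, a cluster's key being
    its smallest leaf label); the new node's height is half the merge
    distance and distances to other clusters are member-count-weighted
    averages, which equals the unweighted mean over all original leaf
    pairs.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least two labels")
    # cluster key -> (size, node); distances in a dict keyed by frozenset
    clusters: dict[str, tuple[int, TreeNode]] = {
        label: (1, TreeNode(height=0.0, name=label)) for label in dist.labels
    }
    d: dict[frozenset[str], float] = {}
    for i, a in enumerate(dist.labels):
        for j in range(i + 1, n):
            b = dist.labels[j]
            d[frozenset((a, b))] = float(dist.values[i, j])

    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        for key in d:
            a, b = sorted(key)
            if a not in clusters or b not in clusters:
                continue
            cand = (d[key], a, b)
            if best is None or cand < best:
                best = cand
        assert best is not None
        dmin, a, b = best
        size_a, node_a = clusters.pop(a)
        size_b, node_b = clusters.pop(b)
        new_key = min(a, b)
        new_node = TreeNode(height=dmin / 2.0, children=[node_a, node_b])
        for other, (size_o, _node) in clusters.items():
            da = d.pop(frozenset((a, other)))
            db = d.pop(frozenset((b, other)))
            d[frozenset((new_key, other))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        del d[frozenset((a, b))]
        clusters[new_key] = (size_a + size_b, new_node)

    (_, root), = clusters.values()
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf sets of all internal nodes (root included, leaves excluded)."""
    return {node.leaves() for node in tree.walk() if not node.is_leaf}


def bootstrap_support(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    n_reps: int = 1000,
    seed: int = 0,
    max_retries: int = 10,
) -> dict[frozenset[str], float]:
    """Column-bootstrap support for each internal bipartition.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate is re-clustered with p-distance UPGMA and support is the
    fraction of replicate trees containing the same leaf bipartition.  A
    replicate in which some pair has no co-scored sites is redrawn, up to
    ``max_retries`` times before raising.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    items = list(alignment.items()) if isinstance(alignment, Mapping) else list(alignment)
    labels = [label for label, _ in items]
    codes = np.stack([encode(seq) for _, seq in items])
    valid = _valid_mask(codes)
    n_cols = codes.shape[1]

    base_tree = upgma(pdist_arrays(labels, codes, valid))
    targets = tree_bipartitions(base_tree)
    counts = {bip: 0 for bip in targets}

    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        for attempt in range(max_retries + 1):
            cols = rng.integers(0, n_cols, size=n_cols)
            try:
                rep_dist = pdist_arrays(labels, codes[:, cols], valid[:, cols])
            except AlignmentError:
                if attempt == max_retries:
                    raise AlignmentError(
                        f"bootstrap replicate unresolvable after {max_retries} retries"
                    )
                continue
            break
        rep_bips = tree_bipartitions(upgma(rep_dist))
        for bip in targets & rep_bips:
            counts[bip] += 1

    return {bip: counts[bip] / n_reps for bip in targets}
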