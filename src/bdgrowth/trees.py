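"""Ultrametric genealogies: Newick I/O, coalescence depths, and branch lengths.

Conventions
-----------
Depths are measured backward from the tips (the sampling instant): a tip has
depth 0, an internal node's depth is its coalescence time, and the root (the
sample MRCA) sits at the deepest coalescence.  A stem edge above the MRCA --
the portion of the coalescent point process's 0th lineage between the deepest
merge and the origin -- may be present (it is written/read as the Newick root
edge length) but is excluded from all branch-length computations: it is
ancestral to every sampled tip and belongs to no frequency class k <= n - 1.

Trees must be binary (polytomies are rejected, not resolved: silently
resolving one would fabricate coalescence times) and ultrametric within a
relative tolerance on the root-to-tip spread.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeError
from .simulate import as_rng

__all__ = [
    "GenealogyTree",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "coalescence_depths",
    "tree_from_cpp",
    "tree_from_random_merge",
    "internal_external_lengths",
    "branch_length_spectrum",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class GenealogyTree:
    """A validated rooted binary ultrametric genealogy.

    Wraps a ``dendropy.Tree``; on construction checks branch lengths, binary
    structure and ultrametricity, and caches each node's time from the root
    (excluding any stem edge) plus the common tip depth (``height``).
    """

    tree: dendropy.Tree
    ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL
    height: float = field(init=False)
    n_tips: int = field(init=False)
    _times: dict = field(init=False, repr=False)
    _tip_counts: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        root = self.tree.seed_node
        times: dict = {root: 0.0}
        tip_counts: dict = {}
        n_tips = 0
        for node in self.tree.preorder_node_iter():
            children = node.child_nodes()
            if node is not root:
                if node.edge.length is None:
                    raise TreeError(
                        f"edge above {_node_name(node)} has no branch length"
                    )
                times[node] = times[node.parent_node] + float(node.edge.length)
            if children:
                if len(children) != 2:
                    raise TreeError(
                        f"node {_node_name(node)} has {len(children)} children; "
                        "only binary trees are supported (polytomies rejected)"
                    )
            else:
                n_tips += 1
        if n_tips < 2:
            raise TreeError(f"a genealogy needs >= 2 tips, got {n_tips}")
        for node in self.tree.postorder_node_iter():
            children = node.child_nodes()
            tip_counts[node] = (
                1 if not children else sum(tip_counts[c] for c in children)
            )
        tip_times = np.array(
            [times[leaf] for leaf in self.tree.leaf_node_iter()], dtype=float
        )
        height = float(np.max(tip_times))
        spread = float(np.max(tip_times) - np.min(tip_times))
        if spread > self.ultrametric_rtol * max(height, 1e-300):
            worst = sorted(
                self.tree.leaf_node_iter(), key=lambda lf: times[lf]
            )
            raise TreeError(
                "tree is not ultrametric within relative tolerance "
                f"{self.ultrametric_rtol:g}: tip depths range from "
                f"{times[worst[0]]:.6g} ({_node_name(worst[0])}) to "
                f"{times[worst[-1]]:.6g} ({_node_name(worst[-1])})"
            )
        self.height = height
        self.n_tips = n_tips
        self._times = times
        self._tip_counts = tip_counts

    @property
    def stem_length(self) -> float:
        """Length of the edge above the MRCA (0 if absent)."""
        length = self.tree.seed_node.edge.length
        return 0.0 if length is None else float(length)

    def node_depth(self, node) -> float:
        """Coalescence depth of a node (time back from the tips)."""
        return self.height - self._times[node]

    def tips_below(self, node) -> int:
        return self._tip_counts[node]


def _node_name(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or "<unnamed>"


def parse_newick(
    text: str, ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> GenealogyTree:
    """Parse a Newick string into a validated :class:`GenealogyTree`.

    Branch lengths are required on every edge; internal node labels are
    ignored; a root edge length, if present, is kept as the stem.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return GenealogyTree(tree, ultrametric_rtol=ultrametric_rtol)


def read_newick_file(
    path, ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> GenealogyTree:
    with open(path) as fh:
        return parse_newick(fh.read(), ultrametric_rtol=ultrametric_rtol)


def write_newick(gt: GenealogyTree) -> str:
    """Serialize to Newick with branch lengths at 17 significant digits, so
    that a parse/write round trip preserves lengths to ~1e-16 relative."""
    s = gt.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    return s.strip() + "\n"


def coalescence_depths(gt: GenealogyTree) -> np.ndarray:
    """The n - 1 coalescence depths (unordered): for each internal node,
    the common tip depth minus the node's time from the root."""
    return np.array(
        [
            gt.node_depth(node)
            for node in gt.tree.preorder_node_iter()
            if node.child_nodes()
        ],
        dtype=float,
    )


def tree_from_cpp(ordered_depths, T: float) -> GenealogyTree:
    """Ladder (coalescent point process) tree from depths in CPP order.

    The 0th lineage has height T; lineage i (height ``H_i``) attaches to the
    nearest lineage on its left whose height exceeds ``H_i``.  Tips are
    labelled ``t0 .. t{n-1}``; the stem above the MRCA has length
    ``T - max_i H_i``.  The tree's coalescence-depth multiset equals the
    input multiset.
    """
    h = np.asarray(ordered_depths, dtype=float).ravel()
    if h.size < 1:
        raise ValueError("need at least one coalescence depth")
    if np.any(h <= 0):
        raise ValueError("all depths must be > 0")
    if np.any(h >= T):
        raise TreeError(f"every depth must be below the lineage height T = {T}")

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(h.size + 1)])
    depth_of: dict = {}

    def leaf(i: int) -> dendropy.Node:
        node = dendropy.Node(taxon=taxa[i])
        depth_of[node] = 0.0
        return node

    def merge(below: dendropy.Node, right: dendropy.Node, depth: float):
        node = dendropy.Node()
        node.add_child(below)
        node.add_child(right)
        depth_of[node] = depth
        return node

    # stack of (support height, subtree root), heights strictly decreasing
    stack: list[tuple[float, dendropy.Node]] = [(float(T), leaf(0))]
    for i, hi in enumerate(h, start=1):
        current = leaf(i)
        while stack[-1][0] < hi:
            top_h, top_node = stack.pop()
            keep_h, keep_node = stack.pop()
            stack.append((keep_h, merge(keep_node, top_node, top_h)))
        stack.append((float(hi), current))
    while len(stack) > 1:
        top_h, top_node = stack.pop()
        keep_h, keep_node = stack.pop()
        stack.append((keep_h, merge(keep_node, top_node, top_h)))
    root = stack[0][1]

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            child.edge.length = depth_of[node] - depth_of[child]
    root.edge.length = float(T) - depth_of[root]
    return GenealogyTree(tree)


def tree_from_random_merge(
    depths, rng: np.random.Generator | int | None = None
) -> GenealogyTree:
    """Harris-style tree: proceed backward in time through the sorted
    coalescence times, merging two uniformly chosen lineages at each.

    Distributionally equivalent to the ladder construction when the depths
    come from the coalescent point process (the merge order carries no
    information about the growth rate).  No stem is attached.
    """
    h = np.sort(np.asarray(depths, dtype=float).ravel())
    if h.size < 1:
        raise ValueError("need at least one coalescence depth")
    if np.any(h <= 0):
        raise ValueError("all depths must be > 0")
    rng = as_rng(rng)
    n = h.size + 1
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    depth_of: dict = {}
    lineages = []
    for i in range(n):
        node = dendropy.Node(taxon=taxa[i])
        depth_of[node] = 0.0
        lineages.append(node)
    for depth in h:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[i], lineages[j]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        depth_of[parent] = float(depth)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(parent)
    root = lineages[0]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            child.edge.length = depth_of[node] - depth_of[child]
    return GenealogyTree(tree)


def internal_external_lengths(gt: GenealogyTree) -> tuple[float, float]:
    """Total internal and external branch length (stem excluded).

    An edge is internal if it is ancestral to >= 2 sampled tips, external if
    it subtends exactly one tip; the two sum to the total edge length below
    the MRCA.
    """
    L_in = L_ext = 0.0
    for node in gt.tree.preorder_node_iter():
        if node is gt.tree.seed_node:
            continue
        length = float(node.edge.length)
        if gt.tips_below(node) >= 2:
            L_in += length
        else:
            L_ext += length
    return L_in, L_ext


def branch_length_spectrum(gt: GenealogyTree) -> dict[int, float]:
    """Branch-length frequency spectrum ``{k: L_k}`` for k = 1 .. n - 1:
    total length of edges ancestral to exactly k sampled tips.

    ``L_1`` is the external length and ``sum_k L_k`` the total edge length
    below the MRCA.
    """
    spectrum = {k: 0.0 for k in range(1, gt.n_tips)}
    for node in gt.tree.preorder_node_iter():
        if node is gt.tree.seed_node:
            continue
        spectrum[gt.tips_below(node)] += float(node.edge.length)
    return spectrum
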