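"""Phylogeny I/O and tree computations.

Wraps :mod:`dendropy` trees with the conventions the rest of the pipeline
relies on: stable postorder clade identifiers for internal nodes, midpoint
rooting, monophyletic clade enumeration, and within-clade tip-to-tip
divergence.

A *clade* here is an internal node together with every tip descending from
it.  Clade identifiers (``node1``, ``node2``, ...) are assigned by a
deterministic postorder traversal, so re-reading the same newick file always
yields the same ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "Phylogeny",
    "Clade",
    "NewickParseError",
    "read_newick",
    "parse_newick",
    "write_newick",
    "midpoint_root",
    "enumerate_clades",
    "clade_divergence",
]

_BLEN_FMT = "%.10g"


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


@dataclass
class Clade:
    """A monophyletic clade: an internal node plus all its descendant tips."""

    clade_id: str
    tip_set: frozenset[str]
    mean_tip_distance: float | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_set)


@dataclass
class Phylogeny:
    """A rooted phylogeny whose tips are ASV identifiers.

    Thin wrapper around a :class:`dendropy.Tree`.  Internal nodes carry a
    stable ``clade_id`` attribute assigned in postorder; tips keep their
    taxon labels.
    """

    tree: dendropy.Tree
    _clade_ids_assigned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self._assign_clade_ids()

    # -- identifiers ----------------------------------------------------

    def _assign_clade_ids(self) -> None:
        """Number internal nodes node1..nodeK in postorder.

        Postorder over a fixed child order is invariant under newick
        round-trips, so ids are reproducible across runs and processes.
        """
        k = 0
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.clade_id = None
            else:
                k += 1
                node.clade_id = f"node{k}"
        self._clade_ids_assigned = True
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels in tree")

    # -- basic accessors ------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in postorder (stable)."""
        return [n.taxon.label for n in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def internal_nodes(self) -> Iterator[dendropy.Node]:
        for node in self.tree.postorder_node_iter():
            if not node.is_leaf():
                yield node

    def total_branch_length(self) -> float:
        return sum(
            e.length for e in self.tree.preorder_edge_iter() if e.length is not None
        )

    def prune_to(self, keep: Sequence[str], on_extra: str = "error") -> "Phylogeny":
        """Restrict the tree to the tips in ``keep``.

        Tips present in the tree but not in ``keep`` are pruned with a
        warning (mirroring guide-sequence removal).  Tips requested but
        absent from the tree raise by default; pass ``on_extra="warn"`` to
        drop them instead.
        """
        keep_set = set(keep)
        have = set(self.tip_labels)
        missing = keep_set - have
        if missing:
            msg = f"{len(missing)} requested tip(s) absent from tree: " + ", ".join(
                sorted(missing)[:5]
            )
            if on_extra == "error":
                raise KeyError(msg)
            warnings.warn(msg)
        drop = have - keep_set
        tree = self.tree.clone(depth=1)
        if drop:
            warnings.warn(f"pruning {len(drop)} tip(s) not in the count table")
            taxa = [t for t in tree.taxon_namespace if t.label in drop]
            tree.prune_taxa(taxa)
        return Phylogeny(tree)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


# -- I/O ------------------------------------------------------------------


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise NewickParseError("malformed newick: unlabelled tip")
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def newick_string(phy: Phylogeny) -> str:
    """Serialise with fixed float formatting so output is byte-stable."""
    out = StringIO()
    phy.tree.write(
        file=out,
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    return out.getvalue()


def write_newick(phy: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(phy))


# -- midpoint rooting ------------------------------------------------------


def _adjacency(tree: dendropy.Tree) -> dict:
    """Undirected node adjacency with branch lengths (the unrooted view)."""
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, bl))
            adj.setdefault(child, []).append((node, bl))
    return adj


def _distances_from(adj: dict, start) -> tuple[dict, dict]:
    dist, parent = {start: 0.0}, {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                parent[v] = u
                stack.append(v)
    return dist, parent


def midpoint_root(phy: Phylogeny) -> Phylogeny:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    The diameter endpoints are found by the standard double sweep (farthest
    tip from an arbitrary tip, then farthest tip from that); the midpoint of
    a tree metric is unique, so the operation is idempotent.  The two
    diameter tips end up equidistant from the root and total branch length
    is conserved.  Trees whose branch lengths are all zero are returned
    unchanged with a warning, since no midpoint is defined.
    """
    if phy.n_tips < 2:
        raise ValueError("midpoint rooting needs at least 2 tips")
    if phy.total_branch_length() <= 0:
        warnings.warn("all branch lengths are zero; tree returned unrooted")
        return phy
    tree = phy.tree.clone(depth=1)
    adj = _adjacency(tree)
    leaves = [n for n in adj if n.is_leaf()]
    # double sweep; ties broken by taxon label for determinism
    d0, _ = _distances_from(adj, leaves[0])
    tip_a = max(leaves, key=lambda n: (d0[n], n.taxon.label))
    da, parent_a = _distances_from(adj, tip_a)
    tip_b = max(leaves, key=lambda n: (da[n], n.taxon.label))
    half = da[tip_b] / 2.0

    # walk the diameter path from tip_a until the midpoint
    path = [tip_b]
    while path[-1] is not tip_a:
        path.append(parent_a[path[-1]])
    path.reverse()  # tip_a .. tip_b
    cum = 0.0
    tol = 1e-12 * max(da[tip_b], 1.0)
    for u, v in zip(path, path[1:]):
        w = next(wt for nb, wt in adj[u] if nb is v)
        if cum + w >= half - tol:
            offset = half - cum  # distance from u along (u, v)
            if offset <= tol:
                _reroot_at(tree, node=u)
            elif offset >= w - tol:
                _reroot_at(tree, node=v)
            else:
                _reroot_at(tree, edge_pair=(u, v), offset=offset, length=w)
            break
        cum += w
    tree.is_rooted = True
    if tree.seed_node.edge.length is None:
        tree.seed_node.edge.length = 0.0
    return Phylogeny(tree)


def _reroot_at(tree: dendropy.Tree, node=None, edge_pair=None, offset=None, length=None):
    """Reroot at a node, or inside the edge between two adjacent nodes."""
    if node is not None:
        if node is tree.seed_node:
            return
        tree.reroot_at_node(node, update_bipartitions=False)
        tree.suppress_unifurcations()
        return
    u, v = edge_pair
    child = v if v.parent_node is u else u
    from_parent = offset if child is v else length - offset
    tree.reroot_at_edge(
        child.edge,
        length1=from_parent,
        length2=length - from_parent,
        update_bipartitions=False,
    )
    tree.suppress_unifurcations()


# -- clade enumeration and divergence -------------------------------------


def enumerate_clades(
    phy: Phylogeny, min_tips: int = 2, with_divergence: bool = False
) -> list[Clade]:
    """List monophyletic clades (internal nodes, root included) in postorder.

    Only internal nodes subtending at least ``min_tips`` tips are reported;
    the default of 2 reflects that a single tip is not a clade for the core
    test.  ``with_divergence`` also fills in the mean pairwise tip-to-tip
    path length per clade.
    """
    clades: list[Clade] = []
    tipsets: dict[int, frozenset[str]] = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = frozenset([node.taxon.label])
            continue
        tips: frozenset[str] = frozenset().union(
            *(tipsets[id(c)] for c in node.child_nodes())
        )
        tipsets[id(node)] = tips
        if len(tips) >= min_tips:
            clades.append(Clade(clade_id=node.clade_id, tip_set=tips))
    if with_divergence:
        div = _all_clade_divergences(phy, min_tips=min_tips)
        for c in clades:
            c.mean_tip_distance = div[c.clade_id]
    return clades


def clade_divergence(phy: Phylogeny, clade: Clade | str) -> float:
    """Mean tip-to-tip path length over all unordered tip pairs in a clade."""
    clade_id = clade.clade_id if isinstance(clade, Clade) else clade
    div = _all_clade_divergences(phy, min_tips=2)
    if clade_id not in div:
        raise ValueError(f"clade {clade_id!r} has fewer than 2 tips or is unknown")
    return div[clade_id]


def _all_clade_divergences(phy: Phylogeny, min_tips: int = 2) -> dict[str, float]:
    """Mean pairwise tip distance for every internal node in one postorder pass.

    For a node with children subtrees we combine, per child c, the pair
    ``(n_c, S_c)`` = (tip count, sum over tips of root-path length to c's
    attachment).  Cross-child pair path lengths decompose as
    ``d(u,v) = depth_u + depth_v`` measured from the node, which lets the
    sum over all pairs be accumulated without enumerating pairs.
    """
    out: dict[str, float] = {}
    stats: dict[int, tuple[int, float, float]] = {}  # id -> (n, sum_depth, pair_sum)
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (1, 0.0, 0.0)
            continue
        n_tot, s_tot, pair_tot = 0, 0.0, 0.0
        for child in node.child_nodes():
            n_c, s_c, p_c = stats[id(child)]
            bl = child.edge.length or 0.0
            s_c = s_c + n_c * bl  # depths re-measured from this node
            # pairs crossing between previously merged tips and this child
            pair_tot += p_c + n_tot * s_c + n_c * s_tot
            n_tot += n_c
            s_tot += s_c
        stats[id(node)] = (n_tot, s_tot, pair_tot)
        if n_tot >= min_tips and n_tot >= 2:
            out[node.clade_id] = pair_tot / (n_tot * (n_tot - 1) / 2)
        elif n_tot >= min_tips:
            out[node.clade_id] = 0.0
    return out
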