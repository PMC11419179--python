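"""Unrooted and rooted leaf-labeled tree topologies.

Topologies are the discrete objects that subsplit Bayesian networks put
probability on.  An unrooted topology on ``N`` taxa is a connected acyclic
graph whose leaves have degree 1 and whose internal nodes have degree 3;
it has ``2N - 3`` edges.  Rooting places a degree-2 "virtual root" on one
edge, which turns the graph into a directed binary tree; the two operations
are inverse to each other and put the ``2N - 3`` edges of a topology in
bijection with its rootings.

Clades are represented throughout as integer bitmasks over the taxon set
(bit ``i`` set means taxon ``i`` is in the clade).  Topology equality is
defined by equality of nontrivial split sets, which is label-invariant and
canonical for bifurcating trees.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "UnrootedTopology",
    "RootedTopology",
    "parse_newick",
    "write_newick",
    "enumerate_unrooted",
    "root_at_edge",
    "unroot",
    "n_unrooted_topologies",
    "read_weighted_trees",
    "write_weighted_trees",
]


class TaxonSet:
    """An ordered collection of distinct taxon names.

    The ordering fixes the bitmask representation of clades: taxon ``i``
    corresponds to bit ``i``.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str]):
        self.labels = tuple(str(x) for x in labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")
        if len(self.labels) < 2:
            raise ValueError("need at least two taxa")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, label) -> bool:
        return label in self._index

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown taxon label {label!r}") from None

    def label(self, i: int) -> str:
        return self.labels[i]

    @property
    def full_mask(self) -> int:
        return (1 << len(self.labels)) - 1

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self.index(lab)
        return m

    def names(self, mask: int) -> tuple[str, ...]:
        """Labels contained in a clade bitmask, in taxon order."""
        return tuple(self.labels[i] for i in range(len(self.labels)) if mask >> i & 1)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({list(self.labels)!r})"


def _ordered_pair(a: int, b: int) -> tuple[int, int]:
    # Total order on clades: bitmask value, descending.  Any strict total
    # order works; this one is fast and deterministic.
    return (a, b) if a > b else (b, a)


class UnrootedTopology:
    """An unrooted bifurcating leaf-labeled tree topology.

    Nodes are integers: leaves ``0..N-1`` (equal to the taxon index) and
    internal nodes ``N..2N-3``.  Edges carry stable integer ids ``0..2N-4``
    assigned by sorting edges on the bitmask of the edge side that does not
    contain taxon 0; the ids therefore depend only on the topology and
    survive serialization round trips.
    """

    __slots__ = ("taxa", "_adj", "_edges", "_side", "_splits", "_hash")

    def __init__(self, taxa: TaxonSet, adjacency: Sequence[Iterable[int]]):
        n = len(taxa)
        if n < 3:
            raise ValueError("unrooted topologies need at least 3 taxa")
        n_nodes = 2 * n - 2
        adj = tuple(tuple(sorted(neigh)) for neigh in adjacency)
        if len(adj) != n_nodes:
            raise ValueError(f"expected {n_nodes} nodes, got {len(adj)}")
        for u, neigh in enumerate(adj):
            deg = 1 if u < n else 3
            if len(neigh) != deg:
                raise ValueError(f"node {u} has degree {len(neigh)}, expected {deg}")
            for v in neigh:
                if not 0 <= v < n_nodes or u not in adj[v]:
                    raise ValueError("adjacency is not symmetric")
        self.taxa = taxa
        self._adj = adj

        # Post-order pass from leaf 0 to get the leaf mask below every
        # directed edge; the reverse direction is the complement.
        parent: dict[int, int | None] = {0: None}
        topo: list[int] = []
        stack = [0]
        while stack:
            u = stack.pop()
            topo.append(u)
            for v in adj[u]:
                if v != parent.get(u):
                    parent[v] = u
                    stack.append(v)
        if len(topo) != n_nodes:
            raise ValueError("topology graph is not connected")
        full = taxa.full_mask
        below = [0] * n_nodes
        for u in reversed(topo):
            below[u] = (1 << u) if u < n else 0
            for v in adj[u]:
                if v != parent[u] and parent.get(v) == u:
                    below[u] |= below[v]
        side: dict[tuple[int, int], int] = {}
        for u in topo[1:]:
            p = parent[u]
            side[(p, u)] = below[u]
            side[(u, p)] = full ^ below[u]
        self._side = side

        edges = []
        for (u, v), m in side.items():
            if u < v:  # one record per undirected edge
                if m & 1:  # canonical side excludes taxon 0
                    edges.append((full ^ m, v, u))
                else:
                    edges.append((m, u, v))
        edges.sort()
        self._edges = tuple((u, v) for _, u, v in edges)
        self._splits = frozenset(
            m for m, _, _ in edges
            if m.bit_count() >= 2 and (full ^ m).bit_count() >= 2
        )
        self._hash = hash((self.taxa, self._splits))

    # -- basic accessors ------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    @property
    def n_edges(self) -> int:
        return 2 * len(self.taxa) - 3

    @property
    def edge_ids(self) -> range:
        return range(self.n_edges)

    def edge_nodes(self, e: int) -> tuple[int, int]:
        """The two endpoints of edge ``e``."""
        return self._edges[e]

    def edge_split(self, e: int) -> int:
        """Canonical split of edge ``e``: the side not containing taxon 0."""
        u, v = self._edges[e]
        return self._side[(u, v)]

    def clade_below(self, u: int, v: int) -> int:
        """Leaf bitmask of the subtree on the ``v`` side of edge (u, v)."""
        return self._side[(u, v)]

    def neighbors(self, u: int) -> tuple[int, ...]:
        return self._adj[u]

    @property
    def splits(self) -> frozenset[int]:
        """Nontrivial splits (internal-edge bipartitions), canonical side."""
        return self._splits

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, UnrootedTopology)
            and self.taxa == other.taxa
            and self._splits == other._splits
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"UnrootedTopology({write_newick(self)!r})"

    # -- conversions ----------------------------------------------------

    def root_at_edge(self, e: int) -> "RootedTopology":
        return root_at_edge(self, e)

    def newick(self) -> str:
        return write_newick(self)


class RootedTopology:
    """A rooted bifurcating topology, stored as its clade decomposition.

    ``clades`` maps every non-singleton clade bitmask to the ordered pair
    of child clades it splits into; the entry for the full taxon set is the
    root subsplit.  This representation is canonical: two rooted topologies
    are equal iff the mappings are equal.
    """

    __slots__ = ("taxa", "clades", "_hash")

    def __init__(self, taxa: TaxonSet, clades: dict[int, tuple[int, int]]):
        full = taxa.full_mask
        if full not in clades:
            raise ValueError("missing root clade")
        if len(clades) != len(taxa) - 1:
            raise ValueError("wrong number of clades for a bifurcating tree")
        for mask, (w, z) in clades.items():
            if w & z or (w | z) != mask or not w or not z or w <= z:
                raise ValueError(f"invalid subsplit {(w, z)} of clade {mask}")
            for comp in (w, z):
                if comp.bit_count() >= 2 and comp not in clades:
                    raise ValueError(f"non-singleton clade {comp} has no subsplit")
        self.taxa = taxa
        self.clades = dict(clades)
        self._hash = hash((taxa, frozenset(clades.items())))

    @property
    def root_subsplit(self) -> tuple[int, int]:
        return self.clades[self.taxa.full_mask]

    def children_of(self, mask: int) -> tuple[int, int]:
        return self.clades[mask]

    def unroot(self) -> UnrootedTopology:
        return unroot(self)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RootedTopology)
            and self.taxa == other.taxa
            and self.clades == other.clades
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"RootedTopology(root={self.root_subsplit})"


# ---------------------------------------------------------------------------
# rooting / unrooting


def root_at_edge(tau: UnrootedTopology, e: int) -> RootedTopology:
    """Insert a degree-2 root on edge ``e`` and direct edges away from it."""
    if e not in tau.edge_ids:
        raise ValueError(f"invalid edge id {e}")
    u, v = tau.edge_nodes(e)
    n = tau.n_leaves
    full = tau.taxa.full_mask
    side = tau._side
    adj = tau._adj
    clades: dict[int, tuple[int, int]] = {full: _ordered_pair(side[(u, v)], side[(v, u)])}
    stack = [(u, v), (v, u)]
    while stack:
        p, x = stack.pop()
        if x >= n:  # internal: record its subsplit and recurse
            a, b = (w for w in adj[x] if w != p)
            ma, mb = side[(x, a)], side[(x, b)]
            clades[ma | mb] = _ordered_pair(ma, mb)
            stack.append((x, a))
            stack.append((x, b))
    return RootedTopology(tau.taxa, clades)


def unroot(tau: RootedTopology) -> UnrootedTopology:
    """Suppress the degree-2 root, merging its two incident edges."""
    taxa = tau.taxa
    n = len(taxa)
    full = taxa.full_mask
    internal_masks = sorted(m for m in tau.clades if m != full)
    node_id = {m: n + i for i, m in enumerate(internal_masks)}

    def node_of(mask: int) -> int:
        if mask.bit_count() == 1:
            return mask.bit_length() - 1
        return node_id[mask]

    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]

    def connect(a: int, b: int) -> None:
        adj[a].append(b)
        adj[b].append(a)

    for mask, (w, z) in tau.clades.items():
        if mask == full:
            continue
        connect(node_of(mask), node_of(w))
        connect(node_of(mask), node_of(z))
    rw, rz = tau.clades[full]
    connect(node_of(rw), node_of(rz))
    return UnrootedTopology(taxa, adj)


# ---------------------------------------------------------------------------
# newick I/O


def write_newick(tau: UnrootedTopology) -> str:
    """Canonical newick string: trifurcation at the internal node next to
    the first taxon, subtrees ordered by their smallest taxon index.

    Two topologies on the same taxon set are equal iff their canonical
    strings are equal.
    """
    taxa = tau.taxa
    n = tau.n_leaves
    adj = tau._adj

    def sub(node: int, parent: int) -> tuple[int, str]:
        if node < n:
            return node, taxa.label(node)
        parts = sorted(sub(w, node) for w in adj[node] if w != parent)
        return parts[0][0], "(" + ",".join(s for _, s in parts) + ")"

    start = adj[0][0]
    parts = sorted(sub(w, start) for w in adj[start])
    return "(" + ",".join(s for _, s in parts) + ");"


def parse_newick(text: str, taxa: TaxonSet) -> UnrootedTopology:
    """Parse a newick tree over exactly the given taxa.

    A trifurcation at the outermost level is read as the unrooted base
    node; a bifurcating (rooted) outermost node is silently unrooted.
    Branch lengths, if present, are ignored.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"invalid newick string: {exc}") from exc
    n = len(taxa)
    seed = tree.seed_node
    if seed.is_leaf():
        raise ValueError("degenerate newick string")
    node_ids: dict[int, int] = {}
    seen: set[int] = set()
    internal_nodes = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            if nd.taxon is None:
                raise ValueError("leaf without a label")
            lab = nd.taxon.label
            if lab not in taxa:
                raise ValueError(f"unknown taxon label {lab!r}")
            i = taxa.index(lab)
            if i in seen:
                raise ValueError(f"duplicate taxon {lab!r}")
            seen.add(i)
            node_ids[id(nd)] = i
        else:
            nc = len(nd.child_nodes())
            if nd is seed:
                if nc not in (2, 3):
                    raise ValueError("outermost node must have 2 or 3 children")
            elif nc != 2:
                raise ValueError("non-binary internal node")
            internal_nodes.append(nd)
    if len(seen) != n:
        missing = set(taxa.labels) - {taxa.label(i) for i in seen}
        raise ValueError(f"newick tree is missing taxa {sorted(missing)}")

    suppress_seed = len(seed.child_nodes()) == 2
    next_id = n
    for nd in internal_nodes:
        if suppress_seed and nd is seed:
            continue
        node_ids[id(nd)] = next_id
        next_id += 1

    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]

    def connect(a: int, b: int) -> None:
        adj[a].append(b)
        adj[b].append(a)

    for nd in internal_nodes:
        if suppress_seed and nd is seed:
            continue
        for ch in nd.child_nodes():
            connect(node_ids[id(nd)], node_ids[id(ch)])
    if suppress_seed:
        a, b = seed.child_nodes()
        connect(node_ids[id(a)], node_ids[id(b)])
    return UnrootedTopology(taxa, adj)


# ---------------------------------------------------------------------------
# enumeration


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted bifurcating topologies on n taxa."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    count = 1
    for k in range(3, 2 * n - 4, 2):
        count *= k
    return count


def enumerate_unrooted(taxa: TaxonSet) -> list[UnrootedTopology]:
    """All distinct unrooted topologies on the taxon set, deterministic order.

    Generated by stepwise leaf insertion: each topology on ``k`` taxa arises
    exactly once from inserting taxon ``k`` on one edge of a topology on
    taxa ``0..k-1``, so no deduplication is needed.  Supported for
    ``3 <= N <= 9`` (135135 topologies at N=9).
    """
    n = len(taxa)
    if not 3 <= n <= 9:
        raise ValueError("enumeration supported for 3 to 9 taxa")
    out: list[UnrootedTopology] = []

    def grow(edges: list[tuple[int, int]], next_leaf: int) -> None:
        if next_leaf == n:
            adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
            for u, v in edges:
                adj[u].append(v)
                adj[v].append(u)
            out.append(UnrootedTopology(taxa, adj))
            return
        new = n + next_leaf - 2
        for i in range(len(edges)):
            u, v = edges[i]
            rest = edges[:i] + edges[i + 1:]
            grow(rest + [(u, new), (v, new), (next_leaf, new)], next_leaf + 1)

    grow([(0, n), (1, n), (2, n)], 3)
    return out


# ---------------------------------------------------------------------------
# weighted tree datasets: one "<newick>\t<weight>" per line


def read_weighted_trees(source, taxa: TaxonSet | None = None):
    """Read a weighted topology dataset from a path or file-like object.

    Each line is ``<newick>\\t<weight>``; a missing weight counts as 1.
    Weights need not be normalized.  If ``taxa`` is None it is inferred
    from the first tree (labels sorted alphabetically).

    Returns ``(taxa, [(topology, weight), ...])``.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    data = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        nwk = parts[0]
        weight = float(parts[1]) if len(parts) > 1 else 1.0
        if taxa is None:
            tmp = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
            taxa = TaxonSet(sorted(lf.taxon.label for lf in tmp.leaf_node_iter()))
        data.append((parse_newick(nwk, taxa), weight))
    if taxa is None:
        raise ValueError("empty tree dataset")
    return taxa, data


def write_weighted_trees(path, data) -> None:
    with open(path, "w") as fh:
        for tau, w in data:
            fh.write(f"{write_newick(tau)}\t{w!r}\n")
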