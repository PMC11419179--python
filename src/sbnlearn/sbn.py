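"""Subsplit Bayesian networks (SBNs) over tree topologies.

An SBN is a Bayesian network whose nodes take subsplit values: ordered
bipartitions ``(W, Z)`` of a clade with ``W`` above ``Z`` in a fixed total
order.  The splitting process of a rooted topology yields the unique
compatible assignment of subsplits to network nodes, so the network
probability of a rooted topology factorizes as the root-subsplit
probability times parent-child conditional probabilities along the way
down (the full-and-complete binary tree network, with conditional
probability sharing: one CPD value per parent-child subsplit pair,
wherever the pair occurs).  The probability of an unrooted topology is the
sum over all of its rootings — the virtual root is marginalized over the
``2N - 3`` edges.

Clades are integer bitmasks and a subsplit is a pair ``(W, Z)`` of masks
with ``W > Z`` numerically.  Clades of size <= 2 are terminal: a singleton
cannot split and a two-leaf clade splits deterministically, so neither
contributes a CPD factor.

Parameters are stored as one flat vector indexed by a
:class:`SubsplitSupport`.  The vector is laid out group-contiguously —
the root-subsplit distribution is one group, and the children of each
(parent subsplit, component clade) combination form one group — so
normalization, softmax and the EM-family updates are vectorized with
``np.reduceat`` over group boundaries.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

from .trees import (
    RootedTopology,
    TaxonSet,
    UnrootedTopology,
    _ordered_pair,
    unroot,
)

__all__ = [
    "OutOfSupportError",
    "Subsplit",
    "SubsplitAssignment",
    "SubsplitSupport",
    "CPDTable",
    "LatentParams",
    "decompose",
    "compose",
    "build_support",
    "latent_to_cpd",
    "rooted_log_prob",
    "unrooted_prob",
    "unrooted_log_prob",
    "sample_topology",
    "simple_average_cpds",
    "subsplit_str",
]

#: A subsplit is an ordered pair of disjoint clade bitmasks (W, Z), W > Z.
Subsplit = tuple[int, int]

ROOT_KEY = ("root",)


class OutOfSupportError(ValueError):
    """A topology uses a subsplit the support has never observed."""


def subsplit_str(ss: Subsplit, taxa: TaxonSet) -> str:
    w, z = ss
    return ",".join(taxa.names(w)) + "|" + ",".join(taxa.names(z))


def _parse_subsplit(text: str, taxa: TaxonSet) -> Subsplit:
    w_part, z_part = text.split("|")
    return (taxa.mask_of(w_part.split(",")), taxa.mask_of(z_part.split(",")))


class SubsplitAssignment:
    """The compatible subsplit assignment of one rooted topology.

    Wraps the clade -> subsplit mapping of a :class:`RootedTopology`; the
    two are in bijection (each rooted topology has exactly one compatible
    assignment and vice versa).
    """

    __slots__ = ("taxa", "clades")

    def __init__(self, taxa: TaxonSet, clades: dict[int, Subsplit]):
        self.taxa = taxa
        self.clades = clades

    @property
    def root_subsplit(self) -> Subsplit:
        return self.clades[self.taxa.full_mask]

    def pairs(self) -> Iterable[tuple[Subsplit, Subsplit]]:
        """Parent-child subsplit pairs (child, parent) that carry a CPD
        factor, i.e. those whose child clade has at least 3 taxa."""
        clades = self.clades
        for t in clades.values():
            for comp in t:
                if comp.bit_count() >= 3:
                    yield (clades[comp], t)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubsplitAssignment)
            and self.taxa == other.taxa
            and self.clades == other.clades
        )

    def __hash__(self) -> int:
        return hash((self.taxa, frozenset(self.clades.items())))


def decompose(tau: RootedTopology) -> SubsplitAssignment:
    """The subsplit assignment obtained by following the splitting process
    of a rooted topology from the root down to the leaves."""
    return SubsplitAssignment(tau.taxa, dict(tau.clades))


def compose(assignment: SubsplitAssignment) -> RootedTopology:
    """Inverse of :func:`decompose`."""
    return RootedTopology(assignment.taxa, dict(assignment.clades))


# ---------------------------------------------------------------------------
# support


class SubsplitSupport:
    """Observed root subsplits and parent-child subsplit pairs.

    Defines the index space of the CPD parameters: parameter ``i`` is
    either a root subsplit or a (child, parent) pair, laid out so that
    every normalization group occupies a contiguous index range.  Group 0
    is the root-subsplit distribution; each further group collects the
    observed children of one (parent subsplit, component clade)
    combination.
    """

    def __init__(
        self,
        taxa: TaxonSet,
        root_subsplits: Iterable[Subsplit],
        pairs: Iterable[tuple[Subsplit, Subsplit]],
    ):
        self.taxa = taxa
        self.root_subsplits = tuple(sorted(set(root_subsplits)))
        if not self.root_subsplits:
            raise ValueError("empty support")
        grouped: dict[tuple, set[Subsplit]] = {}
        for s, t in pairs:
            key = (t, s[0] | s[1])
            grouped.setdefault(key, set()).add(s)
        self.group_keys: list[tuple] = [ROOT_KEY] + sorted(grouped)
        members: list[tuple[Subsplit, ...]] = [self.root_subsplits]
        members += [tuple(sorted(grouped[k])) for k in self.group_keys[1:]]
        self.group_members = members

        starts = []
        child: list[Subsplit] = []
        group_of: list[int] = []
        for g, ms in enumerate(members):
            starts.append(len(child))
            child.extend(ms)
            group_of.extend([g] * len(ms))
        self.n_params = len(child)
        self.param_child = tuple(child)
        self.group_starts = np.asarray(starts, dtype=np.intp)
        self.group_of = np.asarray(group_of, dtype=np.intp)
        self.group_index = {k: g for g, k in enumerate(self.group_keys)}
        r0 = len(self.root_subsplits)
        self.root_index = {s: i for i, s in enumerate(self.root_subsplits)}
        self.pair_index: dict[tuple[Subsplit, Subsplit], int] = {}
        pos = r0
        for key, ms in zip(self.group_keys[1:], members[1:]):
            t = key[0]
            for s in ms:
                self.pair_index[(s, t)] = pos
                pos += 1

    @property
    def n_groups(self) -> int:
        return len(self.group_keys)

    def group_slice(self, g: int) -> slice:
        start = self.group_starts[g]
        end = self.group_starts[g + 1] if g + 1 < self.n_groups else self.n_params
        return slice(int(start), int(end))

    def param_label(self, i: int) -> str:
        """Human-readable label of parameter ``i`` for serialization."""
        s = self.param_child[i]
        g = int(self.group_of[i])
        if g == 0:
            return "ROOT\t" + subsplit_str(s, self.taxa)
        t = self.group_keys[g][0]
        return "COND\t" + subsplit_str(s, self.taxa) + "|" + subsplit_str(t, self.taxa)

    def index_of_root(self, s: Subsplit) -> int | None:
        return self.root_index.get(s)

    def index_of_pair(self, s: Subsplit, t: Subsplit) -> int | None:
        return self.pair_index.get((s, t))

    def assignment_indices(self, assignment: SubsplitAssignment) -> list[int] | None:
        """Parameter indices of a rooted topology's factors, or None if any
        factor is outside the support."""
        out = []
        i = self.root_index.get(assignment.root_subsplit)
        if i is None:
            return None
        out.append(i)
        for pair in assignment.pairs():
            j = self.pair_index.get(pair)
            if j is None:
                return None
            out.append(j)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubsplitSupport)
            and self.taxa == other.taxa
            and self.root_subsplits == other.root_subsplits
            and self.group_keys == other.group_keys
            and self.group_members == other.group_members
        )


def _tree_support_items(tau: UnrootedTopology):
    """Root subsplits and CPD pairs contributed by all rootings of one tree."""
    n = tau.n_leaves
    adj = tau._adj
    side = tau._side
    dir_ss: dict[tuple[int, int], Subsplit] = {}
    for v in range(n, 2 * n - 2):
        for u in adj[v]:
            a, b = (w for w in adj[v] if w != u)
            dir_ss[(u, v)] = _ordered_pair(side[(v, a)], side[(v, b)])
    roots = []
    pairs = []
    # children directly under the virtual root, one pair per rooting edge
    for (u, v) in tau._edges:
        root_ss = _ordered_pair(side[(u, v)], side[(v, u)])
        roots.append(root_ss)
        for p, x in ((u, v), (v, u)):
            if side[(p, x)].bit_count() >= 3:
                pairs.append((dir_ss[(p, x)], root_ss))
    # deeper pairs: parent at an internal node, child one level down
    for v in range(n, 2 * n - 2):
        for u in adj[v]:
            t = dir_ss[(u, v)]
            for w in adj[v]:
                if w != u and side[(v, w)].bit_count() >= 3:
                    pairs.append((dir_ss[(v, w)], t))
    return roots, pairs


def build_support(data, taxa: TaxonSet | None = None) -> SubsplitSupport:
    """Union of root subsplits and parent-child pairs over every tree in
    the dataset and every rooting (all ``2N - 3`` edges per tree).

    ``data`` is a sequence of topologies or of ``(topology, weight)``
    pairs; weights only need to be present, their values are ignored here.
    """
    trees = [d[0] if isinstance(d, tuple) else d for d in data]
    if not trees:
        raise ValueError("empty dataset")
    taxa = taxa or trees[0].taxa
    roots: set[Subsplit] = set()
    pairs: set[tuple[Subsplit, Subsplit]] = set()
    for tau in set(trees):
        r, p = _tree_support_items(tau)
        roots.update(r)
        pairs.update(p)
    return SubsplitSupport(taxa, roots, pairs)


# ---------------------------------------------------------------------------
# parameter containers


def groupwise_normalize(
    support: SubsplitSupport,
    values: np.ndarray,
    prev: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize a nonnegative vector within each support group.

    Groups with zero total mass fall back to ``prev`` (the previous CPD
    values) when given, else to the uniform distribution on the group.
    """
    values = np.asarray(values, dtype=float)
    totals = np.add.reduceat(values, support.group_starts)
    out = np.empty_like(values)
    expanded = totals[support.group_of]
    good = expanded > 0
    out[good] = values[good] / expanded[good]
    if not np.all(good):
        for g in np.nonzero(totals <= 0)[0]:
            sl = support.group_slice(int(g))
            if prev is not None:
                out[sl] = prev[sl]
            else:
                out[sl] = 1.0 / (sl.stop - sl.start)
    return out


class CPDTable:
    """Conditional probability values of an SBN, one flat vector.

    Each support group sums to one: the root group is the distribution of
    the root subsplit, and each (parent, clade) group is the conditional
    distribution of that clade's child subsplit given the parent.
    """

    def __init__(self, support: SubsplitSupport, values, validate: bool = True):
        self.support = support
        self.values = np.asarray(values, dtype=float)
        self._sampler = None
        self._log = None
        self._logpad = None
        if validate:
            if self.values.shape != (support.n_params,):
                raise ValueError("CPD vector has wrong length")
            if np.any(self.values < 0):
                raise ValueError("negative CPD value")
            totals = np.add.reduceat(self.values, support.group_starts)
            if not np.allclose(totals, 1.0, atol=1e-8):
                raise ValueError("CPD groups must each sum to 1")

    @classmethod
    def uniform(cls, support: SubsplitSupport) -> "CPDTable":
        return cls(support, groupwise_normalize(support, np.ones(support.n_params)),
                   validate=False)

    @classmethod
    def random(cls, support: SubsplitSupport, rng: np.random.Generator,
               concentration: float = 1.0) -> "CPDTable":
        """Groupwise-Dirichlet random CPDs (useful for tests)."""
        draws = rng.gamma(concentration, size=support.n_params)
        return cls(support, groupwise_normalize(support, draws), validate=False)

    def log_values(self) -> np.ndarray:
        if self._log is None:
            with np.errstate(divide="ignore"):
                self._log = np.log(self.values)
        return self._log

    def log_values_padded(self) -> np.ndarray:
        """Log values with one trailing -inf sentinel slot (out-of-support
        factors index it)."""
        if self._logpad is None:
            self._logpad = np.append(self.log_values(), -np.inf)
        return self._logpad

    def root_prob(self, s: Subsplit) -> float:
        i = self.support.root_index.get(s)
        return float(self.values[i]) if i is not None else 0.0

    def cond_prob(self, s: Subsplit, t: Subsplit) -> float:
        i = self.support.pair_index.get((s, t))
        return float(self.values[i]) if i is not None else 0.0

    # -- serialization --------------------------------------------------

    def to_tsv(self, path_or_file) -> None:
        """Write as text: ``ROOT<tab>W|Z<tab>value`` and
        ``COND<tab>Wc|Zc|Wp|Zp<tab>value`` lines, taxon names sorted
        within each clade."""
        fh = path_or_file if hasattr(path_or_file, "write") else open(path_or_file, "w")
        try:
            for i, v in enumerate(self.values):
                fh.write(f"{self.support.param_label(i)}\t{float(v)!r}\n")
        finally:
            if fh is not path_or_file:
                fh.close()

    @classmethod
    def from_tsv(cls, source, taxa: TaxonSet) -> "CPDTable":
        fh = source if hasattr(source, "read") else open(source)
        try:
            lines = fh.read().splitlines()
        finally:
            if fh is not source:
                fh.close()
        roots: dict[Subsplit, float] = {}
        pairs: dict[tuple[Subsplit, Subsplit], float] = {}
        for line in lines:
            if not line.strip():
                continue
            kind, key, val = line.split("\t")
            fields = key.split("|")
            if kind == "ROOT":
                roots[_parse_subsplit(key, taxa)] = float(val)
            elif kind == "COND":
                child = _parse_subsplit("|".join(fields[:2]), taxa)
                parent = _parse_subsplit("|".join(fields[2:]), taxa)
                pairs[(child, parent)] = float(val)
            else:
                raise ValueError(f"bad record kind {kind!r}")
        support = SubsplitSupport(taxa, roots.keys(), pairs.keys())
        values = np.empty(support.n_params)
        for s, v in roots.items():
            values[support.root_index[s]] = v
        for st, v in pairs.items():
            values[support.pair_index[st]] = v
        return cls(support, values)


class LatentParams:
    """Unconstrained pre-softmax parameters of the CPDs.

    A groupwise softmax maps any finite vector to a valid
    :class:`CPDTable`; adding a constant within one group leaves the CPDs
    unchanged.
    """

    def __init__(self, support: SubsplitSupport, phi):
        self.support = support
        self.phi = np.asarray(phi, dtype=float)
        if self.phi.shape != (support.n_params,):
            raise ValueError("latent vector has wrong length")

    @classmethod
    def zeros(cls, support: SubsplitSupport) -> "LatentParams":
        return cls(support, np.zeros(support.n_params))

    @classmethod
    def from_cpds(cls, c: CPDTable, floor: float = 1e-40) -> "LatentParams":
        """phi = log c with zero probabilities floored at ``floor``."""
        return cls(c.support, np.log(np.maximum(c.values, floor)))

    def to_cpds(self) -> CPDTable:
        return latent_to_cpd(self)


def latent_to_cpd(phi: LatentParams) -> CPDTable:
    """Groupwise softmax of the latent parameters."""
    sup = phi.support
    x = phi.phi
    m = np.maximum.reduceat(x, sup.group_starts)[sup.group_of]
    e = np.exp(x - m)
    totals = np.add.reduceat(e, sup.group_starts)[sup.group_of]
    return CPDTable(sup, e / totals, validate=False)


# ---------------------------------------------------------------------------
# probabilities


def rooted_log_prob(tau: RootedTopology, c: CPDTable) -> float:
    """Log SBN probability of a rooted topology; -inf if out of support."""
    idx = c.support.assignment_indices(decompose(tau))
    if idx is None:
        return -math.inf
    return float(c.log_values()[idx].sum())


def unrooted_log_prob(tau: UnrootedTopology, c: CPDTable) -> float:
    """Log of the rooting-marginalized probability of an unrooted topology."""
    rlp = [rooted_log_prob(tau.root_at_edge(e), c) for e in tau.edge_ids]
    return float(logsumexp(rlp))


def unrooted_prob(tau: UnrootedTopology, c: CPDTable) -> float:
    """SBN probability of an unrooted topology: the sum of its ``2N - 3``
    rooted probabilities.  Zero if every rooting is out of support."""
    return math.exp(unrooted_log_prob(tau, c))


# ---------------------------------------------------------------------------
# sampling


def _sampler_tables(c: CPDTable) -> np.ndarray:
    # one global cumulative sum; per-group tables are views into it
    if c._sampler is None:
        c._sampler = np.cumsum(c.values)
    return c._sampler


def sample_topology(c: CPDTable, rng: np.random.Generator,
                    cache: dict | None = None) -> UnrootedTopology:
    """Ancestral sampling of the SBN followed by unrooting.

    Draws the root subsplit, then recursively draws each non-terminal
    clade's child subsplit from its conditional distribution; clades of
    size two split deterministically.  ``cache`` memoizes the
    assignment-to-topology conversion across draws (repeat draws dominate
    when the CPDs are concentrated).
    """
    sup = c.support
    cum = _sampler_tables(c)

    def draw(g: int) -> Subsplit:
        sl = sup.group_slice(g)
        base = cum[sl.start - 1] if sl.start > 0 else 0.0
        total = cum[sl.stop - 1] - base
        if total <= 0:
            raise OutOfSupportError("degenerate CPD group with zero mass")
        i = int(np.searchsorted(cum[sl], base + rng.random() * total, side="right"))
        i = min(i, sl.stop - sl.start - 1)
        return sup.group_members[g][i]

    root = draw(0)
    clades: dict[int, Subsplit] = {sup.taxa.full_mask: root}
    stack = [(comp, root) for comp in root]
    while stack:
        comp, parent = stack.pop()
        k = comp.bit_count()
        if k < 2:
            continue
        if k == 2:
            hi = 1 << (comp.bit_length() - 1)
            clades[comp] = (hi, comp ^ hi)
            continue
        g = sup.group_index.get((parent, comp))
        if g is None:
            raise OutOfSupportError(
                "support has no children for a reachable parent-clade pair"
            )
        s = draw(g)
        clades[comp] = s
        stack.append((s[0], s))
        stack.append((s[1], s))
    if cache is None:
        return unroot(RootedTopology(sup.taxa, clades))
    key = frozenset(clades.items())
    tau = cache.get(key)
    if tau is None:
        tau = cache[key] = unroot(RootedTopology(sup.taxa, clades))
    return tau


# ---------------------------------------------------------------------------
# the simple average estimator


def simple_average_cpds(data, support: SubsplitSupport) -> CPDTable:
    """Simple average (SA) of empirical frequencies.

    Each tree's weight is spread uniformly over its ``2N - 3`` rootings;
    root-subsplit and parent-child occurrences are counted and normalized
    groupwise, with no further refinement.  Equivalently, these are the
    EM sufficient statistics computed with uniform root posteriors.
    Support entries never observed in the data keep probability zero
    (groups with no mass fall back to uniform).
    """
    counts = np.zeros(support.n_params)
    for item in data:
        tau, w = item if isinstance(item, tuple) else (item, 1.0)
        wr = w / tau.n_edges
        for e in tau.edge_ids:
            idx = support.assignment_indices(decompose(tau.root_at_edge(e)))
            if idx is None:
                raise OutOfSupportError("tree outside the given support")
            counts[idx] += wr
    return CPDTable(support, groupwise_normalize(support, counts), validate=False)
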