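"""Vectorized evaluation of SBN quantities over fixed topologies.

Training and KL evaluation repeatedly need, for the same topologies, the
rooted log probability of every rooting and posterior-weighted subsplit
counts.  Both reduce to gathers over the flat CPD parameter vector, so a
topology is "compiled" against a support once: for each of its rootings
we store the parameter indices of the factors in the rooted probability
(the root subsplit plus one parent-child pair per informative clade).
Factors outside the support map to a sentinel slot holding log 0, which
makes the corresponding rooting's probability zero without branching.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .sbn import CPDTable, OutOfSupportError, SubsplitSupport
from .trees import UnrootedTopology, _ordered_pair

__all__ = ["CompiledTopology", "CompiledCollection", "compile_topology"]


def _logsumexp1d(x: np.ndarray) -> float:
    # scipy's logsumexp has too much dispatch overhead for tiny arrays
    m = x.max()
    if np.isneginf(m):
        return -np.inf
    return float(m + np.log(np.exp(x - m).sum()))


def _rooting_param_indices(tau: UnrootedTopology, support: SubsplitSupport):
    """Per-rooting parameter index lists, sentinel ``n_params`` if absent."""
    n = tau.n_leaves
    adj = tau._adj
    side = tau._side
    sent = support.n_params
    root_index = support.root_index
    pair_index = support.pair_index

    dir_ss = {}
    for v in range(n, 2 * n - 2):
        for u in adj[v]:
            a, b = (w for w in adj[v] if w != u)
            dir_ss[(u, v)] = _ordered_pair(side[(v, a)], side[(v, b)])

    per_rooting = []
    for (u, v) in tau._edges:
        root_ss = _ordered_pair(side[(u, v)], side[(v, u)])
        idx = [root_index.get(root_ss, sent)]
        stack = [(u, v, root_ss), (v, u, root_ss)]
        while stack:
            p, x, parent_ss = stack.pop()
            if side[(p, x)].bit_count() >= 3:
                t = dir_ss[(p, x)]
                idx.append(pair_index.get((t, parent_ss), sent))
                a, b = (w for w in adj[x] if w != p)
                stack.append((x, a, t))
                stack.append((x, b, t))
        per_rooting.append(idx)
    return per_rooting


class CompiledTopology:
    """One topology's rooting-factor index table against a support."""

    __slots__ = ("topology", "support", "flat", "offsets", "lengths")

    def __init__(self, tau: UnrootedTopology, support: SubsplitSupport):
        self.topology = tau
        self.support = support
        per_rooting = _rooting_param_indices(tau, support)
        self.flat = np.asarray([i for idx in per_rooting for i in idx], dtype=np.intp)
        self.lengths = np.asarray([len(idx) for idx in per_rooting], dtype=np.intp)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)[:-1]))

    @property
    def n_edges(self) -> int:
        return self.topology.n_edges

    def rooted_log_probs(self, c: CPDTable) -> np.ndarray:
        """Log probability of each of the 2N-3 rootings."""
        return np.add.reduceat(c.log_values_padded()[self.flat], self.offsets)

    def log_prob(self, c: CPDTable) -> float:
        return _logsumexp1d(self.rooted_log_probs(c))

    def root_posteriors(self, c: CPDTable) -> np.ndarray:
        """Posterior of the virtual root position over edges."""
        rlp = self.rooted_log_probs(c)
        lq = _logsumexp1d(rlp)
        if np.isneginf(lq):
            raise OutOfSupportError("topology has probability zero under the CPDs")
        return np.exp(rlp - lq)

    def efc(self, c: CPDTable) -> np.ndarray:
        """Dense expected frequency counts (root posteriors spread over the
        factors of each rooting); root entries sum to one."""
        post = self.root_posteriors(c)
        w = np.repeat(post, self.lengths)
        m = np.bincount(self.flat, weights=w, minlength=self.support.n_params + 1)
        return m[: self.support.n_params]

    def efc_items(self, c: CPDTable) -> tuple[np.ndarray, np.ndarray]:
        """Sparse expected frequency counts: (parameter indices, values),
        indices possibly repeated.  Cheaper than :meth:`efc` when the
        support is much larger than one tree's factor table."""
        post = self.root_posteriors(c)
        return self.flat, np.repeat(post, self.lengths)


def compile_topology(
    tau: UnrootedTopology,
    support: SubsplitSupport,
    cache: dict | None = None,
) -> CompiledTopology:
    if cache is None:
        return CompiledTopology(tau, support)
    ct = cache.get(tau)
    if ct is None:
        ct = cache[tau] = CompiledTopology(tau, support)
    return ct


class CompiledCollection:
    """A batch of topologies (a dataset or an enumerated space) compiled
    against one support, with all rootings concatenated for single-pass
    vectorized evaluation."""

    def __init__(self, topologies, support: SubsplitSupport):
        self.topologies = list(topologies)
        self.support = support
        if not self.topologies:
            raise ValueError("empty topology collection")
        n_edges = {t.n_edges for t in self.topologies}
        if len(n_edges) != 1:
            raise ValueError("all topologies must share one taxon set")
        self.n_edges = n_edges.pop()
        per_tree = [_rooting_param_indices(t, support) for t in self.topologies]
        flat: list[int] = []
        lengths: list[int] = []
        for rootings in per_tree:
            for idx in rootings:
                lengths.append(len(idx))
                flat.extend(idx)
        self.flat = np.asarray(flat, dtype=np.intp)
        self.lengths = np.asarray(lengths, dtype=np.intp)
        self.offsets = np.concatenate(([0], np.cumsum(self.lengths)[:-1]))

    def __len__(self) -> int:
        return len(self.topologies)

    def rooted_log_prob_matrix(self, c: CPDTable) -> np.ndarray:
        """(K, 2N-3) matrix of rooted log probabilities."""
        sums = np.add.reduceat(c.log_values_padded()[self.flat], self.offsets)
        return sums.reshape(len(self.topologies), self.n_edges)

    def log_probs(self, c: CPDTable) -> np.ndarray:
        """Per-topology log marginal probability (-inf if out of support)."""
        return logsumexp(self.rooted_log_prob_matrix(c), axis=1)

    def weighted_efc(self, c: CPDTable, weights: np.ndarray) -> np.ndarray:
        """Weighted sum of per-tree expected frequency counts.

        This is the full-batch E-step in one vectorized pass: per-tree
        root posteriors scaled by the tree weights and scattered onto the
        parameter vector.
        """
        weights = np.asarray(weights, dtype=float)
        rlp = self.rooted_log_prob_matrix(c)
        lq = logsumexp(rlp, axis=1)
        active = weights > 0
        if np.any(np.isneginf(lq[active])):
            raise OutOfSupportError("a weighted topology has probability zero")
        with np.errstate(invalid="ignore"):
            post = np.exp(rlp - lq[:, None])
        post[~active] = 0.0
        w = np.repeat((post * weights[:, None]).ravel(), self.lengths)
        m = np.bincount(self.flat, weights=w, minlength=self.support.n_params + 1)
        return m[: self.support.n_params]
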