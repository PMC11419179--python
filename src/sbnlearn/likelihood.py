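"""JC69 substitution model, pruning likelihood, priors and simulation.

The sequence model is a reversible continuous-time Markov chain on the
nucleotide alphabet run independently down each branch: the probability
of one site pattern is the sum over internal-node states of the product
of per-branch transition probabilities, weighted by the stationary
distribution at the (arbitrary) root.  Reversibility makes the value
independent of the root position (pulley principle), so unrooted trees
with branch lengths are valid inputs.  The likelihood is evaluated with
Felsenstein's pruning algorithm: directional partial likelihoods are
propagated from the leaves, with per-site rescaling against underflow.

Only the Jukes-Cantor model (uniform rates, uniform stationary
distribution) is instantiated here; the :class:`SubstitutionModel`
container accepts any reversible rate matrix and falls back to a matrix
exponential when no closed form is available.

Priors follow the standard Bayesian phylogenetics defaults: uniform over
unrooted topologies and i.i.d. exponential branch lengths (rate 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import expm

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import TaxonSet, UnrootedTopology, n_unrooted_topologies

__all__ = [
    "STATES",
    "SubstitutionModel",
    "jc69",
    "jc_transition",
    "Alignment",
    "felsenstein_loglik",
    "branch_gradients",
    "log_prior",
    "log_unnorm_posterior",
    "simulate_alignment",
]

STATES = "ACGT"
_CODE = {ch: i for i, ch in enumerate(STATES)}


@dataclass
class SubstitutionModel:
    """A reversible rate matrix with its stationary distribution."""

    Q: np.ndarray
    pi: np.ndarray
    _closed_form: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.Q.shape != (4, 4) or self.pi.shape != (4,):
            raise ValueError("expected a 4x4 rate matrix and length-4 stationary vector")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to zero")
        if not np.allclose(self.pi @ self.Q, 0.0, atol=1e-10):
            raise ValueError("stationary distribution must satisfy pi Q = 0")
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("stationary distribution must sum to one")

    def transition(self, l: float) -> np.ndarray:
        """P(l) = exp(l Q)."""
        if l < 0:
            raise ValueError("branch length must be nonnegative")
        if self._closed_form:
            return jc_transition(l)
        return expm(l * self.Q)

    def dtransition(self, l: float) -> np.ndarray:
        """dP/dl = Q exp(l Q)."""
        if self._closed_form:
            e = np.exp(-4.0 * l / 3.0)
            return np.where(np.eye(4, dtype=bool), -e, e / 3.0)
        return self.Q @ self.transition(l)


def jc_transition(l: float) -> np.ndarray:
    """Jukes-Cantor transition matrix: P_ii = 1/4 + 3/4 e^{-4l/3},
    P_ij = 1/4 - 1/4 e^{-4l/3}."""
    if l < 0:
        raise ValueError("branch length must be nonnegative")
    e = np.exp(-4.0 * l / 3.0)
    return np.where(np.eye(4, dtype=bool), 0.25 + 0.75 * e, 0.25 - 0.25 * e)


def jc69() -> SubstitutionModel:
    """The Jukes-Cantor model, normalized to one expected substitution
    per unit branch length."""
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return SubstitutionModel(Q, np.full(4, 0.25), _closed_form=True)


# ---------------------------------------------------------------------------
# alignments


class Alignment:
    """Equal-length nucleotide sequences over a taxon set.

    Stored as an (N, S) integer code matrix in taxon order.
    """

    def __init__(self, taxa: TaxonSet, sequences: Mapping[str, str]):
        if set(sequences) != set(taxa.labels):
            raise ValueError("alignment taxa do not match the taxon set")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        self.taxa = taxa
        self.codes = np.empty((len(taxa), lengths.pop()), dtype=np.int8)
        for lab, seq in sequences.items():
            try:
                self.codes[taxa.index(lab)] = [_CODE[ch] for ch in seq.upper()]
            except KeyError as exc:
                raise ValueError(f"invalid character {exc} in sequence {lab!r}") from None

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, label: str) -> str:
        return "".join(STATES[i] for i in self.codes[self.taxa.index(label)])

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site columns and their multiplicities."""
        cols, counts = np.unique(self.codes, axis=1, return_counts=True)
        return cols, counts

    @classmethod
    def read(cls, source, taxa: TaxonSet | None = None, format: str = "fasta") -> "Alignment":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(source, format)}
        if taxa is None:
            taxa = TaxonSet(sorted(records))
        return cls(taxa, records)

    def write(self, path, format: str = "fasta") -> None:
        records = [
            SeqRecord(Seq(self.sequence(lab)), id=lab, description="")
            for lab in self.taxa
        ]
        SeqIO.write(records, path, format)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and np.array_equal(self.codes, other.codes)
        )


# ---------------------------------------------------------------------------
# pruning


def _bl_array(tau: UnrootedTopology, bl) -> np.ndarray:
    if isinstance(bl, Mapping):
        arr = np.empty(tau.n_edges)
        for e in tau.edge_ids:
            arr[e] = bl[e]
    else:
        arr = np.asarray(bl, dtype=float)
        if arr.shape != (tau.n_edges,):
            raise ValueError(f"expected {tau.n_edges} branch lengths")
    if np.any(arr < 0):
        raise ValueError("branch lengths must be nonnegative")
    return arr


def _messages(tau: UnrootedTopology, bl: np.ndarray, cols: np.ndarray,
              model: SubstitutionModel):
    """Directional partial likelihoods F(v<-u)[a, s]: probability of the
    leaf data in the subtree on the v side of edge (u, v), given state a
    at v.  Returned with per-site log rescaling factors."""
    n = tau.n_leaves
    adj = tau._adj
    edge_of = {}
    P = {}
    for e in tau.edge_ids:
        u, v = tau.edge_nodes(e)
        edge_of[(u, v)] = edge_of[(v, u)] = e
        P[e] = model.transition(bl[e])

    n_sites = cols.shape[1]
    memo: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def compute(v: int, u: int):
        key = (v, u)
        if key in memo:
            return memo[key]
        if v < n:
            arr = np.zeros((4, n_sites))
            arr[cols[v], np.arange(n_sites)] = 1.0
            scale = np.zeros(n_sites)
        else:
            arr = np.ones((4, n_sites))
            scale = np.zeros(n_sites)
            for w in adj[v]:
                if w == u:
                    continue
                sub, sub_scale = compute(w, v)
                arr = arr * (P[edge_of[(v, w)]] @ sub)
                scale = scale + sub_scale
            mx = arr.max(axis=0)
            nz = mx > 0
            arr[:, nz] /= mx[nz]
            scale = scale + np.where(nz, np.log(np.where(nz, mx, 1.0)), -np.inf)
        memo[key] = (arr, scale)
        return memo[key]

    for e in tau.edge_ids:
        u, v = tau.edge_nodes(e)
        compute(u, v)
        compute(v, u)
    return memo, P, edge_of


def _edge_site_likelihoods(tau, messages, P, e, model):
    u, v = tau.edge_nodes(e)
    A, sa = messages[(u, v)]
    B, sb = messages[(v, u)]
    ps = np.einsum("a,as,ab,bs->s", model.pi, A, P[e], B)
    return ps, sa + sb


def felsenstein_loglik(tau: UnrootedTopology, bl, Y: Alignment,
                       model: SubstitutionModel | None = None) -> float:
    """Log likelihood of the alignment on an unrooted tree with branch
    lengths, sites i.i.d.  Equals the brute-force marginalization over
    internal states; the root is placed on the first canonical edge (the
    choice is irrelevant for reversible models)."""
    model = model or jc69()
    if Y.taxa != tau.taxa:
        raise ValueError("alignment and topology taxon sets differ")
    blv = _bl_array(tau, bl)
    cols, counts = Y.patterns()
    messages, P, _ = _messages(tau, blv, cols, model)
    ps, scale = _edge_site_likelihoods(tau, messages, P, 0, model)
    with np.errstate(divide="ignore"):
        return float(np.dot(counts, np.log(ps) + scale))


def branch_gradients(tau: UnrootedTopology, bl, Y: Alignment,
                     model: SubstitutionModel | None = None) -> np.ndarray:
    """d log likelihood / d branch length, per edge id (exact)."""
    model = model or jc69()
    blv = _bl_array(tau, bl)
    cols, counts = Y.patterns()
    messages, P, _ = _messages(tau, blv, cols, model)
    out = np.empty(tau.n_edges)
    for e in tau.edge_ids:
        u, v = tau.edge_nodes(e)
        A, _ = messages[(u, v)]
        B, _ = messages[(v, u)]
        ps = np.einsum("a,as,ab,bs->s", model.pi, A, P[e], B)
        dps = np.einsum("a,as,ab,bs->s", model.pi, A, model.dtransition(blv[e]), B)
        out[e] = float(np.dot(counts, dps / ps))
    return out


# ---------------------------------------------------------------------------
# priors and posterior kernel


def log_prior(tau: UnrootedTopology, bl, branch_rate: float = 10.0) -> float:
    """Uniform prior over unrooted topologies plus i.i.d. Exp(rate)
    branch lengths."""
    blv = _bl_array(tau, bl)
    n = tau.n_leaves
    return float(
        -np.log(n_unrooted_topologies(n))
        + np.sum(np.log(branch_rate) - branch_rate * blv)
    )


def log_unnorm_posterior(tau: UnrootedTopology, bl, Y: Alignment,
                         beta: float = 1.0, branch_rate: float = 10.0,
                         model: SubstitutionModel | None = None) -> float:
    """Annealed unnormalized posterior kernel:
    beta * log p(Y | tau, l) + log p(tau, l)."""
    return beta * felsenstein_loglik(tau, bl, Y, model) + log_prior(tau, bl, branch_rate)


# ---------------------------------------------------------------------------
# simulation


def simulate_alignment(tau: UnrootedTopology, bl, n_sites: int,
                       rng: np.random.Generator,
                       model: SubstitutionModel | None = None) -> Alignment:
    """Forward-simulate i.i.d. sites: draw a root state from the
    stationary distribution at an internal node and propagate state
    transitions along every branch."""
    model = model or jc69()
    blv = _bl_array(tau, bl)
    n = tau.n_leaves
    adj = tau._adj
    edge_of = {}
    for e in tau.edge_ids:
        u, v = tau.edge_nodes(e)
        edge_of[(u, v)] = edge_of[(v, u)] = e

    states = np.empty((2 * n - 2, n_sites), dtype=np.int8)
    start = adj[0][0]
    states[start] = rng.choice(4, size=n_sites, p=model.pi)
    stack = [(start, w) for w in adj[start]]
    while stack:
        u, v = stack.pop()
        P = model.transition(blv[edge_of[(u, v)]])
        cum = np.cumsum(P, axis=1)
        r = rng.random(n_sites)
        states[v] = (r[:, None] < cum[states[u]]).argmax(axis=1)
        for w in adj[v]:
            if w != u:
                stack.append((v, w))
    seqs = {
        tau.taxa.label(i): "".join(STATES[s] for s in states[i]) for i in range(n)
    }
    return Alignment(tau.taxa, seqs)
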