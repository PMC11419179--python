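"""Variational Bayesian phylogenetic inference (VBPI) with SBNs.

The variational family factorizes as q_{phi,psi}(tau, l) =
Q_phi(tau) q_psi(l | tau): an SBN over tree topologies times a diagonal
lognormal over branch lengths whose location/scale parameters are
amortized over topologies through shared local structure (here: one
(mu, log sigma) pair per observed split, an edge reading its parameters
from the bipartition it induces).

Training maximizes the expected log variational density under the
posterior (equivalently, minimizes the inclusive KL divergence), using
self-normalized importance sampling (SNIS) with the variational
distribution as proposal.  The topology-parameter gradient is the
reweighted wake-sleep (RWS) estimator — a SNIS-weighted average of
``grad log Q_phi`` over particles — or its variance-reduced variant
(RWSVR), which subtracts the same particles' gradient evaluated at the
epoch-start parameters and adds back a large-sample gradient estimate
cached once per epoch.  Branch parameters always use the reparameterized
(pathwise) gradient through l = exp(mu + sigma * eps).

Targets come in two flavors: a full phylogenetic model (alignment +
priors, with an annealed likelihood exponent) and a branchless simulated
model given by an explicit normalized distribution over an enumerated
topology space, for which the ELBO and KL can be computed exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._compile import CompiledCollection, compile_topology
from ._optim import Adam
from .estimators import _grad_from_efc
from .likelihood import (
    Alignment,
    SubstitutionModel,
    branch_gradients,
    felsenstein_loglik,
    jc69,
    log_prior,
)
from .sbn import (
    LatentParams,
    SubsplitSupport,
    latent_to_cpd,
    sample_topology,
)
from .trees import UnrootedTopology, _ordered_pair

__all__ = [
    "VbpiConfig",
    "BranchParams",
    "ParticleSet",
    "DiscreteTarget",
    "PhyloTarget",
    "anneal",
    "sample_branches",
    "snis_weights",
    "rws_grad",
    "RwsvrState",
    "rwsvr_grad",
    "reparam_grad_psi",
    "elbo_exact",
    "elbo",
    "marginal_likelihood_is",
    "run_vbpi",
    "VbpiResult",
]


@dataclass
class VbpiConfig:
    """VBPI hyperparameters.

    ``R`` is the per-iteration particle count and ``F`` the (much larger)
    epoch sample size used for the RWSVR control-variate constant;
    ``iters_per_epoch`` (T) controls how stale the constant may become.
    The annealing exponent follows beta_t = min(1, anneal_init + t / anneal_iters).
    """

    estimator: str = "rwsvr"
    R: int = 10
    F: int = 1000
    iters_per_epoch: int = 100
    n_iters: int = 200000
    optimizer: str = "amsgrad"
    learning_rate: float = 0.002
    decay_rate: float = 0.75
    decay_every: int = 20000
    anneal_init: float = 0.001
    anneal_iters: int = 100000
    seed: int | None = 0

    def __post_init__(self):
        if self.estimator not in ("rws", "rwsvr"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.R < 1 or self.iters_per_epoch < 1:
            raise ValueError("R and iters_per_epoch must be >= 1")
        if self.estimator == "rwsvr" and self.F < self.R:
            raise ValueError("epoch sample size F must be >= iteration sample size R")


def anneal(t: int, init: float = 0.001, total: int = 100000) -> float:
    """Likelihood inverse temperature: linear warm-up from ``init`` to 1."""
    return min(1.0, init + t / total)


# ---------------------------------------------------------------------------
# branch-length family


class BranchParams:
    """Split-amortized lognormal branch-length parameters.

    One (mu, log sigma) pair per root subsplit of the support — a root
    subsplit is exactly a split of the taxon set, and every edge of every
    in-support topology induces one.  Topologies sharing a split share
    that edge's parameters.  Zero initialization gives mu = 0, sigma = 1
    for every edge.
    """

    def __init__(self, support: SubsplitSupport):
        self.support = support
        n = len(support.root_subsplits)
        self.mu = np.zeros(n)
        self.log_sigma = np.zeros(n)

    @property
    def n_features(self) -> int:
        return len(self.mu)

    def edge_features(self, tau: UnrootedTopology) -> np.ndarray:
        """Feature index of every edge of a topology, in edge-id order."""
        full = tau.taxa.full_mask
        idx = np.empty(tau.n_edges, dtype=np.intp)
        for e in tau.edge_ids:
            m = tau.edge_split(e)
            ss = _ordered_pair(m, full ^ m)
            i = self.support.root_index.get(ss)
            if i is None:
                raise ValueError("edge split not covered by the support")
            idx[e] = i
        return idx

    def lookup(self, tau: UnrootedTopology) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (mu, sigma) arrays for a topology."""
        idx = self.edge_features(tau)
        return self.mu[idx], np.exp(self.log_sigma[idx])

    def log_density(self, tau: UnrootedTopology, bl: np.ndarray) -> float:
        """Diagonal lognormal log density of the branch lengths."""
        mu, sigma = self.lookup(tau)
        z = (np.log(bl) - mu) / sigma
        return float(np.sum(-np.log(bl) - np.log(sigma)
                            - 0.5 * math.log(2 * math.pi) - 0.5 * z * z))


def sample_branches(psi: BranchParams, tau: UnrootedTopology,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw l_e = exp(mu_e + sigma_e * eps_e); returns (lengths, eps)."""
    mu, sigma = psi.lookup(tau)
    eps = rng.standard_normal(tau.n_edges)
    return np.exp(mu + sigma * eps), eps


# ---------------------------------------------------------------------------
# targets


@dataclass
class DiscreteTarget:
    """Branchless simulated target: an explicit normalized distribution
    over an enumerated topology space (exact evidence log 1 = 0).

    ``log_probs`` may be supplied separately when probabilities underflow
    on the linear scale (very concentrated Dirichlet targets)."""

    topologies: tuple
    probs: np.ndarray
    log_probs: np.ndarray | None = None
    has_branches: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.topologies = tuple(self.topologies)
        self.probs = np.asarray(self.probs, dtype=float)
        if not math.isclose(float(self.probs.sum()), 1.0, abs_tol=1e-12):
            raise ValueError("target probabilities must sum to 1")
        if self.log_probs is None:
            with np.errstate(divide="ignore"):
                self.log_probs = np.log(self.probs)
        else:
            self.log_probs = np.asarray(self.log_probs, dtype=float)
        self._logp = {
            tau: float(lp) for tau, lp in zip(self.topologies, self.log_probs)
        }

    def log_prob(self, tau: UnrootedTopology) -> float:
        return self._logp.get(tau, -math.inf)


@dataclass
class PhyloTarget:
    """Full phylogenetic model: annealed likelihood times priors."""

    alignment: Alignment
    model: SubstitutionModel | None = None
    branch_rate: float = 10.0
    has_branches: bool = field(default=True, repr=False)

    def __post_init__(self):
        if self.model is None:
            self.model = jc69()

    def log_joint(self, tau: UnrootedTopology, bl: np.ndarray, beta: float = 1.0) -> float:
        return (beta * felsenstein_loglik(tau, bl, self.alignment, self.model)
                + log_prior(tau, bl, self.branch_rate))

    def branch_grad(self, tau: UnrootedTopology, bl: np.ndarray, beta: float = 1.0) -> np.ndarray:
        """d log_joint / d branch length per edge."""
        return (beta * branch_gradients(tau, bl, self.alignment, self.model)
                - self.branch_rate)


# ---------------------------------------------------------------------------
# particles and weights


@dataclass
class ParticleSet:
    """R draws from the variational family with SNIS weights."""

    topologies: list
    log_weights: np.ndarray
    weights: np.ndarray
    branches: list | None = None
    eps: list | None = None

    def __len__(self) -> int:
        return len(self.topologies)


def snis_weights(log_w: np.ndarray) -> np.ndarray:
    """Self-normalized importance weights from unnormalized log weights
    (stable log-sum-exp); raises if every weight is zero."""
    log_w = np.asarray(log_w, dtype=float)
    total = logsumexp(log_w)
    if np.isneginf(total):
        raise ValueError("all importance weights are zero")
    return np.exp(log_w - total)


def draw_particles(phi: LatentParams, psi: BranchParams | None, target,
                   n: int, rng: np.random.Generator, beta: float = 1.0,
                   compiled_cache: dict | None = None,
                   topo_cache: dict | None = None) -> ParticleSet:
    """Sample n particles from the variational family and compute their
    unnormalized SNIS log weights against the (annealed) target.

    Out-of-target-support topologies get weight zero; if every particle
    lands outside the target support the normalized weights are all zero
    (the training loop then skips the update).
    """
    c = latent_to_cpd(phi)
    topologies, log_w = [], []
    branches: list | None = [] if target.has_branches else None
    eps_list: list | None = [] if target.has_branches else None
    for _ in range(n):
        tau = sample_topology(c, rng, cache=topo_cache)
        lq_topo = compile_topology(tau, phi.support, compiled_cache).log_prob(c)
        if target.has_branches:
            bl, eps = sample_branches(psi, tau, rng)
            branches.append(bl)
            eps_list.append(eps)
            lw = (target.log_joint(tau, bl, beta) - lq_topo
                  - psi.log_density(tau, bl))
        else:
            lw = target.log_prob(tau) - lq_topo
        topologies.append(tau)
        log_w.append(lw)
    log_w = np.asarray(log_w)
    total = logsumexp(log_w)
    weights = np.zeros(n) if np.isneginf(total) else np.exp(log_w - total)
    return ParticleSet(topologies, log_w, weights, branches, eps_list)


# ---------------------------------------------------------------------------
# gradient estimators for the topology parameters


def _weighted_topo_grad(topologies, weights, phi_eval: LatentParams,
                        compiled_cache: dict | None = None,
                        efc_cache: dict | None = None) -> np.ndarray:
    """sum_i w_i * grad_phi log Q_phi(tau_i) at the evaluation point.

    The per-tree gradient is linear in the tree's expected frequency
    counts, so the weighted EFC aggregate is formed first and mapped
    through the softmax Jacobian once.  ``efc_cache`` may be reused
    across calls only while the evaluation point is unchanged.
    """
    c = latent_to_cpd(phi_eval)
    sup = phi_eval.support
    acc = np.zeros(sup.n_params)
    for tau, w in zip(topologies, weights):
        if w == 0.0:
            continue
        if efc_cache is not None and tau in efc_cache:
            idx, vals = efc_cache[tau]
        else:
            idx, vals = compile_topology(tau, sup, compiled_cache).efc_items(c)
            if efc_cache is not None:
                efc_cache[tau] = (idx, vals)
        np.add.at(acc, idx, w * vals)
    return _grad_from_efc(c, acc)


def rws_grad(phi_eval: LatentParams, particles: ParticleSet,
             weights: np.ndarray | None = None, **caches) -> np.ndarray:
    """Reweighted wake-sleep estimator: the SNIS-weighted average of
    ``grad log Q_phi`` over the particles, evaluated at ``phi_eval``
    (which may differ from the sampling parameters)."""
    w = particles.weights if weights is None else np.asarray(weights)
    return _weighted_topo_grad(particles.topologies, w, phi_eval, **caches)


@dataclass
class RwsvrState:
    """Per-epoch control-variate constant for RWSVR: the epoch-start
    parameters and the large-sample gradient estimate cached there."""

    phi0: LatentParams
    grad0: np.ndarray


def rwsvr_grad(state: RwsvrState, particles: ParticleSet,
               phi_t: LatentParams, **caches) -> np.ndarray:
    """Variance-reduced RWS: G_R(phi_t) - G_R(phi_0) + G_F(phi_0), the two
    R-sample terms computed from the same particle set."""
    g_t = rws_grad(phi_t, particles, **caches)
    g_0 = rws_grad(state.phi0, particles)
    return g_t - g_0 + state.grad0


# ---------------------------------------------------------------------------
# branch-parameter gradient (reparameterization trick)


def reparam_grad_psi(psi: BranchParams, particles: ParticleSet, target,
                     beta: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Pathwise gradient of the SNIS objective with respect to the branch
    parameters (weights held fixed).

    With l = exp(mu + sigma * eps) the per-edge chain rule gives
    d/dmu  = D*l + 1  and  d/dlog sigma = (D*l + 1) * sigma * eps + 1,
    where D = d log p(tau, l, Y) / dl; the +1 terms come from the
    lognormal entropy.  Returns (grad mu, grad log sigma).
    """
    gmu = np.zeros(psi.n_features)
    gls = np.zeros(psi.n_features)
    for tau, bl, eps, w in zip(particles.topologies, particles.branches,
                               particles.eps, particles.weights):
        if w == 0.0:
            continue
        D = target.branch_grad(tau, bl, beta)
        idx = psi.edge_features(tau)
        sigma = np.exp(psi.log_sigma[idx])
        core = D * bl + 1.0
        np.add.at(gmu, idx, w * core)
        np.add.at(gls, idx, w * (core * sigma * eps + 1.0))
    return gmu, gls


# ---------------------------------------------------------------------------
# diagnostics


def elbo_exact(q_probs: np.ndarray, log_p_probs: np.ndarray) -> float:
    """Exact ELBO of a branchless model over an enumerated space:
    sum_tau Q(tau) log(p(tau)/Q(tau)); 0 iff Q = p, else negative.

    The target enters on the log scale so that probabilities too small to
    represent linearly still contribute finite terms."""
    q = np.asarray(q_probs, dtype=float)
    log_p = np.asarray(log_p_probs, dtype=float)
    pos = q > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(q[pos] * (log_p[pos] - np.log(q[pos]))))


def elbo(phi: LatentParams, target, psi: BranchParams | None = None,
         n_samples: int = 1000, rng: np.random.Generator | None = None,
         space: CompiledCollection | None = None) -> float:
    """Evidence lower bound of the variational approximation.

    For a branchless target over an enumerated space the expectation is
    computed exactly by summation; otherwise by Monte Carlo over
    ``n_samples`` draws from the variational family.
    """
    if not target.has_branches:
        if space is None:
            space = CompiledCollection(target.topologies, phi.support)
        q = np.exp(space.log_probs(latent_to_cpd(phi)))
        return elbo_exact(q, target.log_probs)
    rng = rng if rng is not None else np.random.default_rng()
    ps = draw_particles(phi, psi, target, n_samples, rng, beta=1.0)
    c = latent_to_cpd(phi)
    vals = []
    for tau, bl in zip(ps.topologies, ps.branches):
        lq = (compile_topology(tau, phi.support).log_prob(c)
              + psi.log_density(tau, bl))
        vals.append(target.log_joint(tau, bl, 1.0) - lq)
    return float(np.mean(vals))


def marginal_likelihood_is(phi: LatentParams, target,
                           psi: BranchParams | None = None,
                           n_samples: int = 1000, n_reps: int = 1,
                           rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Importance-sampling estimate of the log marginal likelihood:
    log mean of the unnormalized weights over ``n_samples`` draws from
    the variational family; returns (mean, std) over ``n_reps``
    independent replicates."""
    rng = rng if rng is not None else np.random.default_rng()
    estimates = []
    for _ in range(n_reps):
        ps = draw_particles(phi, psi, target, n_samples, rng, beta=1.0)
        estimates.append(float(logsumexp(ps.log_weights) - math.log(n_samples)))
    return float(np.mean(estimates)), float(np.std(estimates))


def estimator_variance_study(target, support: SubsplitSupport,
                             phi0: LatentParams, phi_t: LatentParams,
                             R: int = 10, F: int = 1000, n_reps: int = 1000,
                             rng: np.random.Generator | None = None,
                             psi: BranchParams | None = None) -> dict:
    """Empirical variance of the RWS and RWSVR gradient estimators.

    Replicates the estimators ``n_reps`` times around a pair of nearby
    parameter vectors (``phi0`` plays the epoch-start role, ``phi_t`` the
    current iterate): per replicate, F particles drawn at ``phi0`` give
    the control-variate constant and R particles drawn at ``phi_t`` give
    both the RWS gradient and the two correlated RWSVR terms.  Returns the
    total variance (trace of the empirical covariance) of each estimator
    together with the standard error of that variance estimate, i.e. the
    ingredients of a "variance is smaller" comparison.
    """
    rng = rng if rng is not None else np.random.default_rng()
    compiled_cache: dict = {}
    topo_cache: dict = {}
    efc_cache_t: dict = {}
    efc_cache_0: dict = {}
    n = support.n_params
    g_rws = np.empty((n_reps, n), dtype=np.float32)
    g_rwsvr = np.empty((n_reps, n), dtype=np.float32)
    for r in range(n_reps):
        epoch_ps = draw_particles(phi0, psi, target, F, rng,
                                  compiled_cache=compiled_cache,
                                  topo_cache=topo_cache)
        grad_F = rws_grad(phi0, epoch_ps, compiled_cache=compiled_cache,
                          efc_cache=efc_cache_0)
        ps = draw_particles(phi_t, psi, target, R, rng,
                            compiled_cache=compiled_cache,
                            topo_cache=topo_cache)
        g_t = rws_grad(phi_t, ps, compiled_cache=compiled_cache,
                       efc_cache=efc_cache_t)
        g_0 = rws_grad(phi0, ps, compiled_cache=compiled_cache,
                       efc_cache=efc_cache_0)
        g_rws[r] = g_t
        g_rwsvr[r] = g_t - g_0 + grad_F

    out = {}
    for name, g in (("rws", g_rws), ("rwsvr", g_rwsvr)):
        dev = g - g.mean(axis=0, keepdims=True)
        d = np.sum(dev.astype(np.float64) ** 2, axis=1)  # per-rep squared deviation
        out[f"{name}_variance"] = float(d.mean())
        out[f"{name}_variance_se"] = float(d.std(ddof=1) / math.sqrt(n_reps))
    return out


# ---------------------------------------------------------------------------
# training loop


@dataclass
class VbpiResult:
    phi: LatentParams
    psi: BranchParams | None
    trace: pd.DataFrame
    n_likelihood_computations: int = 0


def run_vbpi(target, support: SubsplitSupport, config: VbpiConfig,
             space: CompiledCollection | None = None,
             rng: np.random.Generator | None = None) -> VbpiResult:
    """Train the variational approximation with RWS or RWSVR.

    phi starts at zero (uniform CPDs).  For RWSVR each epoch starts by
    drawing F particles at the current parameters and caching the
    large-sample gradient as the control-variate constant for the next
    ``iters_per_epoch`` iterations; the constant is recomputed with the
    annealing temperature current at that time.  The trace records, per
    epoch, the exact ELBO and inclusive KL for branchless targets (an
    ELBO estimate is not recorded for full models to keep training cheap;
    use :func:`elbo` afterwards).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    phi = LatentParams.zeros(support)
    psi = BranchParams(support) if target.has_branches else None
    amsgrad = config.optimizer == "amsgrad"
    opt_phi = Adam(support.n_params, lr=config.learning_rate, amsgrad=amsgrad)
    opt_psi = (Adam(2 * psi.n_features, lr=config.learning_rate, amsgrad=amsgrad)
               if psi is not None else None)
    compiled_cache: dict = {}
    topo_cache: dict = {}
    if space is None and not target.has_branches:
        space = CompiledCollection(target.topologies, support)

    rows = []
    n_like = 0
    state: RwsvrState | None = None
    for t in range(config.n_iters):
        beta = anneal(t, config.anneal_init, config.anneal_iters) if target.has_branches else 1.0
        if config.estimator == "rwsvr" and t % config.iters_per_epoch == 0:
            epoch_particles = draw_particles(phi, psi, target, config.F, rng,
                                             beta, compiled_cache, topo_cache)
            phi0 = LatentParams(support, phi.phi.copy())
            grad0 = rws_grad(phi0, epoch_particles, compiled_cache=compiled_cache)
            state = RwsvrState(phi0=phi0, grad0=grad0)
            n_like += config.F
        particles = draw_particles(phi, psi, target, config.R, rng, beta,
                                   compiled_cache, topo_cache)
        n_like += config.R
        lr_scale = config.decay_rate ** (t // config.decay_every)
        if np.any(particles.weights > 0):
            if config.estimator == "rwsvr":
                g = rwsvr_grad(state, particles, phi, compiled_cache=compiled_cache)
            else:
                g = rws_grad(phi, particles, compiled_cache=compiled_cache)
            phi = LatentParams(support, opt_phi.step(phi.phi, g, lr_scale))
            if psi is not None:
                gmu, gls = reparam_grad_psi(psi, particles, target, beta)
                packed = opt_psi.step(np.concatenate([psi.mu, psi.log_sigma]),
                                      np.concatenate([gmu, gls]), lr_scale)
                psi.mu = packed[: psi.n_features]
                psi.log_sigma = packed[psi.n_features:]
        if (t + 1) % config.iters_per_epoch == 0 and not target.has_branches:
            q = np.exp(space.log_probs(latent_to_cpd(phi)))
            lb = elbo_exact(q, target.log_probs)
            p = target.probs
            pos = p > 0
            kl = float(np.sum(p[pos] * (np.log(p[pos])
                                        - np.log(np.maximum(q[pos], 1e-40)))))
            rows.append({"iteration": t + 1,
                         "n_likelihood_computations": n_like,
                         "elbo": lb, "kl": kl})
        elif (t + 1) % config.iters_per_epoch == 0:
            rows.append({"iteration": t + 1,
                         "n_likelihood_computations": n_like})
    return VbpiResult(phi=phi, psi=psi, trace=pd.DataFrame(rows),
                      n_likelihood_computations=n_like)
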