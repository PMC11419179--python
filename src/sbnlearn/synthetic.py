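"""Synthetic study generators and drivers.

The simulated benchmark puts a random target distribution on the
enumerated space of unrooted topologies (10395 trees at 8 taxa): one draw
from a symmetric Dirichlet whose concentration controls how diffuse the
target is.  Training data are the top-K most probable topologies with
their renormalized target probabilities as weights — deliberately hard
for tree-similarity-based estimators because Dirichlet mass is assigned
with no regard to topological similarity.  Study drivers train the
estimator families on such data and report inclusive KL (probability
estimates clipped at 1e-40) or exact ELBO traces against likelihood
computation counts.  All randomness derives from one seed; identical
seeds reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._compile import CompiledCollection
from .estimators import DEFAULT_LEARNING_RATES, TrainConfig, fit
from .sbn import build_support
from .trees import TaxonSet, enumerate_unrooted
from .vbpi import DiscreteTarget, VbpiConfig, run_vbpi

__all__ = [
    "TargetDistribution",
    "EstimationStudySpec",
    "VbpiSimStudySpec",
    "dirichlet_target",
    "topk_dataset",
    "default_taxa",
    "run_estimation_study",
    "run_vbpi_sim_study",
]


@dataclass
class TargetDistribution:
    """An explicit distribution over a list of topologies.

    ``log_probs`` carries the exact log probabilities; with very small
    Dirichlet concentrations many probabilities underflow to zero on the
    linear scale while remaining finite in log space.
    """

    topologies: tuple
    probs: np.ndarray
    log_probs: np.ndarray | None = None

    def __post_init__(self):
        self.topologies = tuple(self.topologies)
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.topologies) != len(self.probs):
            raise ValueError("length mismatch")
        if np.any(self.probs < 0) or abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        if self.log_probs is None:
            with np.errstate(divide="ignore"):
                self.log_probs = np.log(self.probs)
        else:
            self.log_probs = np.asarray(self.log_probs, dtype=float)


def default_taxa(n: int) -> TaxonSet:
    return TaxonSet(f"t{i}" for i in range(n))


def dirichlet_target(space, beta: float, rng: np.random.Generator) -> TargetDistribution:
    """One draw from the symmetric Dirichlet(beta) of order ``len(space)``,
    assigned to the topologies in their given (enumeration) order.

    Small concentrations give very peaked targets; coordinates that
    underflow to zero are kept as exact zeros.
    """
    if beta <= 0:
        raise ValueError("concentration must be positive")
    n = len(space)
    # Log-space gamma sampling via the boost Gamma(beta) = Gamma(beta+1) * U^(1/beta),
    # which keeps tiny coordinates finite in log space at small beta.
    log_g = (np.log(rng.standard_gamma(beta + 1.0, size=n))
             + np.log(np.maximum(rng.random(n), 1e-300)) / beta)
    log_p = log_g - logsumexp(log_g)
    p = np.exp(log_p)
    return TargetDistribution(tuple(space), p / p.sum(), log_probs=log_p)


def topk_dataset(target: TargetDistribution, K: int):
    """The K most probable topologies, weighted by their renormalized
    target probabilities; ties broken by topology order.  Weights come out
    non-increasing and sum to one."""
    if not 1 <= K <= len(target.topologies):
        raise ValueError("K must be between 1 and the space size")
    order = np.argsort(-target.probs, kind="stable")[:K]
    top = target.probs[order]
    if top.sum() <= 0:
        raise ValueError("top-K topologies have zero total probability")
    weights = top / top.sum()
    return [(target.topologies[i], float(w)) for i, w in zip(order, weights)]


# ---------------------------------------------------------------------------
# tree probability estimation study


@dataclass
class EstimationStudySpec:
    """Configuration of the topology probability estimation benchmark.

    Defaults are a desk-scale version of the printed study conditions:
    8-taxon space, minibatch size 1, 1000 iterations per epoch, method
    learning rates (sem 0.001, semvr 0.01, sga 0.0001, svrg 0.001,
    ga 0.01) with the sem/sga rate decaying by 0.75 every 50 epochs, and
    20000 total iterations over 5 replicates in place of the full-scale
    200000 over 10.
    """

    n_taxa: int = 8
    beta: float = 0.01
    K: int = 2000
    methods: tuple = ("em", "sem", "semvr", "sga", "svrg")
    replicates: int = 5
    iters: int = 20000
    iters_per_epoch: int = 1000
    batch_size: int = 1
    alpha: float = 0.0
    em_epochs: int = 300
    seed: int = 0
    learning_rates: dict = field(default_factory=dict)

    def learning_rate(self, method: str) -> float:
        return self.learning_rates.get(method, DEFAULT_LEARNING_RATES[method])


def run_estimation_study(spec: EstimationStudySpec,
                         space=None, compiled_space_cache=None) -> pd.DataFrame:
    """Per-replicate, per-method KL traces on Dirichlet/top-K problems.

    Each replicate draws a fresh target and dataset; every method trains
    from the same simple-average initialization implied by the shared
    support.  Returns a long table with columns
    (replicate, method, epoch, n_likelihood_computations, loglik, kl).
    """
    taxa = default_taxa(spec.n_taxa)
    if space is None:
        space = enumerate_unrooted(taxa)
    epochs = max(1, spec.iters // spec.iters_per_epoch)
    rows = []
    root_ss = np.random.SeedSequence(spec.seed)
    for rep, child in enumerate(root_ss.spawn(spec.replicates)):
        rng = np.random.default_rng(child)
        target = dirichlet_target(space, spec.beta, rng)
        data = topk_dataset(target, spec.K)
        support = build_support(data)
        compiled_space = CompiledCollection(space, support)
        for method in spec.methods:
            cfg = TrainConfig(
                method=method,
                learning_rate=spec.learning_rate(method),
                batch_size=spec.batch_size,
                iters_per_epoch=spec.iters_per_epoch,
                epochs=spec.em_epochs if method in ("em", "em-a") else epochs,
                alpha=spec.alpha,
                seed=int(rng.integers(2**31)),
                tol=1e-5,
            )
            result = fit(data, cfg, support=support, target=target,
                         space=compiled_space)
            for _, r in result.trace.iterrows():
                rows.append({
                    "replicate": rep, "method": method,
                    "epoch": int(r["epoch"]),
                    "n_likelihood_computations": int(r["n_likelihood_computations"]),
                    "loglik": r["loglik"],
                    "kl": max(float(r["kl"]), 0.0),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulated VBPI study


@dataclass
class VbpiSimStudySpec:
    """Configuration of the branchless simulated VBPI benchmark: the
    8-taxon enumerated space with a Dirichlet(0.008) target, RWS vs RWSVR
    at iteration sample sizes R with epoch sample size F=1000 and 100
    iterations per epoch, AMSGrad at rate 0.002 decayed by 0.75 every
    20000 iterations."""

    n_taxa: int = 8
    beta: float = 0.008
    estimators: tuple = ("rws", "rwsvr")
    R_values: tuple = (10,)
    F: int = 1000
    iters_per_epoch: int = 100
    n_iters: int = 20000
    replicates: int = 5
    optimizer: str = "amsgrad"
    learning_rate: float = 0.002
    decay_every: int = 20000
    seed: int = 0


def run_vbpi_sim_study(spec: VbpiSimStudySpec, space=None,
                       support=None, compiled_space=None) -> pd.DataFrame:
    """ELBO and KL traces of RWS/RWSVR on the simulated branchless model.

    The SBN support is the full enumerated space, so the variational
    family can represent any target exactly and the ELBO is bounded above
    by the exact evidence log 1 = 0.  Returns a long table with columns
    (replicate, estimator, R, iteration, n_likelihood_computations,
    elbo, kl).
    """
    taxa = default_taxa(spec.n_taxa)
    if space is None:
        space = enumerate_unrooted(taxa)
    if support is None:
        support = build_support(space)
    if compiled_space is None:
        compiled_space = CompiledCollection(space, support)
    rows = []
    root_ss = np.random.SeedSequence(spec.seed)
    for rep, child in enumerate(root_ss.spawn(spec.replicates)):
        target_rng = np.random.default_rng(child)
        target_dist = dirichlet_target(space, spec.beta, target_rng)
        target = DiscreteTarget(target_dist.topologies, target_dist.probs,
                                log_probs=target_dist.log_probs)
        for estimator in spec.estimators:
            for R in spec.R_values:
                cfg = VbpiConfig(
                    estimator=estimator, R=R, F=spec.F,
                    iters_per_epoch=spec.iters_per_epoch,
                    n_iters=spec.n_iters, optimizer=spec.optimizer,
                    learning_rate=spec.learning_rate,
                    decay_every=spec.decay_every,
                    seed=int(target_rng.integers(2**31)),
                )
                result = run_vbpi(target, support, cfg, space=compiled_space)
                for _, r in result.trace.iterrows():
                    rows.append({
                        "replicate": rep, "estimator": estimator, "R": R,
                        "iteration": int(r["iteration"]),
                        "n_likelihood_computations": int(r["n_likelihood_computations"]),
                        "elbo": float(r["elbo"]),
                        "kl": max(float(r["kl"]), 0.0),
                    })
    return pd.DataFrame(rows)
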