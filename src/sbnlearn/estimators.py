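"""Trainers for SBN-based tree topology probability estimation.

Given a weighted sample of unrooted topologies (for instance the sample
relative frequencies of an MCMC run), the SBN log likelihood is

    L(c) = sum_k w_k log q(tau_k | c),

with the root position of each tree a latent variable.  This module
implements the trainer family:

* ``em`` — full-batch expectation maximization.  The E-step computes, per
  tree, the posterior of the virtual root over edges and the resulting
  expected frequency counts (EFCs); the M-step renormalizes the weighted
  counts groupwise.  With ``alpha > 0``, a symmetric Dirichlet prior on
  each CPD group is folded into the M-step (MAP-EM), giving ``em-a``.
* ``sem`` / ``semvr`` — stochastic EM: an exponential moving average of
  minibatch EFCs replaces the full-batch E-step; the variance-reduced
  variant recenters each minibatch EFC with full-batch sufficient
  statistics recomputed once per epoch (control variates) and clips the
  running average elementwise to keep the M-step well defined.
* ``ga`` / ``sga`` / ``svrg`` — (stochastic) gradient ascent on the latent
  softmax parameterization of the CPDs, optionally with the full-batch
  gradient as a once-per-epoch control variate.

Diagnostics: the data log likelihood and the inclusive KL divergence to a
known target distribution, with probability estimates clipped at 1e-40 so
out-of-support trees contribute a finite penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._compile import CompiledCollection, compile_topology
from .sbn import (
    CPDTable,
    LatentParams,
    OutOfSupportError,
    SubsplitSupport,
    build_support,
    groupwise_normalize,
    latent_to_cpd,
    simple_average_cpds,
)
from .trees import UnrootedTopology

__all__ = [
    "EFC",
    "SuffStats",
    "TrainConfig",
    "FitResult",
    "root_posteriors",
    "expected_frequency_counts",
    "full_suff_stats",
    "m_step",
    "log_likelihood",
    "grad_log_prob",
    "full_gradient",
    "run_em",
    "run_stochastic_em",
    "run_gradient_ascent",
    "sem_update",
    "semvr_epoch",
    "svrg_epoch",
    "kl_to_target",
    "fit",
]

EM_METHODS = ("em", "em-a")
SEM_METHODS = ("sem", "sem-a", "semvr", "semvr-a")
GRAD_METHODS = ("ga", "sga", "svrg")
DEFAULT_ALPHA = 1e-4  # regularization strength for the "-a" variants

#: Default learning rates per method (the benchmark study settings).
DEFAULT_LEARNING_RATES = {
    "sem": 0.001, "sem-a": 0.001,
    "semvr": 0.01, "semvr-a": 0.01,
    "sga": 0.0001, "svrg": 0.001, "ga": 0.01,
    "em": 0.0, "em-a": 0.0,
}


class SuffStats:
    """Aggregated sufficient statistics M over the support's parameters."""

    __slots__ = ("support", "values")

    def __init__(self, support: SubsplitSupport, values):
        self.support = support
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (support.n_params,):
            raise ValueError("sufficient statistics vector has wrong length")


class EFC(SuffStats):
    """Single-tree expected frequency counts; root entries sum to one."""


@dataclass
class TrainConfig:
    """Hyperparameters of the trainer family.

    ``learning_rate`` is the EMA rate (EM family) or step size (gradient
    family); ``iters_per_epoch`` is the number of minibatch iterations
    between full-batch recomputations; ``decay_every`` counts epochs for
    the sem/sga decaying schedule rho_n = rho * decay_rate^(n // (decay_every * T)).
    ``clip`` is the elementwise floor applied to the variance-reduced
    running statistics (machine epsilon by default).
    """

    method: str = "em"
    learning_rate: float = 0.01
    batch_size: int = 1
    iters_per_epoch: int = 1000
    epochs: int = 300
    decay_rate: float = 0.75
    decay_every: int = 50
    alpha: float = 0.0
    clip: float = float(np.finfo(float).eps)
    seed: int | None = 0
    tol: float = 1e-5

    def __post_init__(self):
        if self.method.endswith("-a") and self.alpha == 0.0:
            self.alpha = DEFAULT_ALPHA
        # batch_size 0 selects a deterministic full weighted pass in the
        # stochastic trainers (the degenerate reductions to EM / GA).
        if self.batch_size < 0 or self.iters_per_epoch < 1:
            raise ValueError("batch_size must be >= 0, iters_per_epoch >= 1")
        if self.clip <= 0 or self.alpha < 0:
            raise ValueError("clip must be > 0 and alpha >= 0")

    @property
    def base_method(self) -> str:
        return self.method[:-2] if self.method.endswith("-a") else self.method


@dataclass
class FitResult:
    cpds: CPDTable
    trace: pd.DataFrame
    phi: LatentParams | None = None
    n_likelihood_computations: int = 0


# ---------------------------------------------------------------------------
# E-step quantities


def _as_pairs(data):
    return [(d[0], float(d[1])) if isinstance(d, tuple) else (d, 1.0) for d in data]


def _normalized(data):
    pairs = _as_pairs(data)
    total = sum(w for _, w in pairs)
    if total <= 0:
        raise ValueError("dataset weights must have positive total")
    return [(t, w / total) for t, w in pairs]


def root_posteriors(tau: UnrootedTopology, c: CPDTable) -> np.ndarray:
    """Posterior probability of the virtual root lying on each edge,
    p(root = e | tau, c); sums to one."""
    return compile_topology(tau, c.support).root_posteriors(c)


def expected_frequency_counts(tau: UnrootedTopology, c: CPDTable) -> EFC:
    """Expected frequency counts of one tree: each rooting's factor
    occurrences weighted by that rooting's root posterior."""
    return EFC(c.support, compile_topology(tau, c.support).efc(c))


def full_suff_stats(data, c: CPDTable, compiled: CompiledCollection | None = None) -> SuffStats:
    """Weight-averaged EFCs over the dataset (weights normalized)."""
    pairs = _normalized(data)
    weights = np.asarray([w for _, w in pairs])
    if compiled is None:
        compiled = CompiledCollection([t for t, _ in pairs], c.support)
    return SuffStats(c.support, compiled.weighted_efc(c, weights))


def m_step(M: SuffStats, alpha: float = 0.0, prev: CPDTable | None = None) -> CPDTable:
    """Groupwise normalization of (M + alpha) — the closed-form maximizer
    of the EM lower bound, with an optional symmetric-Dirichlet MAP term.

    A group with zero total mass (possible only with ``alpha = 0``) keeps
    the previous CPD values when given, otherwise it is an error.
    """
    values = M.values + alpha
    totals = np.add.reduceat(values, M.support.group_starts)
    if np.any(totals <= 0) and prev is None:
        raise ValueError("a CPD group received zero mass and no fallback was given")
    out = groupwise_normalize(M.support, values, prev=None if prev is None else prev.values)
    return CPDTable(M.support, out, validate=False)


def log_likelihood(data, c: CPDTable, compiled: CompiledCollection | None = None) -> float:
    """L(c) = sum_k w_k log q(tau_k | c) with normalized weights."""
    pairs = _normalized(data)
    if compiled is None:
        compiled = CompiledCollection([t for t, _ in pairs], c.support)
    lq = compiled.log_probs(c)
    weights = np.asarray([w for _, w in pairs])
    if np.any(np.isneginf(lq[weights > 0])):
        raise OutOfSupportError("a tree in the dataset has probability zero")
    return float(np.dot(weights, np.where(weights > 0, lq, 0.0)))


# ---------------------------------------------------------------------------
# gradients in the latent (softmax) parameterization


def _grad_from_efc(c: CPDTable, m: np.ndarray) -> np.ndarray:
    """d log q / d phi from EFCs: within each group, counts minus the
    group's total count times the softmax probabilities."""
    sup = c.support
    gsum = np.add.reduceat(m, sup.group_starts)[sup.group_of]
    return m - c.values * gsum

def grad_log_prob(tau: UnrootedTopology, phi: LatentParams) -> np.ndarray:
    """Exact gradient of log q_phi(tau) with respect to the latent
    parameters; raises if the topology is out of support."""
    c = latent_to_cpd(phi)
    return _grad_from_efc(c, compile_topology(tau, phi.support).efc(c))


def full_gradient(data, phi: LatentParams, compiled: CompiledCollection | None = None) -> np.ndarray:
    """Gradient of the full-batch log likelihood (linearity of the EFC map)."""
    c = latent_to_cpd(phi)
    M = full_suff_stats(data, c, compiled)
    return _grad_from_efc(c, M.values)


# ---------------------------------------------------------------------------
# diagnostics


def kl_to_target(target, c: CPDTable, clip: float = 1e-40,
                 compiled: CompiledCollection | None = None) -> float:
    """Inclusive KL divergence sum_tau p(tau) log(p(tau) / q(tau)).

    ``target`` is anything with ``topologies`` and ``probs`` attributes
    (or a pair of such sequences).  Probability estimates below ``clip``
    are clipped so out-of-support topologies contribute a finite penalty.
    """
    if hasattr(target, "topologies"):
        tops, p = target.topologies, np.asarray(target.probs, dtype=float)
    else:
        tops, p = target
        p = np.asarray(p, dtype=float)
    if compiled is None:
        compiled = CompiledCollection(tops, c.support)
    q = np.maximum(np.exp(compiled.log_probs(c)), clip)
    pos = p > 0
    return float(np.sum(p[pos] * (np.log(p[pos]) - np.log(q[pos]))))


def _penalized_objective(loglik: float, c: CPDTable, alpha: float) -> float:
    if alpha == 0.0:
        return loglik
    with np.errstate(divide="ignore"):
        return loglik + alpha * float(np.sum(np.log(c.values)))


# ---------------------------------------------------------------------------
# full-batch EM


def run_em(data, config: TrainConfig | None = None, init: CPDTable | None = None,
           support: SubsplitSupport | None = None, target=None,
           space: CompiledCollection | None = None) -> FitResult:
    """Full-batch (MAP-)EM until ``config.epochs`` iterations or the log
    likelihood changes by less than ``config.tol``.

    The objective (penalized when ``alpha > 0``) is asserted to be
    non-decreasing at every iteration.  ``target``/``space`` add an
    inclusive-KL column to the trace.
    """
    config = config or TrainConfig(method="em")
    pairs = _normalized(data)
    support = support or (init.support if init is not None else build_support(pairs))
    compiled = CompiledCollection([t for t, _ in pairs], support)
    weights = np.asarray([w for _, w in pairs])
    c = init if init is not None else simple_average_cpds(pairs, support)
    alpha = config.alpha

    rows = []
    n_like = 0
    loglik = log_likelihood(pairs, c, compiled)
    obj = _penalized_objective(loglik, c, alpha)
    for epoch in range(config.epochs):
        M = SuffStats(support, compiled.weighted_efc(c, weights))
        c = m_step(M, alpha=alpha, prev=c)
        new_loglik = log_likelihood(pairs, c, compiled)
        new_obj = _penalized_objective(new_loglik, c, alpha)
        assert new_obj >= obj - 1e-8, (
            f"EM objective decreased: {obj} -> {new_obj}"
        )
        n_like += len(pairs)
        row = {"epoch": epoch + 1, "n_likelihood_computations": n_like,
               "loglik": new_loglik}
        if target is not None:
            row["kl"] = kl_to_target(target, c, compiled=space)
        rows.append(row)
        done = abs(new_loglik - loglik) < config.tol
        loglik, obj = new_loglik, new_obj
        if done:
            break
    return FitResult(cpds=c, trace=pd.DataFrame(rows), n_likelihood_computations=n_like)


# ---------------------------------------------------------------------------
# stochastic EM family


def sem_update(Mbar: SuffStats, batch, c: CPDTable, rho: float) -> SuffStats:
    """Exponential-moving-average E-step: blend the mean EFC of the
    minibatch into the running statistics with rate ``rho``."""
    m = np.zeros(c.support.n_params)
    batch = [b[0] if isinstance(b, tuple) else b for b in batch]
    for tau in batch:
        m += compile_topology(tau, c.support).efc(c)
    m /= len(batch)
    return SuffStats(c.support, (1.0 - rho) * Mbar.values + rho * m)


@dataclass
class _SemState:
    c: CPDTable
    Mbar: np.ndarray
    rng: np.random.Generator
    iteration: int = 0
    n_like: int = 0


def _draw_batch(rng, pairs, weights, size):
    idx = rng.choice(len(pairs), size=size, p=weights)
    return [pairs[i][0] for i in idx]


def _batch_mean_efc(batch, support, c, cache):
    m = np.zeros(support.n_params)
    for tau in batch:
        m += compile_topology(tau, support, cache).efc(c)
    return m / len(batch)


def semvr_epoch(state: _SemState, data, config: TrainConfig,
                compiled: CompiledCollection | None = None,
                cache: dict | None = None) -> _SemState:
    """One variance-reduced stochastic EM epoch.

    Full-batch sufficient statistics are computed once at the epoch-start
    CPDs and used as control variates: each inner iteration blends
    ``m_B(c_t) - m_B(c_0) + M(c_0)`` into the running average, which is
    clipped elementwise at ``config.clip`` before the M-step.
    """
    pairs = _normalized(data)
    weights = np.asarray([w for _, w in pairs])
    support = state.c.support
    if compiled is None:
        compiled = CompiledCollection([t for t, _ in pairs], support)
    cache = cache if cache is not None else {}
    c0 = state.c
    M0 = compiled.weighted_efc(c0, weights)
    state.n_like += len(pairs)
    rho = config.learning_rate
    for _ in range(config.iters_per_epoch):
        if config.batch_size == 0:  # deterministic full weighted pass
            m_t = compiled.weighted_efc(state.c, weights)
            m_0 = M0
            n_evals = len(pairs)
        else:
            batch = _draw_batch(state.rng, pairs, weights, config.batch_size)
            m_t = _batch_mean_efc(batch, support, state.c, cache)
            m_0 = _batch_mean_efc(batch, support, c0, cache)
            n_evals = config.batch_size
        state.Mbar = (1.0 - rho) * state.Mbar + rho * (m_t - m_0 + M0)
        clipped = SuffStats(support, np.maximum(state.Mbar, config.clip))
        state.c = m_step(clipped, alpha=config.alpha, prev=state.c)
        state.iteration += 1
        state.n_like += n_evals
    return state


def _sem_epoch(state: _SemState, pairs, weights, config: TrainConfig,
               cache: dict) -> _SemState:
    support = state.c.support
    for _ in range(config.iters_per_epoch):
        decay_steps = state.iteration // (config.decay_every * config.iters_per_epoch)
        rho = config.learning_rate * config.decay_rate ** decay_steps
        batch = _draw_batch(state.rng, pairs, weights, max(config.batch_size, 1))
        m = _batch_mean_efc(batch, support, state.c, cache)
        state.Mbar = (1.0 - rho) * state.Mbar + rho * m
        state.c = m_step(SuffStats(support, state.Mbar), alpha=config.alpha,
                         prev=state.c)
        state.iteration += 1
        state.n_like += len(batch)
    return state


def run_stochastic_em(data, config: TrainConfig, init: CPDTable | None = None,
                      support: SubsplitSupport | None = None, target=None,
                      space: CompiledCollection | None = None) -> FitResult:
    """SEM or SEMVR (optionally Dirichlet-regularized) training loop.

    The running statistics start at the full-batch sufficient statistics
    of the initial CPDs.  The trace records the log likelihood once per
    epoch; training stops after ``config.epochs`` epochs or when the
    epoch-to-epoch log likelihood change drops below ``config.tol``.
    """
    if config.base_method not in ("sem", "semvr"):
        raise ValueError(f"not a stochastic EM method: {config.method}")
    pairs = _normalized(data)
    support = support or (init.support if init is not None else build_support(pairs))
    compiled = CompiledCollection([t for t, _ in pairs], support)
    weights = np.asarray([w for _, w in pairs])
    c = init if init is not None else simple_average_cpds(pairs, support)
    rng = np.random.default_rng(config.seed)
    state = _SemState(c=c, Mbar=compiled.weighted_efc(c, weights), rng=rng)
    state.n_like += len(pairs)
    cache: dict = {}

    rows = []
    loglik = log_likelihood(pairs, c, compiled)
    for epoch in range(config.epochs):
        if config.base_method == "semvr":
            state = semvr_epoch(state, pairs, config, compiled=compiled, cache=cache)
        else:
            state = _sem_epoch(state, pairs, weights, config, cache)
        new_loglik = log_likelihood(pairs, state.c, compiled)
        row = {"epoch": epoch + 1, "n_likelihood_computations": state.n_like,
               "loglik": new_loglik}
        if target is not None:
            row["kl"] = kl_to_target(target, state.c, compiled=space)
        rows.append(row)
        done = abs(new_loglik - loglik) < config.tol
        loglik = new_loglik
        if done:
            break
    return FitResult(cpds=state.c, trace=pd.DataFrame(rows),
                     n_likelihood_computations=state.n_like)


# ---------------------------------------------------------------------------
# gradient ascent family


@dataclass
class _GradState:
    phi: LatentParams
    rng: np.random.Generator
    iteration: int = 0
    n_like: int = 0


def svrg_epoch(state: _GradState, data, config: TrainConfig,
               compiled: CompiledCollection | None = None,
               cache: dict | None = None) -> _GradState:
    """One SVRG epoch: the full-batch gradient at the epoch-start
    parameters recenters every minibatch gradient (Robbins-Monro ascent
    with a constant step size)."""
    pairs = _normalized(data)
    weights = np.asarray([w for _, w in pairs])
    support = state.phi.support
    if compiled is None:
        compiled = CompiledCollection([t for t, _ in pairs], support)
    cache = cache if cache is not None else {}
    phi0 = LatentParams(support, state.phi.phi.copy())
    c0 = latent_to_cpd(phi0)
    G_full = _grad_from_efc(c0, compiled.weighted_efc(c0, weights))
    state.n_like += len(pairs)
    for _ in range(config.iters_per_epoch):
        c_t = latent_to_cpd(state.phi)
        if config.batch_size == 0:  # deterministic full weighted pass
            m_t = compiled.weighted_efc(c_t, weights)
            m_0 = compiled.weighted_efc(c0, weights)
            n_evals = len(pairs)
        else:
            batch = _draw_batch(state.rng, pairs, weights, config.batch_size)
            m_t = _batch_mean_efc(batch, support, c_t, cache)
            m_0 = _batch_mean_efc(batch, support, c0, cache)
            n_evals = config.batch_size
        g = _grad_from_efc(c_t, m_t) - _grad_from_efc(c0, m_0) + G_full
        state.phi = LatentParams(support, state.phi.phi + config.learning_rate * g)
        state.iteration += 1
        state.n_like += n_evals
    return state


def run_gradient_ascent(data, config: TrainConfig, init: LatentParams | None = None,
                        support: SubsplitSupport | None = None, target=None,
                        space: CompiledCollection | None = None) -> FitResult:
    """GA, SGA or SVRG on the latent softmax parameterization.

    Initialization is phi = log(SA) with zero frequencies floored at
    1e-40, matching the EM family's simple-average start.
    """
    if config.method not in GRAD_METHODS:
        raise ValueError(f"not a gradient method: {config.method}")
    pairs = _normalized(data)
    support = support or (init.support if init is not None else build_support(pairs))
    compiled = CompiledCollection([t for t, _ in pairs], support)
    weights = np.asarray([w for _, w in pairs])
    if init is None:
        init = LatentParams.from_cpds(simple_average_cpds(pairs, support))
    rng = np.random.default_rng(config.seed)
    state = _GradState(phi=LatentParams(support, init.phi.copy()), rng=rng)
    cache: dict = {}

    rows = []
    loglik = log_likelihood(pairs, latent_to_cpd(state.phi), compiled)
    for epoch in range(config.epochs):
        if config.method == "svrg":
            state = svrg_epoch(state, pairs, config, compiled=compiled, cache=cache)
        elif config.method == "ga":
            for _ in range(config.iters_per_epoch):
                g = full_gradient(pairs, state.phi, compiled)
                state.phi = LatentParams(support,
                                         state.phi.phi + config.learning_rate * g)
                state.iteration += 1
                state.n_like += len(pairs)
        else:  # sga
            for _ in range(config.iters_per_epoch):
                decay_steps = state.iteration // (
                    config.decay_every * config.iters_per_epoch)
                lr = config.learning_rate * config.decay_rate ** decay_steps
                batch = _draw_batch(state.rng, pairs, weights,
                                    max(config.batch_size, 1))
                c_t = latent_to_cpd(state.phi)
                g = _grad_from_efc(c_t, _batch_mean_efc(batch, support, c_t, cache))
                state.phi = LatentParams(support, state.phi.phi + lr * g)
                state.iteration += 1
                state.n_like += config.batch_size
        c = latent_to_cpd(state.phi)
        new_loglik = log_likelihood(pairs, c, compiled)
        row = {"epoch": epoch + 1, "n_likelihood_computations": state.n_like,
               "loglik": new_loglik}
        if target is not None:
            row["kl"] = kl_to_target(target, c, compiled=space)
        rows.append(row)
        done = abs(new_loglik - loglik) < config.tol
        loglik = new_loglik
        if done:
            break
    return FitResult(cpds=latent_to_cpd(state.phi), trace=pd.DataFrame(rows),
                     phi=state.phi, n_likelihood_computations=state.n_like)


def fit(data, config: TrainConfig, **kwargs) -> FitResult:
    """Dispatch to the trainer matching ``config.method``."""
    if config.method in EM_METHODS:
        return run_em(data, config, **kwargs)
    if config.method in SEM_METHODS:
        return run_stochastic_em(data, config, **kwargs)
    if config.method in GRAD_METHODS:
        return run_gradient_ascent(data, config, **kwargs)
    raise ValueError(f"unknown method {config.method!r}")
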