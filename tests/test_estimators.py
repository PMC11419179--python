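"""Trainer family: E-step quantities, M-step, EM and the stochastic variants."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from sbnlearn import (
    CPDTable,
    LatentParams,
    OutOfSupportError,
    TrainConfig,
    build_support,
    expected_frequency_counts,
    full_gradient,
    full_suff_stats,
    grad_log_prob,
    kl_to_target,
    latent_to_cpd,
    log_likelihood,
    m_step,
    root_at_edge,
    root_posteriors,
    rooted_log_prob,
    run_em,
    run_gradient_ascent,
    run_stochastic_em,
    simple_average_cpds,
    unrooted_log_prob,
    unrooted_prob,
)
from sbnlearn._compile import CompiledCollection
from sbnlearn.estimators import SuffStats, _SemState, sem_update, semvr_epoch


@pytest.fixture
def dataset5(space5, rng):
    idx = rng.choice(15, 6, replace=False)
    w = rng.dirichlet(np.ones(6))
    return [(space5[i], float(x)) for i, x in zip(idx, w)]


def test_root_posteriors_bayes_oracle(space5, support5, rng):
    c = CPDTable.random(support5, rng)
    for tau in space5[::4]:
        rlp = np.array([rooted_log_prob(root_at_edge(tau, e), c)
                        for e in tau.edge_ids])
        expected = np.exp(rlp) / np.exp(rlp).sum()
        got = root_posteriors(tau, c)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got.sum() == pytest.approx(1.0)


def test_root_posteriors_uniform_case():
    # on 3 taxa all child clades are terminal, so uniform root CPDs give
    # uniform rooted probabilities and posterior 1/(2N-3) per edge
    from sbnlearn import TaxonSet, enumerate_unrooted
    taxa = TaxonSet("ABC")
    tau = enumerate_unrooted(taxa)[0]
    sup = build_support([tau])
    c = CPDTable.uniform(sup)
    np.testing.assert_allclose(root_posteriors(tau, c), 1 / 3)
    m = expected_frequency_counts(tau, c)
    np.testing.assert_allclose(m.values, root_posteriors(tau, c))


def test_efc_and_q_function_two_routes(space5, support5, rng):
    c_hat = CPDTable.random(support5, rng)
    c = CPDTable.random(support5, rng)
    logc = c.log_values()
    for tau in space5[::5]:
        m = expected_frequency_counts(tau, c_hat)
        assert m.values[: len(support5.root_subsplits)].sum() == pytest.approx(1.0)
        # route 1: EFC inner product with log c
        q1 = float(np.dot(m.values, logc))
        # route 2: posterior-weighted rooted log probabilities
        post = root_posteriors(tau, c_hat)
        q2 = sum(p * rooted_log_prob(root_at_edge(tau, e), c)
                 for e, p in zip(tau.edge_ids, post))
        assert q1 == pytest.approx(q2, abs=1e-10)


def test_full_suff_stats_linearity(space5, support5, dataset5, rng):
    c = CPDTable.random(support5, rng)
    M = full_suff_stats(dataset5, c)
    manual = np.zeros(support5.n_params)
    total = sum(w for _, w in dataset5)
    for tau, w in dataset5:
        manual += (w / total) * expected_frequency_counts(tau, c).values
    np.testing.assert_allclose(M.values, manual, atol=1e-12)
    assert M.values[: len(support5.root_subsplits)].sum() == pytest.approx(1.0)
    single = full_suff_stats([(dataset5[0][0], 1.0)], c)
    np.testing.assert_allclose(
        single.values, expected_frequency_counts(dataset5[0][0], c).values)


def test_m_step_closed_form_and_prior():
    from sbnlearn import TaxonSet, enumerate_unrooted
    taxa = TaxonSet("ABC")
    tau = enumerate_unrooted(taxa)[0]
    sup = build_support([tau])  # a single group of three root subsplits
    out = m_step(SuffStats(sup, np.array([3.0, 1.0, 0.0])))
    np.testing.assert_allclose(out.values, [0.75, 0.25, 0.0])
    # zero counts with a Dirichlet prior give the uniform distribution
    out = m_step(SuffStats(sup, np.zeros(3)), alpha=1.0)
    np.testing.assert_allclose(out.values, [1 / 3] * 3)
    with pytest.raises(ValueError):
        m_step(SuffStats(sup, np.zeros(3)))


def test_m_step_is_constrained_maximizer(support5, space5, rng):
    # the EM lower bound is separable per group; compare against SLSQP
    # with simplex constraints on a few groups
    c = CPDTable.random(support5, rng)
    M = full_suff_stats([(space5[i], w) for i, w in [(0, 0.4), (5, 0.6)]], c)
    sup = M.support
    out = m_step(M, prev=c)
    for g in [1, 2, 3]:
        sl = sup.group_slice(g)
        m = M.values[sl]
        if m.sum() <= 0 or sl.stop - sl.start < 2:
            continue
        k = sl.stop - sl.start
        res = minimize(
            lambda x: -float(np.dot(m, np.log(np.maximum(x, 1e-12)))),
            np.full(k, 1 / k),
            constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1}],
            bounds=[(0, 1)] * k, method="SLSQP")
        np.testing.assert_allclose(out.values[sl], res.x, atol=1e-5)


def test_log_likelihood_properties(space5, support5, dataset5, rng):
    from sbnlearn import TaxonSet, enumerate_unrooted
    taxa = TaxonSet("ABC")
    tau = enumerate_unrooted(taxa)[0]
    sup3 = build_support([tau])
    assert log_likelihood([(tau, 1.0)], CPDTable.uniform(sup3)) == pytest.approx(0.0)
    c = CPDTable.random(support5, rng)
    assert log_likelihood(dataset5, c) <= 0.0
    sup_small = build_support(space5[:1])
    with pytest.raises(OutOfSupportError):
        log_likelihood([(space5[14], 1.0)], CPDTable.uniform(sup_small))


def test_gradient_matches_finite_differences(space5, support5, rng):
    phi = LatentParams(support5, rng.standard_normal(support5.n_params))
    tau = space5[8]
    g = grad_log_prob(tau, phi)
    h = 1e-6
    for j in rng.choice(support5.n_params, 15, replace=False):
        up, dn = phi.phi.copy(), phi.phi.copy()
        up[j] += h
        dn[j] -= h
        fd = (unrooted_log_prob(tau, latent_to_cpd(LatentParams(support5, up)))
              - unrooted_log_prob(tau, latent_to_cpd(LatentParams(support5, dn)))
              ) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)
    # within-group entries sum to zero (softmax shift invariance)
    for grp in range(support5.n_groups):
        sl = support5.group_slice(grp)
        assert abs(g[sl].sum()) < 1e-10


def test_gradient_saturated_softmax_is_zero(space5, support5):
    from sbnlearn import decompose
    idx = support5.assignment_indices(decompose(root_at_edge(space5[0], 0)))
    phi = np.zeros(support5.n_params)
    phi[idx] = 60.0  # one huge logit along a single assignment
    g = grad_log_prob(space5[0], LatentParams(support5, phi))
    assert np.abs(g).max() < 1e-10


def test_full_gradient_matches_weighted_sum(space5, support5, dataset5, rng):
    phi = LatentParams(support5, 0.5 * rng.standard_normal(support5.n_params))
    g = full_gradient(dataset5, phi)
    total = sum(w for _, w in dataset5)
    manual = sum((w / total) * grad_log_prob(tau, phi) for tau, w in dataset5)
    np.testing.assert_allclose(g, manual, atol=1e-12)


def test_run_em_monotone_fixed_point_and_recovery(space5, support5, rng):
    # parameter recovery: exact SBN probabilities as weights over the full
    # space drive the inclusive KL to (numerical) zero
    c_true = CPDTable.random(support5, rng)
    probs = np.array([unrooted_prob(t, c_true) for t in space5])
    data = list(zip(space5, probs))
    res = run_em(data, TrainConfig(method="em", epochs=100, tol=1e-12),
                 support=support5)
    kl = kl_to_target((space5, probs), res.cpds)
    assert kl < 1e-6
    assert np.all(np.diff(res.trace["loglik"].to_numpy()) >= -1e-8)
    # fixed point: one more M-step barely moves the CPDs
    M = full_suff_stats(data, res.cpds)
    again = m_step(M, prev=res.cpds)
    assert np.abs(again.values - res.cpds.values).max() < 1e-6


def test_run_em_with_regularization_is_monotone(dataset5):
    res = run_em(dataset5, TrainConfig(method="em-a", epochs=40))
    assert len(res.trace) >= 1  # internal ascent assertion did not fire
    assert np.all(res.cpds.values > 0)  # MAP smoothing keeps mass everywhere


def test_sem_update_limits(dataset5, rng):
    sup = build_support(dataset5)
    c = CPDTable.random(sup, rng)
    Mbar = SuffStats(sup, np.full(sup.n_params, 0.1))
    batch = [dataset5[0][0]]
    m = expected_frequency_counts(batch[0], c)
    np.testing.assert_allclose(sem_update(Mbar, batch, c, 1.0).values, m.values)
    np.testing.assert_allclose(sem_update(Mbar, batch, c, 0.0).values, Mbar.values)


def test_minibatch_efc_is_unbiased(dataset5, rng):
    # E[m_B] over weighted resampling equals the full-batch statistics
    sup = build_support(dataset5)
    c = CPDTable.random(sup, rng)
    M = full_suff_stats(dataset5, c).values
    weights = np.array([w for _, w in dataset5])
    weights = weights / weights.sum()
    per_tree = np.stack([expected_frequency_counts(t, c).values
                         for t, _ in dataset5])
    reps = 20000
    picks = rng.choice(len(dataset5), size=reps, p=weights)
    est = per_tree[picks].mean(axis=0)
    se = per_tree[picks].std(axis=0) / math.sqrt(reps)
    assert np.all(np.abs(est - M) <= 3.5 * se + 1e-4)


def test_semvr_full_batch_rho_one_reduces_to_em(dataset5):
    sup = build_support(dataset5)
    init = simple_average_cpds(dataset5, sup)
    cfg_vr = TrainConfig(method="semvr", learning_rate=1.0, batch_size=0,
                         iters_per_epoch=2, epochs=2, tol=-1.0, seed=0)
    cfg_em = TrainConfig(method="em", epochs=4, tol=-1.0)
    r_vr = run_stochastic_em(dataset5, cfg_vr, init=init, support=sup)
    r_em = run_em(dataset5, cfg_em, init=init, support=sup)
    np.testing.assert_allclose(r_vr.cpds.values, r_em.cpds.values, atol=1e-12)


def test_semvr_same_point_update_driven_by_full_stats(dataset5, rng):
    # with c(h,t) = c(h,0) the stochastic terms cancel for any batch
    sup = build_support(dataset5)
    c0 = simple_average_cpds(dataset5, sup)
    weights = np.array([w for _, w in dataset5])
    weights = weights / weights.sum()
    compiled = CompiledCollection([t for t, _ in dataset5], sup)
    M0 = compiled.weighted_efc(c0, weights)
    rho = 0.3
    state = _SemState(c=c0, Mbar=M0.copy(), rng=np.random.default_rng(1))
    cfg = TrainConfig(method="semvr", learning_rate=rho, batch_size=1,
                      iters_per_epoch=1, epochs=1, tol=-1.0, seed=1)
    state = semvr_epoch(state, dataset5, cfg, compiled=compiled)
    expected = (1 - rho) * M0 + rho * M0  # m_B(c0) - m_B(c0) + M0
    np.testing.assert_allclose(state.Mbar, expected, atol=1e-12)


def test_semvr_clipping_floor(dataset5):
    cfg = TrainConfig(method="semvr", learning_rate=0.5, batch_size=1,
                      iters_per_epoch=20, epochs=2, tol=-1.0, seed=3)
    res = run_stochastic_em(dataset5, cfg)
    assert np.all(np.isfinite(res.cpds.values))
    assert cfg.clip == pytest.approx(2.22e-16, rel=1e-2)


def test_svrg_full_batch_reduces_to_ga(dataset5):
    sup = build_support(dataset5)
    init = LatentParams.from_cpds(simple_average_cpds(dataset5, sup))
    cfg_s = TrainConfig(method="svrg", learning_rate=0.1, batch_size=0,
                        iters_per_epoch=3, epochs=2, tol=-1.0, seed=0)
    cfg_g = TrainConfig(method="ga", learning_rate=0.1, iters_per_epoch=3,
                        epochs=2, tol=-1.0)
    r_s = run_gradient_ascent(dataset5, cfg_s, init=init, support=sup)
    r_g = run_gradient_ascent(dataset5, cfg_g, init=init, support=sup)
    np.testing.assert_allclose(r_s.phi.phi, r_g.phi.phi, atol=1e-10)


def test_svrg_variance_below_plain_stochastic_gradient(dataset5, rng):
    # near the optimum the control variate makes the minibatch gradient
    # nearly deterministic
    sup = build_support(dataset5)
    res = run_em(dataset5, TrainConfig(method="em", epochs=200, tol=1e-12),
                 support=sup)
    phi0 = LatentParams.from_cpds(res.cpds, floor=1e-12)
    phi_t = LatentParams(sup, phi0.phi + 0.01 * rng.standard_normal(sup.n_params))
    weights = np.array([w for _, w in dataset5])
    weights = weights / weights.sum()
    compiled = CompiledCollection([t for t, _ in dataset5], sup)
    c_t, c_0 = latent_to_cpd(phi_t), latent_to_cpd(phi0)
    from sbnlearn.estimators import _grad_from_efc
    G_full = _grad_from_efc(c_0, compiled.weighted_efc(c_0, weights))
    plain, vr = [], []
    for _ in range(400):
        k = rng.choice(len(dataset5), p=weights)
        tau = dataset5[k][0]
        g_t = _grad_from_efc(c_t, expected_frequency_counts(tau, c_t).values)
        g_0 = _grad_from_efc(c_0, expected_frequency_counts(tau, c_0).values)
        plain.append(g_t)
        vr.append(g_t - g_0 + G_full)
    var = lambda g: float(np.mean(np.sum((np.array(g) - np.mean(g, axis=0)) ** 2,
                                         axis=1)))
    assert var(vr) < var(plain)


def test_kl_two_routes_and_clipping(space5, support5, rng):
    c = CPDTable.random(support5, rng)
    p = rng.dirichlet(np.ones(15))
    direct = sum(pi * (math.log(pi) - math.log(max(unrooted_prob(t, c), 1e-40)))
                 for t, pi in zip(space5, p) if pi > 0)
    assert kl_to_target((space5, p), c) == pytest.approx(direct, abs=1e-10)
    assert kl_to_target((space5, p), c) >= -1e-12
    same = kl_to_target((space5, p), c)
    assert kl_to_target((space5, p), c, compiled=CompiledCollection(
        space5, support5)) == pytest.approx(same)
    # q identically zero on p's support: the clipping floor keeps KL finite
    sup_small = build_support(space5[:1])
    c_small = CPDTable.uniform(sup_small)
    missing = [t for t in space5 if unrooted_prob(t, c_small) == 0.0]
    p_miss = np.ones(len(missing)) / len(missing)
    expected = sum(pi * (math.log(pi) - math.log(1e-40)) for pi in p_miss)
    assert kl_to_target((missing, p_miss), c_small) == pytest.approx(expected)


def test_trace_bookkeeping_follows_method(dataset5):
    K = len(dataset5)
    r_em = run_em(dataset5, TrainConfig(method="em", epochs=3, tol=-1.0))
    assert list(r_em.trace["n_likelihood_computations"]) == [K, 2 * K, 3 * K]
    cfg = TrainConfig(method="sem", learning_rate=0.01, batch_size=1,
                      iters_per_epoch=5, epochs=2, tol=-1.0, seed=0)
    r_sem = run_stochastic_em(dataset5, cfg)
    # SEM costs T*B per epoch (plus the one-off initialization pass)
    diffs = np.diff([K] + list(r_sem.trace["n_likelihood_computations"]))
    assert list(diffs) == [5, 5]
    cfg_vr = TrainConfig(method="semvr", learning_rate=0.1, batch_size=1,
                         iters_per_epoch=5, epochs=2, tol=-1.0, seed=0)
    r_vr = run_stochastic_em(dataset5, cfg_vr)
    diffs = np.diff([K] + list(r_vr.trace["n_likelihood_computations"]))
    assert list(diffs) == [K + 5, K + 5]
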