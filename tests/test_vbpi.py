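"""Variational inference: branch family, SNIS gradients, ELBO, training."""

import math

import numpy as np
import pytest
from scipy import stats

from sbnlearn import (
    BranchParams,
    CPDTable,
    DiscreteTarget,
    LatentParams,
    PhyloTarget,
    TaxonSet,
    TrainConfig,
    VbpiConfig,
    anneal,
    build_support,
    enumerate_unrooted,
    latent_to_cpd,
    run_em,
    run_vbpi,
    sample_branches,
    simulate_alignment,
    unrooted_prob,
)
from sbnlearn._compile import CompiledCollection, compile_topology
from sbnlearn.vbpi import (
    ParticleSet,
    RwsvrState,
    draw_particles,
    elbo,
    elbo_exact,
    marginal_likelihood_is,
    reparam_grad_psi,
    rws_grad,
    rwsvr_grad,
    snis_weights,
)


@pytest.fixture
def discrete5(space5, support5, rng):
    p = rng.dirichlet(np.full(15, 0.1))
    return DiscreteTarget(tuple(space5), p)


@pytest.fixture
def phylo4(rng):
    taxa = TaxonSet("ABCD")
    space = enumerate_unrooted(taxa)
    tau = space[0]
    bl = rng.exponential(0.1, 5)
    aln = simulate_alignment(tau, bl, 10, rng)
    return build_support(space), PhyloTarget(aln)


def test_anneal_schedule():
    assert anneal(0) == pytest.approx(0.001)
    assert anneal(99900) == pytest.approx(1.0)
    assert anneal(200000) == 1.0
    assert anneal(50000) == pytest.approx(0.501)


def test_branch_lookup_sharing_and_purity(space5, support5):
    psi = BranchParams(support5)
    # zero parameters: every edge reads (mu, sigma) = (0, 1)
    mu, sigma = psi.lookup(space5[0])
    assert np.all(mu == 0.0) and np.all(sigma == 1.0)
    # two topologies sharing a split get identical parameters there
    psi.mu[:] = np.arange(psi.n_features, dtype=float)
    a, b = space5[0], space5[1]
    shared = a.splits & b.splits
    assert shared
    split = next(iter(shared))
    ea = [e for e in a.edge_ids if a.edge_split(e) == split][0]
    eb = [e for e in b.edge_ids if b.edge_split(e) == split][0]
    assert psi.lookup(a)[0][ea] == psi.lookup(b)[0][eb]
    # pure function: repeated calls identical
    np.testing.assert_array_equal(psi.lookup(a)[0], psi.lookup(a)[0])


def test_sample_branches_lognormal(space5, support5):
    psi = BranchParams(support5)
    psi.mu[:] = -1.0
    psi.log_sigma[:] = math.log(0.5)
    rng = np.random.default_rng(7)
    tau = space5[0]
    draws = np.array([sample_branches(psi, tau, rng)[0] for _ in range(4000)])
    assert np.all(draws > 0)
    # log lengths are Normal(mu, sigma) per edge (KS on the first edge)
    ks = stats.kstest(np.log(draws[:, 0]), "norm", args=(-1.0, 0.5))
    assert ks.pvalue > 0.01
    # eps recovers the draw
    bl, eps = sample_branches(psi, tau, np.random.default_rng(0))
    np.testing.assert_allclose(bl, np.exp(-1.0 + 0.5 * eps))


def test_snis_weights(rng):
    np.testing.assert_allclose(snis_weights(np.full(7, -3.0)), 1 / 7)
    w = snis_weights(rng.standard_normal(20))
    assert w.sum() == pytest.approx(1.0)
    dominant = snis_weights(np.array([0.0, -1e3, -1e3]))
    assert dominant[0] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        snis_weights(np.array([-np.inf, -np.inf]))


def test_rws_grad_single_particle_and_linearity(space5, support5, rng):
    from sbnlearn import grad_log_prob
    phi = LatentParams(support5, 0.3 * rng.standard_normal(support5.n_params))
    tau = space5[4]
    ps = ParticleSet([tau], np.zeros(1), np.ones(1))
    np.testing.assert_allclose(rws_grad(phi, ps), grad_log_prob(tau, phi),
                               atol=1e-12)
    ps2 = ParticleSet([space5[4], space5[9]], np.zeros(2), np.array([0.3, 0.7]))
    manual = 0.3 * grad_log_prob(space5[4], phi) + 0.7 * grad_log_prob(space5[9], phi)
    np.testing.assert_allclose(rws_grad(phi, ps2), manual, atol=1e-12)


def test_rws_score_identity(space5, support5, rng):
    # when the target equals q itself the expected gradient is zero
    phi = LatentParams(support5, 0.2 * rng.standard_normal(support5.n_params))
    c = latent_to_cpd(phi)
    q = np.array([unrooted_prob(t, c) for t in space5])
    target = DiscreteTarget(tuple(space5), q / q.sum())
    reps, acc = 800, []
    for _ in range(reps):
        ps = draw_particles(phi, None, target, 2, rng)
        acc.append(rws_grad(phi, ps))
    acc = np.array(acc)
    mean = acc.mean(axis=0)
    se = acc.std(axis=0) / math.sqrt(reps)
    assert np.all(np.abs(mean) <= 4 * se + 1e-3)


def test_rwsvr_cancellation_identities(space5, support5, discrete5, rng):
    phi0 = LatentParams(support5, 0.1 * rng.standard_normal(support5.n_params))
    ps = draw_particles(phi0, None, discrete5, 20, rng)
    grad0 = rws_grad(phi0, ps)
    state = RwsvrState(phi0=phi0, grad0=grad0)
    # phi_t = phi_0: the two R-sample terms cancel exactly
    np.testing.assert_allclose(rwsvr_grad(state, ps, phi0), grad0, atol=1e-12)
    # F = R with the epoch sample reused: output equals the RWS value
    state2 = RwsvrState(phi0=phi0, grad0=rws_grad(phi0, ps))
    np.testing.assert_allclose(rwsvr_grad(state2, ps, phi0), rws_grad(phi0, ps),
                               atol=1e-12)


def test_reparam_grad_matches_finite_differences(phylo4, rng):
    support, target = phylo4
    phi = LatentParams(support, 0.2 * rng.standard_normal(support.n_params))
    psi = BranchParams(support)
    psi.mu += 0.2 * rng.standard_normal(psi.n_features)
    psi.log_sigma += 0.1 * rng.standard_normal(psi.n_features)
    beta = 0.7
    ps = draw_particles(phi, psi, target, 5, rng, beta)
    gmu, gls = reparam_grad_psi(psi, ps, target, beta)
    c = latent_to_cpd(phi)

    def objective(mu, log_sigma):
        p2 = BranchParams(support)
        p2.mu, p2.log_sigma = mu, log_sigma
        val = 0.0
        for tau, eps, w in zip(ps.topologies, ps.eps, ps.weights):
            if w == 0:
                continue
            m, s = p2.lookup(tau)
            bl = np.exp(m + s * eps)
            lq = compile_topology(tau, support).log_prob(c) + p2.log_density(tau, bl)
            val += w * (target.log_joint(tau, bl, beta) - lq)
        return val

    h = 1e-6
    for j in rng.choice(psi.n_features, 6, replace=False):
        up, dn = psi.mu.copy(), psi.mu.copy()
        up[j] += h
        dn[j] -= h
        fd = (objective(up, psi.log_sigma) - objective(dn, psi.log_sigma)) / (2 * h)
        assert gmu[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        up, dn = psi.log_sigma.copy(), psi.log_sigma.copy()
        up[j] += h
        dn[j] -= h
        fd = (objective(psi.mu, up) - objective(psi.mu, dn)) / (2 * h)
        assert gls[j] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_reparam_grad_zero_in_expectation_at_optimum(phylo4, rng):
    # target proportional to q along the psi-path: the pathwise gradient
    # has zero expectation (it is the optimum), checked at 3 sigma
    support, _ = phylo4
    phi = LatentParams.zeros(support)
    psi = BranchParams(support)
    psi.mu[:] = -1.5

    class SelfTarget:
        has_branches = True

        def log_joint(self, tau, bl, beta=1.0):
            c = latent_to_cpd(phi)
            return (compile_topology(tau, support).log_prob(c)
                    + psi.log_density(tau, bl) + 2.5)  # constant offset

        def branch_grad(self, tau, bl, beta=1.0):
            mu, sigma = psi.lookup(tau)
            z = (np.log(bl) - mu) / sigma
            return (-1.0 - z / sigma) / bl

    target = SelfTarget()
    acc_mu = []
    for _ in range(600):
        ps = draw_particles(phi, psi, target, 2, rng)
        gmu, gls = reparam_grad_psi(psi, ps, target)
        acc_mu.append(np.concatenate([gmu, gls]))
    acc = np.array(acc_mu)
    mean = acc.mean(axis=0)
    se = acc.std(axis=0) / math.sqrt(len(acc))
    assert np.all(np.abs(mean) <= 4 * se + 1e-3)


def test_elbo_exact_properties(space5, support5, discrete5, rng):
    # evidence of the simulated model is log 1 = 0, and ELBO at Q = p0 is 0
    assert elbo_exact(discrete5.probs, discrete5.log_probs) == pytest.approx(0.0)
    phi = LatentParams(support5, rng.standard_normal(support5.n_params))
    val = elbo(phi, discrete5)
    assert val <= 1e-12
    # matches manual summation
    c = latent_to_cpd(phi)
    q = np.array([unrooted_prob(t, c) for t in space5])
    manual = sum(qi * (math.log(pi) - math.log(qi))
                 for qi, pi in zip(q, discrete5.probs) if qi > 0)
    assert val == pytest.approx(manual, abs=1e-10)


def test_marginal_likelihood_exact_family_zero_variance(space5, support5, discrete5):
    # fit Q to the target exactly, then IS gives the true log evidence 0
    data = list(zip(space5, discrete5.probs))
    res = run_em(data, TrainConfig(method="em", epochs=200, tol=1e-13),
                 support=support5)
    phi = LatentParams.from_cpds(res.cpds)
    est, sd = marginal_likelihood_is(phi, discrete5, n_samples=100, n_reps=4,
                                     rng=np.random.default_rng(0))
    assert est == pytest.approx(0.0, abs=1e-5)
    assert sd < 1e-5


def test_marginal_likelihood_jensen_and_consistency(space5, support5, discrete5):
    # a mismatched Q underestimates the evidence on average, and the bias
    # shrinks with the sample size
    phi = LatentParams.zeros(support5)
    rng = np.random.default_rng(3)
    small = np.array([marginal_likelihood_is(phi, discrete5, n_samples=10,
                                             rng=rng)[0] for _ in range(60)])
    large = np.array([marginal_likelihood_is(phi, discrete5, n_samples=400,
                                             rng=rng)[0] for _ in range(60)])
    # Jensen: the expected log estimate cannot exceed the true log
    # evidence 0 (allow 3 standard errors of Monte Carlo noise)
    assert small.mean() <= 3 * small.std(ddof=1) / math.sqrt(small.size)
    assert large.mean() <= 3 * large.std(ddof=1) / math.sqrt(large.size)
    # consistency: the estimator concentrates as the sample size grows
    assert large.std(ddof=1) < small.std(ddof=1)


def test_run_vbpi_discrete_improves_and_is_deterministic(space5, support5, discrete5):
    comp = CompiledCollection(space5, support5)
    cfg = VbpiConfig(estimator="rwsvr", R=10, F=100, iters_per_epoch=25,
                     n_iters=200, learning_rate=0.05, seed=11)
    res1 = run_vbpi(discrete5, support5, cfg, space=comp)
    res2 = run_vbpi(discrete5, support5, cfg, space=comp)
    assert res1.trace.equals(res2.trace)
    assert (res1.trace["elbo"] <= 1e-12).all()
    assert res1.trace["elbo"].iloc[-1] > res1.trace["elbo"].iloc[0]
    # likelihood-computation accounting: R per iteration plus F per epoch
    expected = 25 * 10 + 100
    assert res1.trace["n_likelihood_computations"].iloc[0] == expected


def test_run_vbpi_rws_smoke(space5, support5, discrete5):
    comp = CompiledCollection(space5, support5)
    cfg = VbpiConfig(estimator="rws", R=10, iters_per_epoch=25, n_iters=100,
                     learning_rate=0.05, seed=5)
    res = run_vbpi(discrete5, support5, cfg, space=comp)
    assert np.isfinite(res.trace["elbo"]).all()
    assert res.trace["n_likelihood_computations"].iloc[-1] == 100 * 10


def test_run_vbpi_full_model_smoke(phylo4):
    support, target = phylo4
    cfg = VbpiConfig(estimator="rwsvr", R=5, F=20, iters_per_epoch=10,
                     n_iters=40, learning_rate=0.05, seed=2, anneal_iters=50)
    res = run_vbpi(target, support, cfg)
    assert res.psi is not None
    lb = elbo(res.phi, target, psi=res.psi, n_samples=100,
              rng=np.random.default_rng(0))
    est, _ = marginal_likelihood_is(res.phi, target, psi=res.psi,
                                    n_samples=200, rng=np.random.default_rng(1))
    assert np.isfinite(lb) and np.isfinite(est)
    assert lb <= est + 1.0  # the bound can only be exceeded by MC noise


def test_config_validation():
    with pytest.raises(ValueError):
        VbpiConfig(estimator="vimco")
    with pytest.raises(ValueError):
        VbpiConfig(estimator="rwsvr", R=100, F=10)
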