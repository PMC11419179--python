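# sbnlearn

Subsplit Bayesian networks (SBNs) for probability estimation over
phylogenetic tree topologies, with a family of scalable trainers and a
variational Bayesian phylogenetic inference (VBPI) engine.

## The problem

Bayesian phylogenetics summarizes the evolutionary relationships of N
taxa as a posterior distribution over unrooted bifurcating tree
topologies.  MCMC runs yield weighted samples of topologies, but the raw
sample relative frequencies support only the trees actually visited and
are unstable for low-probability trees.  SBNs fix this by modeling the
*splitting process* of a tree: a rooted topology is a chain of subsplits
(ordered bipartitions of clades), and a Bayesian network over subsplit
values with shared conditional probabilities,

```
q(tau)   = c_{s1} * prod_i c_{s_i | t_i}          (rooted)
q(tau_u) = sum_{e in E(tau_u)} q(tau_u rooted at e)  (unrooted; the root
                                                      is marginalized
                                                      over the 2N-3 edges)
```

generalizes smoothly across the whole topology space while remaining a
proper distribution.  The root placement is a latent variable, so the
maximum-likelihood parameters are found by EM — and, for large samples,
by the stochastic variants implemented here:

| method | update | variance reduction |
|---|---|---|
| `em`, `em-a` | full-batch E/M steps (optionally Dirichlet-MAP) | — |
| `sem`, `sem-a` | EMA of minibatch expected frequency counts | no |
| `semvr`, `semvr-a` | + epoch-wise full-batch statistics as control variates, clipped at machine epsilon | yes |
| `ga` / `sga` | (stochastic) gradient ascent on `c = softmax(phi)` | no |
| `svrg` | + epoch-wise full-batch gradient as control variate | yes |

For VBPI the SBN is paired with a split-amortized diagonal lognormal over
branch lengths and trained against the (annealed) phylogenetic posterior
by self-normalized importance sampling: the reweighted wake-sleep (RWS)
gradient for the topology parameters, or its variance-reduced variant
(RWSVR) that recenters each iteration's R-particle gradient with a large
F-particle gradient cached once per epoch; branch parameters use the
reparameterization trick.  A JC69 pruning likelihood, priors, and a
sequence simulator make the whole stack testable on synthetic data, and
spaces of up to 9 taxa can be enumerated exhaustively so normalization,
ELBO and KL are exact.

See `docs/methods.md` for the model, estimators, defaults and
limitations in detail.

## Worked example

Estimate a deliberately hard target — a symmetric Dirichlet(0.01) draw
over all 10395 eight-taxon topologies, observed only through its top 500
trees:

```python
import numpy as np
from sbnlearn import (
    TaxonSet, enumerate_unrooted, build_support, dirichlet_target,
    topk_dataset, TrainConfig, run_em, run_stochastic_em, kl_to_target,
    simple_average_cpds,
)

rng = np.random.default_rng(0)
taxa = TaxonSet(f"t{i}" for i in range(8))
space = enumerate_unrooted(taxa)
print(f"8-taxon topology space: {len(space)} trees")

target = dirichlet_target(space, beta=0.01, rng=rng)
data = topk_dataset(target, K=500)
support = build_support(data)
print(f"support: {support.n_params} CPD parameters in {support.n_groups} groups")

sa = simple_average_cpds(data, support)
print(f"SA   KL(p || q) = {kl_to_target(target, sa):.4f}")

em = run_em(data, TrainConfig(method="em"), support=support)
print(f"EM   KL(p || q) = {kl_to_target(target, em.cpds):.4f} "
      f"after {len(em.trace)} epochs")

cfg = TrainConfig(method="semvr", learning_rate=0.01, batch_size=1,
                  iters_per_epoch=1000, epochs=10, seed=1)
semvr = run_stochastic_em(data, cfg, support=support)
print(f"SEMVR KL(p || q) = {kl_to_target(target, semvr.cpds):.4f} "
      f"after {semvr.n_likelihood_computations} likelihood computations")
```

Output:

```
8-taxon topology space: 10395 trees
support: 6997 CPD parameters in 2217 groups
SA   KL(p || q) = 0.4940
EM   KL(p || q) = 0.2358 after 92 epochs
SEMVR KL(p || q) = 0.2013 after 15500 likelihood computations
```

The simple average (the raw empirical-frequency baseline) is refined
substantially by EM, and the variance-reduced stochastic trainer reaches
a better inclusive KL than full-batch EM with far fewer likelihood
computations per update — the pattern that motivates the stochastic
family.  KL here is the inclusive divergence from the known target to
the SBN estimate, with out-of-support trees clipped at 1e-40.

## Command line

```
sbnlearn fit      --data trees.tsv --method semvr --lr 0.01 --out cpds.tsv --trace trace.csv
sbnlearn simstudy --n-taxa 8 --beta 0.01 -K 2000 --methods em,sem,semvr --out results.csv
sbnlearn vbpi     --alignment aln.fasta --enumerate --estimator rwsvr -R 10 -F 1000 --out params/
sbnlearn vbpi-sim --n-taxa 8 --beta 0.008 --iters 20000 --out sim.csv
```

Weighted tree datasets are plain text, one `<newick><TAB><weight>` per
line; CPD tables serialize to a readable TSV of `ROOT`/`COND` records.

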