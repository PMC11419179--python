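# Methods

## The model

`sbnlearn` estimates probability distributions over unrooted bifurcating
leaf-labeled tree topologies with subsplit Bayesian networks (SBNs).  A
*clade* is a nonempty subset of the N taxa (stored as a bitmask); a
*subsplit* is an ordered bipartition (W, Z) of a clade, with W above Z in a
fixed strict total order.  A rooted topology is equivalent to the subsplit
assignment produced by its splitting process — the root subsplit of the
full taxon set, then recursively the subsplit of each non-terminal clade —
and the SBN assigns it the probability

    q(tau) = c_{s1} * prod c_{s|t}

where `c_{s1}` is the root-subsplit probability and `c_{s|t}` the
conditional probability of child subsplit `s` given parent subsplit `t`,
shared wherever the pair occurs (*conditional probability sharing*).  An
unrooted topology's probability marginalizes the unobserved root position
over its 2N−3 edges:

    q(tau_u) = sum over edges e of q(tau_u rooted at e).

Two representational choices deserve note:

* **Normalization groups.**  The conditional distributions normalize per
  (parent subsplit, component clade): the child of the W-clade of `t` and
  the child of the Z-clade of `t` are distinct network nodes with distinct
  (shared) CPDs.  Grouping all children of `t` into one distribution would
  not define a proper network.  All parameters live in one flat vector laid
  out group-contiguously, so normalization, softmax, and M-steps are single
  `reduceat` passes.
* **Terminal clades.**  Clades of size ≤ 2 carry no parameter: a singleton
  cannot split and a two-leaf clade splits deterministically.  Omitting the
  forced factors changes nothing (they are identically 1).

The *support* — which root subsplits and parent-child pairs get parameters
at all — is the union over the training trees and all of their rootings.
Topologies not representable within the support have probability exactly
zero; diagnostics clip probability estimates at 1e−40 so such trees
contribute a finite KL penalty rather than an infinity.

The total order on clades is numeric comparison of bitmasks (descending).
Any strict total order is admissible; this one is fast and deterministic.

## Trainers for topology probability estimation

Given weighted topologies (weights need not be normalized; they are
normalized internally), the log likelihood `L(c) = sum_k w_k log q(tau_k|c)`
is a latent-variable objective with the root placement unobserved.

* **EM** (`em`, `em-a`): the E-step computes per-tree root posteriors over
  edges and the resulting *expected frequency counts* (EFCs) — the
  sufficient statistics; the M-step renormalizes the weighted counts per
  group.  With `alpha > 0` a symmetric Dirichlet prior is folded in by
  adding `alpha` to every count (MAP-EM); the printed default for the
  regularized variants is `alpha = 1e-4`.  The run asserts ascent of the
  (penalized, when `alpha > 0`) objective at every iteration and stops
  after 300 epochs or when the log likelihood moves by less than 1e−5.
* **SEM / SEMVR** (`sem`, `semvr`, `*-a`): stochastic EM keeps an
  exponential moving average of minibatch EFCs; minibatches (size 1 by
  default) are drawn with replacement proportionally to the weights.  SEM
  uses a decaying rate `rho_n = rho * 0.75^(n // (50 T))`; SEMVR uses a
  constant rate but recenters each minibatch EFC with full-batch
  sufficient statistics recomputed once per epoch (control variates) and
  clips the running average elementwise at machine epsilon
  (≈ 2.22e−16) so the M-step stays well defined.  Setting `batch_size=0`
  replaces the sampled minibatch by a deterministic full weighted pass;
  with `rho = 1` this reduces SEMVR exactly to EM (a tested identity).
* **GA / SGA / SVRG** (`ga`, `sga`, `svrg`): plain gradient ascent on the
  latent parameterization `c = softmax(phi)` per group.  The gradient of
  `log q` is computed in closed form from the EFCs
  (`m − c * groupsum(m)`), verified against central finite differences.
  SVRG recenters minibatch gradients with a full-batch gradient cached at
  each epoch start and uses a constant step size; `batch_size=0` reduces
  it exactly to GA.
* **SA** (simple average): the non-iterative baseline and the EM-family
  initialization — each tree's weight spread uniformly over its rootings,
  counts normalized per group.  The gradient family initializes at
  `phi = log SA` with zero frequencies floored at 1e−40.

Default learning rates follow the study settings: SEM 0.001, SEMVR 0.01,
SGA 0.0001, SVRG 0.001, GA 0.01, with T = 1000 iterations per epoch.
Trace tables record the likelihood-computation count per epoch (EM: K;
SEM/SGA: T·B; SEMVR/SVRG: K + T·B) so methods are comparable on a common
x-axis.

## Phylogenetic likelihood

The sequence model is Jukes-Cantor: uniform stationary distribution and a
rate matrix normalized to one expected substitution per unit branch
length, with the closed-form transition matrix
`P_ii = 1/4 + 3/4 e^{−4l/3}`, `P_ij = 1/4 − 1/4 e^{−4l/3}`.  The
`SubstitutionModel` container accepts any reversible rate matrix and falls
back to `expm`; only JC69 is instantiated because it is the model all of
the package's experiments use.  Site likelihoods are computed by
Felsenstein pruning over directional partial likelihoods with per-node,
per-site rescaling against underflow, and identical site columns are
collapsed to patterns.  Reversibility makes the value independent of root
placement (pulley principle, asserted to 1e−10); the implementation roots
at the first canonical edge.  Exact per-edge derivatives of the log
likelihood come from the same directional messages with `dP/dl` in closed
form.  Priors are uniform over topologies and i.i.d. Exp(10) branch
lengths; the unnormalized posterior kernel supports an annealing exponent
`beta` on the likelihood term only.  A forward simulator draws i.i.d.
sites from the same process, so the whole variational stack is testable
on synthetic alignments.

## Variational inference (VBPI)

The variational family is `Q_phi(tau) * q_psi(l | tau)`: an SBN over
topologies and a diagonal lognormal over branch lengths.  Branch
parameters are amortized by *split*: one (mu, log sigma) pair per observed
split of the taxon set (equivalently per root subsplit of the support),
an edge reading its parameters from the bipartition it induces.  Split
sharing is the minimal scheme satisfying the amortization contract; the
lookup is a pure function and zero initialization gives mu = 0, sigma = 1
on every edge.  Primary-subsplit-pair features would refine this and are
left as an extension.

Training maximizes the expected log variational density under the
posterior (minimum inclusive KL) with self-normalized importance sampling
from the variational family itself:

* **RWS**: the gradient for `phi` is the SNIS-weighted average of
  `grad log Q_phi` over R particles per iteration.
* **RWSVR**: adds a control variate — the same R particles' gradient
  evaluated at the epoch-start parameters — plus a large-sample (F ≫ R)
  gradient estimate drawn once per epoch at those parameters and held
  constant for T iterations.  When the iterate is at the epoch start the
  two R-sample terms cancel exactly and the estimator returns the cached
  constant (a tested identity).  Near convergence its empirical variance
  is orders of magnitude below RWS's (measured directly by
  `estimator_variance_study`).
* **psi** always uses the reparameterized pathwise gradient through
  `l = exp(mu + sigma * eps)`, with per-edge chain rule
  `d/dmu = D l + 1` and `d/dlog sigma = (D l + 1) sigma eps + 1`
  (`D` the derivative of the log target joint in the branch length; the
  +1 terms are the lognormal entropy), verified against finite
  differences.  No variance reduction is applied on psi.

Defaults mirror the study settings: R = 10, F = 1000, T = 100, AMSGrad at
0.002 (simulated) or Adam at 0.001 (sequence data), decay 0.75 every
20000 iterations, annealing `beta_t = min(1, 0.001 + t/100000)`, and
`phi` initialized to zeros (uniform CPDs).  The epoch constant is
recomputed with the annealing temperature current at its epoch start.
Particles falling outside the target's support get zero weight; an
all-zero-weight iteration skips the update.

Two targets are supported: the full phylogenetic model (alignment +
priors, annealed) and a *branchless simulated model* — an explicit
normalized distribution p0 over an enumerated topology space, for which
the evidence is exactly log 1 = 0 and the ELBO
`sum_tau Q(tau) log(p0(tau)/Q(tau)) <= 0` is computed exactly by
summation.  Marginal likelihoods are estimated by importance sampling
(log-mean-exp of the unnormalized weights), reported with a standard
deviation over independent replicates.

## Synthetic benchmarks

The simulated estimation benchmark draws a target from a symmetric
Dirichlet over the enumerated 8-taxon space (10395 topologies, the
largest space that is exhaustively enumerable at desk scale; spaces up to
9 taxa are supported).  Concentration `beta` controls diffusion; the
data are the top-K topologies with renormalized target probabilities as
weights — noiseless weights, which isolates estimator behavior from
sampling noise in the weights themselves.  Because Dirichlet mass ignores
topological similarity, the task is deliberately hard for models that
generalize through shared subsplits.  At very small `beta` (0.008) most
coordinates underflow the linear scale, so targets are sampled in log
space (Gamma(beta) = Gamma(beta+1) · U^(1/beta)) and exact log
probabilities are carried alongside; ELBO sums use them, keeping the
bound finite.

What this generator does *not* emulate: posterior correlations between
topologically similar trees (real phylogenetic posteriors concentrate
mass on neighborhoods), MCMC sampling noise in the weights, and
alignment-level model misspecification.  Passing benchmarks here
demonstrates correct optimization and the variance-reduction mechanics,
not accuracy on real sequence data.

Desk-scale sizes: the study drivers default to 20000 iterations and 5
replicates (the full-scale printed settings, 200000 iterations and 10
replicates, are reachable via flags); the tests and the acceptance script
further shrink to 2000 estimator iterations / 1000 VBPI iterations with
5 replicates and K = 500, sizes at which the qualitative orderings
(SEMVR ≤ SEM in final KL on concentrated targets; RWSVR ≥ RWS in final
ELBO at R = 10; Var(RWSVR) < Var(RWS) at 3 sigma with F = 1000) hold with
wide margins.  All study randomness derives from a single seed through
`SeedSequence` spawning; identical seeds reproduce identical tables
bit-for-bit.

## Numerical choices and degenerate inputs

* Out-of-support factors index a sentinel log-probability slot holding
  −inf, making out-of-support rootings exact zeros without branching.
* KL and ELBO diagnostics clip q at 1e−40; reported KL medians are
  clamped at zero (float summation can produce −1e−16).
* M-step groups with zero mass (possible only with `alpha = 0`) keep
  their previous values; in the SA estimator they fall back to uniform.
* The SEMVR chain is kept unclipped; the elementwise floor at machine
  epsilon is applied to the copy entering the M-step.
* Ties in top-K selection break by enumeration order (stable argsort).
* Per-node likelihood rescaling divides by the per-site maximum and
  accumulates log scales; sites with zero likelihood (contradictory
  leaves across zero-length branches) propagate to −inf cleanly.
* Minibatch draws use `Generator.choice` with the normalized weights;
  enumeration order, canonical newick output, and edge ids are all
  deterministic functions of the topology, so every run is reproducible
  from its seed.

## Known limitations

* Bifurcating, leaf-labeled trees only; no multifurcations and no
  taxon-set reconciliation.
* The SBN structure is the full-and-complete binary tree network with
  conditional probability sharing; higher-order dependency structures are
  out of scope.
* JC69 only (no rate heterogeneity, GTR, or codon/protein models).
* Split-based branch amortization is the simplest admissible scheme;
  richer local-structure features and normalizing-flow branch families
  are not implemented.
* Exhaustive enumeration (and hence exact ELBO/KL evaluation) is limited
  to 9 taxa; larger problems require supplied tree samples for support
  construction and Monte Carlo diagnostics.
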