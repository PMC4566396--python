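# Methods

This note documents the models, estimators and numerical choices behind
`oncodict`, and what the synthetic benchmarks do and do not establish.

## Problem setting

Multi-sample aCGH cohorts measure DNA copy number as probe-level log2
ratios. The package addresses three linked questions: how to place
heterogeneous platforms on one coordinate system, how to summarize a
cohort as a small dictionary of recurrent alteration patterns, and how
to order those patterns into putative progression pathways.

## Virtual-probe grid and alignment

Cytogenetic bands (UCSC cytoBand format, 0-based half-open coordinates)
anchor a shared grid: every retained band is subdivided into
`n_per_band = 10` equal slots, and a virtual probe sits at each slot
midpoint. Bands on the acrocentric short arms 13p, 14p, 15p, 22p and on
the sex chromosomes are excluded; only autosomes are analyzed. The
centromere is located at the junction of the two acen-stained bands —
the only centromere annotation the cytoBand format carries.

Each sample is resampled onto the grid by within-band K-NN: a virtual
probe takes the unweighted mean of its min(k, m) genomically nearest
real probes among the m probes of its own band (k = 10 is an upper
bound). Ties at the cut distance are all included, so the estimate is
independent of input ordering. Bands without any real probe are imputed
with 0 — the neutral log-ratio — and flagged in the log; imputing the
neutral value avoids leaking signal across band boundaries. No z-score
or other per-sample standardization is applied: a profile constant at c
resamples to exactly c.

Averaging k noisy probes shrinks probe noise by sqrt(k); the round-trip
benchmark checks the resulting error against the union-bound normal
quantile for the maximum over all L x S estimates (about 5 sigma at
alpha = 1e-4), since a 3-sigma band applies to a single estimate, not
to the maximum of several hundred.

## Dictionary model

Samples y_s (length L) are approximated by nonnegative combinations of
J shared atoms B = (beta_j):

    min over B, Theta:
        sum_s ||y_s - B theta_s||^2
      + lambda * sum_j ||beta_j||_1^2
      + mu     * sum_j TV_w(beta_j)
      + tau    * sum_s ||theta_s||_1^2
    subject to 0 <= theta_js <= theta_max (default 1)

TV_w(beta) = sum_l w_l |beta_{l+1} - beta_l| with w_l = 0 exactly at
chromosome boundaries and centromeres, so the fused penalty enforces
piecewise constancy within arms while alterations may start and end
freely at arm boundaries. The box constraint keeps coefficients
nonnegative and bounded, so gains and losses at one locus cannot cancel
and must be carried by separate atoms — this is what makes atoms
directly interpretable as alteration patterns. The squared-L1 terms
induce structured sparsity in atoms and per-sample atom usage.

### Optimization

A PALM-style alternating scheme: each block takes a proximal-gradient
step with step size 1/Lipschitz and a monotone backtracking halving
safeguard on the full objective.

* Coefficient block: the penalty tau*||theta||_1^2 plus the box
  constraint admits an exact joint prox — on the nonnegative box the L1
  norm is linear, so the KKT system reduces to a monotone scalar
  equation in s = sum(theta), solved by bracketing bisection.
* Atom block: the composite penalty lambda*||.||_1^2 + mu*TV_w is
  handled as the TV prox followed by the squared-L1 prox. The
  composition is inexact in general; the backtracking line search
  absorbs the error, and the objective-decrease invariant plus
  small-instance oracles bound its effect.

Both individual proxes are exact:

* squared-L1: soft-threshold at 2*sigma*s where s = ||x*||_1 solves a
  scalar fixed point found by sorting |z| and scanning the active set;
* weighted TV (1-D fused lasso with per-edge weights): a dynamic
  program on the piecewise-linear derivative of the cost-to-go, clipped
  to [-lam_t, +lam_t] at each edge, with backward clamping. Zero-weight
  edges split the signal into segments solved independently, which also
  guarantees fitted atoms incur no TV cost across arm boundaries.

Initialization: atoms from J randomly chosen samples plus 1% Gaussian
noise, coefficients Uniform(0, 0.5), all driven by one seed; identical
seeds give bit-identical traces. Stopping: relative objective change
below 1e-6 or `max_iter` sweeps (default 500). Desk-scale recovery
benchmarks run the cap at 1500 sweeps because the alternating scheme
approaches the planted solution slowly on flat regions of the
objective; recovery quality is a convergence question, not an
identifiability one, at these sizes.

### Model-size selection

J is the smallest number of principal components of the column-centered
cohort explaining at least 70% of the covariance (PCA via SVD). The
penalty triple (lambda, mu, tau) is chosen on a user grid by BIC =
(S*L) ln(RSS/(S*L)) + df ln(S*L), with df the number of entries of B
and Theta above 1e-8 in magnitude — the standard sparsity-aware df for
lasso-type models; ties break toward the stronger penalty.

## Atom interpretation

Probes with |beta| >= epsilon (default 0.1 on the log2 scale —
conservative for single-copy changes after within-band averaging) are
called gained or lost; a band is altered when any of its probes is
(majority direction if a band mixes signs, both directions on a tie);
maximal runs of adjacent same-direction bands merge into one call, and
labels collapse to arm ("+17q") or chromosome ("+7") when the run
covers them. Theta is binarized at 0.05 * theta_max (discarding
coefficients that reflect solver inexactness rather than atom usage)
to produce the per-sample binary atom patterns.

## Oncogenetic tree mixtures

A tree T places every atom under one parent (root R = no event) with an
edge probability p(child | parent); a pattern's probability is the
product over edges whose parent is present, and 0 when ancestor closure
is violated. A mixture M = sum_k a_k T_k adds a mandatory star noise
component (all atoms at depth 1) that models independent random
alterations and absorbs patterns no structured tree can produce. All
weights, including the star's, sum to 1.

### Single-tree estimation

Given (possibly fractional) pattern weights, edge u -> v scores

    W(u -> v) = n(u,v) ln p + (n(u) - n(u,v)) ln(1 - p)
                + n(v without u) * ln(eps)

with p = (n(u,v) + c)/(n(u) + 2c), pseudo-count c = 0.5, and n(R) = the
total weight. The ln(eps) term charges every observation that
contradicts the edge (child present, parent absent) as an error event
with probability eps (default 0.01). Without this term the plain
count score provably prefers the *reversed* edge on chain-generated
data — a child that never occurs without its parent gets p ~ 1 and
near-zero weight — so the term is what makes the maximum-weight
branching the maximum-likelihood tree of the error-tolerant model (and
of the strict model in the eps -> 0 limit, where the per-edge
decomposition is exact). The branching itself is solved by a
Chu-Liu/Edmonds implementation with a deterministic smallest-parent
tie-break (ties go to the root, so all-equal weights give the star);
it is validated against exhaustive enumeration and networkx.

### Mixture estimation

EM on the matching error-tolerant pseudo-likelihood (strict pattern
likelihood, except a present atom under an absent parent contributes
eps instead of 0). With that likelihood the penalized branching refit
is the exact M-step, so each sweep is monotone; the pseudo-counted
probabilities can introduce sub-1e-9 dips, which an accept-only-if-
nondecreasing safeguard removes. eps is annealed over (0.1, 0.01,
0.001): loose tolerance lets structure emerge while components are
still mixed; tight tolerance sharpens topology once responsibilities
separate. The surface is multimodal, so the fit restarts 8 times from
seeded initializations alternating two families — uniform random
splits, and splits induced by burden-weighted prototype patterns
(Jaccard assignment) — keeping the best final pseudo-likelihood. The
returned log-likelihood is the strict model's; the trace reported for
monotonicity is the final annealing stage of the winning restart.

Design constraints worth stating: hard compatibility vetoes collapse
components to stars whenever responsibilities are mixed; hard
cluster-then-fit seeding manufactures spurious edges from
boundary-induced co-occurrence; and a fixed-eps Bayes-net relaxation
(where absences under absent parents also pay (1 - eps)) is biased
toward tucking rare atoms under unrelated parents. The pseudo-
likelihood above avoids all three, which is why it is the fitting
objective.

### K selection

K (structured components) is user-set, default 1; the pipeline exposes
a scan over K in {1, 2, 3} scored by BIC over the strict pattern
log-likelihood with df = free edge probabilities + K mixture weights.

## Synthetic cohorts

The generator plants every structure the analysis assumes, as pure
functions of (parameters, seed):

* atoms: band-aligned piecewise-constant columns, magnitudes +-0.5
  (single-copy log2 scale) or +-1, events specified by label
  ("+17q") or drawn as 1-3 random whole-arm/sub-band events;
* coefficients: Bernoulli(sparsity/J) support with Uniform(0.5, 1)
  magnitudes — an expected `sparsity` (default 2) active atoms per
  sample; cohort Y = Theta^T B^T + Gaussian probe noise (default sd
  0.1, a realistic post-normalization aCGH noise level);
* probe-level profiles: per-band probe counts with jittered positions
  and independent probe noise (the inverse of the K-NN alignment);
* patterns: component chosen by mixture weight, then root-down
  sampling (child drawn only if its parent is present);
* ages: LogNormal months (median 18, sigma 0.6 — an infant/toddler
  neuroblastoma-like age scale) plus a location shift for carriers of
  loss atoms.

The default grid is 6 toy chromosomes x 5 bands x 10 probes (L = 300)
— large enough to exercise arm and centromere boundaries, small enough
for fast tests. A full-genome grid only requires passing a real
cytoBand file. Default cohorts use S = 60 samples.

The benchmark tree mixture plants two pathways over the same six atoms
as chains in opposite order (distinct initiating lesions), edge
probabilities 0.8/0.6/0.5 and 0.7/0.6/0.5, star weight 0.1 with
per-atom marginal 0.2. Opposite-order chains have pattern supports that
overlap only at the empty and full patterns, which makes the mixture
identifiable at n = 1000; with heavily overlapping supports the
maximum-likelihood mixture at this sample size genuinely differs from
the planted one, so exact-recovery benchmarks are not meaningful there.
Recovery degrades as the noise weight grows (at star weight 0.3
roughly a third of runs miss one edge); the reported recovery rates
are statements about the benchmark conditions, not about arbitrary
mixtures.

What the synthetic data do not emulate: raw two-channel intensities,
dye bias, wave artifacts, platform-specific probe densities, and any
normalization upstream of log-ratios. Noise is Gaussian and
independent across probes, which real aCGH violates (spatial waves,
outlier probes); passing benchmarks therefore demonstrate correctness
of the estimators under their assumed model, not robustness to real
measurement artifacts.

## Age-association test

Carriers of at least one atom from a chosen subset (typically the loss
atoms) are compared with non-carriers by a two-sided Mann-Whitney test
on age (exact null for small untied samples via scipy, normal
approximation otherwise). A rank test avoids assumptions on the skewed
age distribution; Fisher's exact test on age dichotomized at the median
is provided as an alternative. Calibration is verified empirically:
type-I error within the binomial 3-sigma band of 0.05 over 1000 null
simulations.

## Degenerate inputs and tie-breaks

* Empty bands: imputed 0, flagged; a chromosome with no probes warns.
* K-NN distance ties: all tied probes at the cut distance included.
* Zero-variance cohorts: J = 1.
* BIC ties: the larger (lambda, mu, tau) wins.
* Branching ties: smallest parent index (root first).
* Atoms never observed in any pattern: attached to the root.
* Mixed-sign bands: majority direction; exact ties report both.

## Known limitations

* The atom-block composite prox is a sequential composition, exact only
  in the limit; the line search guarantees monotonicity, not exactness.
* Tree-mixture recovery is benchmark-conditional (see above); K is not
  selected automatically by default.
* The alternating dictionary fit is non-convex; different seeds can
  reach different local minima, and desk-scale recovery required the
  1500-sweep cap rather than the 500 default.
* The pipeline consumes normalized log-ratios; QC filtering, intensity
  normalization and genome-build lift-over are upstream concerns.
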