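# Methods

## The model

aldmix infers the ancestral origin of chromosomal segments in admixed
individuals from dense, phased biallelic markers and K >= 2 modern
surrogate panels for the founding populations.  The genome is tiled
into fixed-width windows (default 0.1 cM); the hidden state of window
j on haplotype copy c of individual i is its ancestral population
g_ijc in {1..K}.

**Transitions.** The chain prior combines the haplotype's global
ancestry A_ic (a K-simplex) with persistence of the previous state:

    P(g_j = k) = A_k P(r_j) + gamma_{j-1,k} (1 - P(r_j))
    P(r_j)     = 1 - ((1 + exp(-2 d_j / 100)) / 2)^lambda

where d_j is the cM distance between consecutive window midpoints and
lambda the number of generations since admixture (per haplotype copy).
At lambda = 1 this reduces to the single-generation Haldane-type map
function (1 - exp(-2d/100))/2.  The first window of each chromosome is
treated as if preceded by a certain recombination (P(r) = 1), so its
prior is the global ancestry.  Equivalently the chain has kernel
T_j(k* -> k) = P(r_j) A_k + (1 - P(r_j)) 1[k = k*], which is
reversible with respect to A.

**Emissions.** Ancestral LD within each window is modeled indirectly:
for every window, a PCA of all markers within a support span (default
2 cM total, centered on the window) is fitted on the reference
surrogate panel, components are retained up to 80% cumulative
variance, and a logistic (K = 2) or multinomial (K > 2) principal
component regression of population membership on the projected
components yields a class posterior q_k(h) for a haplotype h.  The
emission of a window blends this with the member-marker allele
frequencies p_jk:

    e_jk = pbar_jk * P(X>0 | w) + q~_jk * (1 - P(X>0 | w))
    P(X>0 | w) = 1 - exp(-lambda w / 100)

where w is the support span in cM, pbar is the K-normalized Bernoulli
likelihood of the window's member alleles under each population's
frequencies, and P(X>0|w) is the probability that at least one
admixture-era crossover has disrupted the support haplotype -- in that
case the haplotype no longer resembles any single ancestral
population and only the marginal frequencies remain informative.
Windows holding a single marker, or whose support is monomorphic in
the reference panel, use the allele-frequency likelihood alone.
Missing alleles contribute a factor of 1.

q~ is the PCR posterior tempered by the exponent window/support
(~0.05 at the defaults): adjacent windows share almost their entire
support span, so an untempered chain would re-count every support
marker's evidence about twenty times, producing overconfident fields
whose sampled paths wobble across ancestry switches.  Tempering makes
the product of emissions along a chromosome count each marker's
evidence approximately once; in our validation runs it raised
window-level accuracy (93% -> 99% at desk scale) and removed a large
upward bias in the posterior of lambda.

**Smoothing.** Posteriors are computed by a scaled forward pass
(per-window renormalization; the recursion printed above) and an
emission-free backward pass of the same kernel; the normalized
product is the field gamma.  On every instance small enough to
enumerate (<= 4 windows, K <= 3) gamma matches exhaustive path
enumeration to 1e-10.  A formulation that multiplies two full
*posterior* chains instead double-counts both the local emission and
the prior and fails the uninformative-data identity (uniform
emissions must return gamma = A), so it was rejected.

## The sampler

A Metropolis-within-Gibbs sweep alternates (1) field computation and
ancestral-state sampling with (2) updates of every parameter block in
a fixed order: A, A_X, crossovers + lambda, p, beta, P, B, tau,
omega / omega_X, alpha.  All proposals are independence proposals of
conjugate form; acceptance ratios are the matching prior or
likelihood density ratios (Beta, Dirichlet, Gamma and normal density
ratios evaluated in full, including their normalizing constants,
which depend on the parameter being updated).

Ancestral states G are drawn as a joint path per chromosome
(forward-filter backward-sample through the kernel T).  The
crossover-count augmentation -- draw the Poisson crossover count
conditional on at least one crossover by CDF inversion, then keep it
with probability 1 - P(x = 0 | G), which is 0 when adjacent states
differ and exp(-mu)/(exp(-mu) + A_g(1 - exp(-mu))) when they agree --
conditions on agreement of *adjacent* states, which is only
meaningful when G is a path sample; independent per-window draws
create spurious switches that inflated lambda several-fold in pilot
runs.  An independent per-window categorical sampler is still
exported for field summaries.

Genetic distances entering Poisson rates (crossover sampling and the
rate increment of lambda's Gamma proposal) are in Morgans (d/100),
keeping lambda in units of generations everywhere.

Priors and hyperpriors: A ~ Dirichlet(omega) with log10(omega_k) ~
N(1, 0.5); A_X ~ Dirichlet(omega_X A) with scalar omega_X; lambda ~
Gamma(alpha1, alpha2) updated through the mean/variance
reparameterization m = alpha1/alpha2, v = alpha1/alpha2^2, each with
log10 prior N(1, 0.5); p ~ Beta(tau P, tau (1-P)); P ~ Beta(Omega)
with Omega the pseudocounted (Jeffreys 0.5) surrogate allele counts;
beta ~ N(B, diag(Sigma)/tau^2); B ~ N(H, diag(Sigma)); log10(tau) ~
N(2, 0.5).  A low posterior tau (< 100, strongly < 50) indicates
surrogate panels that fit the admixed sample poorly or allele flips.

Per-iteration beta refits use a warm-started, lightly ridge-penalized
IRLS on the haplotypes currently labelled by G; a window skips its
beta update in iterations with fewer than m + 5 assigned haplotypes.
Burn-in defaults to 100 iterations with 200 follow-on draws; traces
should be checked with the drift diagnostics.  Multiple chains run in
lockstep and, during burn-in only, blend each parameter with the
across-chain mean using weight iter/n_burn.

Initialization: window-wise maximum-likelihood classification under
the prior PCR with a uniform prior; both copies of an individual
start with equal global ancestry; lambda starts at 6 and tau at 300
(values appropriate for African-American-style admixture); other
hyperparameters start at their prior medians.

## Association statistics

Local ancestry enters the mapping models as the expected diploid
dosage (sum of the two haplotype posteriors, 0..2), which propagates
inference uncertainty.  The case-only model regresses global ancestry
on local dosage among cases (the conventional reversed direction is
available behind a flag); the general scan fits
link(Y) ~ local + global + covariates per window with a Wald test on
the local term; fine mapping adds the marker genotype and tests it,
conditioning on local and global ancestry.  Scans report Bonferroni
and Benjamini-Hochberg adjustments; collinear or non-convergent fits
are flagged, never silently dropped.

## The synthetic-data generator

The generator replaces external reference panels so the full pipeline
runs and is tested without downloads.  Per-marker ancestral
frequencies are Uniform(0.05, 0.95); population frequencies follow a
Balding-Nichols Beta spread with divergence parameter F (default
0.15, roughly a West-African/European contrast).  Within-population
LD: a pool of 100 founder haplotypes carries alleles thresholded from
a Gaussian AR(1) copula whose lag correlation is exp(-dcM/ld_decay)
(ld_decay 0.2 cM by default -- ancestral LD in humans rarely extends
past ~0.1-0.3 cM); panel haplotypes are Li-Stephens-style mosaics of
the founders with switch rate 1/ld_decay per cM.  The copula supplies
the founder LD that copying from an LD-free pool cannot create; the
copying supplies haplotype-block sharing between panel members.
Realized Hudson F_ST tracks the divergence parameter within 0.02.

Admixed chromosomes: per chromosome, lambda ~ Gamma(mean 6, sd 2) and
majority ancestry ~ Beta(mean 0.82, sd 0.1) (an African-American-like
history); breakpoints are a Poisson process of rate lambda per
Morgan; each segment copies a uniformly chosen panel haplotype from a
population drawn with probability G.  Truth labels, breakpoints and
source haplotypes are recorded.  PCR priors can be perturbed by
N(0, scale x SE) noise to emulate imperfect surrogates (scale 1 in
the validation experiment).

What the generator does not emulate: mutation and genotyping error,
coalescent depth within populations (the copula/copying process is a
phenomenological LD model), panel depletion (segments are drawn with
replacement), phasing errors, and variable marker density along real
maps.  Passing tests therefore demonstrate correctness of the
inference machinery under a realistic-in-spirit but idealized data
process, not performance on real cohorts.

## Validation experiments and problem sizes

The desk-scale experiment uses one 100 cM chromosome with 2,000
uniformly spaced markers, two panels of 100 haplotypes at divergence
0.15, 50 admixed individuals (100 chromosomes), perturbed priors, and
a 100 + 200 iteration chain -- sizes chosen so the whole experiment
completes in a few minutes on one CPU while leaving ~1,000 windows
and ~6 expected breakpoints per chromosome.  It reaches ~98-99%
window-level accuracy with the posterior means of lambda and global
ancestry within 10% of simulation truth.  Scan calibration draws
per-window dosages independently across 1,000 null windows (so the
type-I error estimate has binomial error ~0.007) from 1,000
individuals; windows on a real chromosome are correlated, so this
isolates the test's calibration from admixture LD.

## Numerical choices and edge cases

- PCA uses SVD of the column-centered panel; centering means are
  stored and applied at projection time.  Monomorphic support: zero
  loadings; fully monomorphic windows fall back to frequency
  emissions.
- Separation in any logistic fit (common with strongly diverged dense
  markers) triggers an L2 penalty of 1e-4 n; flagged in the log.
- All acceptance-ratio computations are in log space; p and P are
  clipped to (1e-9, 1 - 1e-9); gamma rows renormalize after every
  stage (sum-to-one enforced to 1e-10 in tests).
- Poisson CDF inversion for crossover counts iterates the recurrence
  term_k = term_{k-1} mu / k, exact for any mu.
- Windows are anchored at the first marker of each chromosome;
  midpoints are the mean cM of member markers (robust for one-marker
  windows); empty windows are dropped; inter-window d is undefined at
  chromosome starts.
- Sparse regions (gaps much larger than the window size) remain
  ordinary windows with a large d; the kernel handles d -> infinity
  by decoupling (prior reverts to A).

## Known limitations

- Phased input is required; unphased heterozygotes are either an
  error or, permissively, missing.
- The beta/B updates accept rarely when tau is large (the prior pins
  coefficients to the surrogate estimates); this is the intended
  behavior of the tight N(B, Sigma/tau^2) prior, not a defect, but it
  means the PCR coefficients are effectively prior-driven for
  well-matched surrogates.
- The case-only model as stated regresses global on local ancestry;
  its coefficient scale differs from the conventional direction.
- X-chromosome handling treats X as one more chromosome with its own
  global-ancestry prior A_X; no dosage-compensation modeling.
- Time-to-event phenotype links are out of scope (the GLM layer is
  extensible to them).
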