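# Methods

`memesel` detects codon sites that have experienced *episodic*
diversifying selection — positive selection confined to a subset of
lineages — in an in-frame coding alignment with a known phylogeny. This
note records the model, the estimation procedure, the numerical choices,
and what the bundled simulations do and do not demonstrate.

## Substitution model

Evolution at a codon site is a continuous-time reversible Markov chain
on the sense codons of the genetic code (61 states for the universal
code; other NCBI tables are supported). Only single-nucleotide changes
have nonzero instantaneous rate. For a change at codon position `k`
replacing nucleotide `x` with `y`,

    q_ij = scale * r * theta(x, y) * F_k[y],

where `r = alpha` for synonymous and `r = beta` for nonsynonymous
changes, `theta` are the six symmetric GTR exchangeabilities (identified
by `theta(A,G) = 1`, five free parameters), and `F` is a 3x4 matrix of
position-specific target-nucleotide frequencies. The equilibrium
distribution is the stop-excluded, renormalized product `F_1[x] F_2[y]
F_3[z]`, and `F` itself is estimated by the CF3x4 correction: the
position-specific marginals of that sense-codon distribution are matched
to the observed position-specific frequencies by least squares (12
constraints, 9 free parameters), because removing stop codons shifts
the marginals away from the raw parameter values.

Transition matrices are computed by symmetric eigendecomposition:
`Q(alpha, beta)` is similar to a symmetric matrix under the sqrt-pi
scaling, and because `Q(alpha, beta) = s * Q(alpha/s, beta/s)` with `s =
alpha + beta`, one decomposition (cached on the rate *direction*) serves
every branch length and overall rate. This is exact, stable for the
matrices that arise here, and roughly an order of magnitude cheaper than
repeated general matrix exponentials during optimization.

## The branch-site mixture and its likelihood

At a site, the synonymous rate `alpha` is shared by all branches, while
each branch *independently* draws its nonsynonymous rate: `beta_minus <=
alpha` with probability `1 - p_plus`, or an unrestricted `beta_plus`
with probability `p_plus`. The site likelihood marginalizes over all
`2^B` joint branch assignments; under branch-wise independence this
collapses to ordinary Felsenstein pruning with each branch's transition
matrix replaced by the convex combination

    P_b = (1 - p_plus) exp(Q(alpha, beta_minus) t_b)
        +      p_plus  exp(Q(alpha, beta_plus)  t_b).

The test suite verifies this identity against an explicit enumeration
over all branch configurations on small random trees (agreement to
1e-9), which is the central correctness property of the engine. Note
one subtlety: the *pure* (single-category) likelihood is invariant to
re-rooting, but the mixture likelihood is only invariant to operations
that preserve the branch set — splitting or merging edges at the root
changes how many independent category draws occur.

## Three-stage fitting

1. **Global fit.** GTR on the nucleotide-ized alignment provides
   starting values; its branch lengths are multiplied by three (per
   nucleotide site -> per codon site) and then *re-estimated* under the
   codon model with a single alignment-wide omega, since nucleotide
   fits can substantially underestimate codon branch lengths.
   Frequencies stay fixed at the CF3x4 estimates (nine extra free
   dimensions buy negligible likelihood). Optimization alternates
   per-branch Brent passes — using an inside-outside decomposition so a
   trial branch length costs one small matrix product — with bounded
   quasi-Newton passes over (theta, omega); the sweep converges when
   the log-likelihood improves by less than 1e-8. The normalizer
   making the mean substitution rate one at the global MLEs is frozen
   as `scale`, so per-site rates are multipliers on a calibrated tree.
2. **Per-site alternative fits.** FEL fits one (alpha, beta) pair per
   site (bounds [0, 1e4]; published sites can have huge beta interval
   endpoints, so the bound must be generous). The MEME alternative
   fits (alpha, beta_minus <= alpha, beta_plus, p_plus), parameterized
   with `beta_minus = f * alpha`, `f in [0, 1]` so the constraint is
   built in. Starts: a deterministic 12-point grid over `p_plus in
   {0.05, 0.25, 0.5, 1.0} x beta_plus in {FEL beta, 2 alpha + 1, 10}`
   warm-started at the FEL estimates; the grid is ranked by likelihood
   and local optimization runs from the best grid point *and* from the
   FEL-equivalent point (which guarantees the nesting invariant
   `lnL_alt >= lnL_FEL` by construction). Adding further local starts
   changed the fitted log-likelihoods by < 1e-4 across neutral and
   episodic simulations while tripling runtime, so one grid start is
   the default. Ties are broken toward the smallest `p_plus`.
3. **Null fit and test.** The null adds `beta_plus <= alpha`,
   implemented as an inequality via `beta_plus = f2 * alpha`: if the
   alternative MLE already satisfies it the LRT is exactly zero, making
   the test one-sided for diversification. Because the constrained
   parameter sits on a boundary, the LRT is referred to a mixture of
   chi-square distributions rather than chi-square(2): the default puts
   weight 1/3 on 1 df and 2/3 on 2 df, which sits between the
   too-liberal pure chi-square(1) and too-conservative chi-square(2)
   and can be checked or refit for any tree by the parametric-bootstrap
   calibrator (`memesel.calibrate`). The strict-neutral null (alpha =
   beta = 1 everywhere) is the worst case for this test, so its
   p-values are upper bounds; reported q-values are Benjamini-Hochberg
   across the sites of one alignment (site-wise, not family-wise,
   error control). A 2-df LRT comparing the MEME alternative with the
   FEL fit flags sites with branch-to-branch rate variation.

Rate profiles flatten at large rates (transition matrices saturate at
equilibrium), so one-dimensional fits bracket the optimum with a coarse
grid before Brent refinement rather than searching the full bound range.
Likelihood values of impossible parameter points are clamped to a large
finite penalty so finite-difference gradients stay defined. Invariant
columns (a single codon state compatible with every leaf) short-circuit
to LRT = 0, p = 1. Duplicate columns are fitted once and shared. All
fits are deterministic: identical inputs give bit-identical results.

## Empirical-Bayes branch reports

At sites the LRT flags, the posterior that branch `b` drew `beta_plus`
follows from Bayes' theorem with two extra pruning passes per branch:
the focal branch forced to the pure `beta_plus` (resp. `beta_minus`)
matrix while all other branches keep their fitted mixture matrices. The
empirical Bayes factor is the posterior-to-prior odds ratio; branches
with EBF >= 20 at sites with p <= 0.05 are flagged. This evidence rests
on one codon's evolution along one branch and carries no error-rate
control; it is exploratory output only, and the flag threshold is a
convention, not a calibrated test. EBFs are reported as undefined
(rather than infinite) when the prior or posterior is degenerate.

## Synthetic data

The simulator draws a root codon from the model equilibrium and samples
child states branch-by-branch from the exact transition matrices (no
within-branch stepping is needed; the process is observed only at
nodes). Site regimes are either constant `(alpha, omega)` or episodic
`(alpha, omega_minus, omega_plus, q_plus)` with independent per-branch
category draws, recorded in a truth table. Each site has its own RNG
stream derived from (master seed, site index), so alignments are
byte-reproducible regardless of evaluation order.

Default study conditions follow the simulation designs the test suite
reproduces: balanced 16- and 32-taxon trees with i.i.d. Uniform(0.05,
0.3) branch lengths (expected substitutions per codon site), a mildly
transition-biased exchangeability vector, and gently skewed position
frequencies — stand-ins chosen to be typical of vertebrate/viral coding
data. The strict-neutral null is `alpha = omega = 1` everywhere; the
episodic power scenario uses `omega_minus = 0, omega_plus = 36, q_plus
= 0.1`.

What the simulations do **not** emulate: indels and alignment error,
recombination breakpoints (handled only via user-supplied partitions),
site-to-site rate correlation, within-branch rate switching (covarion
behavior), and non-equilibrium base composition. Passing tests
demonstrate correctness and calibration *under the model*, not
robustness to these violations.

## Problem sizes used by the checks

Chosen so the whole suite runs on one CPU at desk scale:

- mixture-vs-enumeration oracle: 50 random 4-6-taxon trees;
- null calibration: 600 bootstrap sites, 8-taxon tree, with a one-sided
  95% DKW band on the p in [0.001, 0.1] tail;
- type-I error: 300 strict-neutral sites, 16 taxa;
- power comparison: 60 episodic sites, 32 taxa;
- recovery: 200 constant-omega sites at omega in {0.5, 1, 4}, 8 taxa;
- the acceptance script re-runs the strict-neutral study at full scale
  (1000 sites, 32 taxa).

Aggregate FEL bias is judged on the mean nonsynonymous rate and the
*median* synonymous rate: per-site `alpha` MLEs have a heavy upper tail
on small trees (a handful of synonymous events per site), which
dominates a naive mean.

## Known limitations

- Branch lengths and nuisance parameters are estimated once and treated
  as known by the site tests; their uncertainty is not propagated.
- The asymptotic mixture null is an approximation; for small trees the
  test is conservative (the bootstrap calibrator quantifies this for a
  given tree).
- Power against selection confined to a *single* branch, or driven by a
  single fixed substitution, is intrinsically low.
- The empirical-Bayes branch report cannot be turned into a controlled
  branch-level test; site-level and branch-level localization trade off
  against each other.
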