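# Methods

`phyloclock` estimates divergence times on a fixed rooted topology by
Bayesian MCMC, combining fossil-calibration densities, a birth-death prior
on node ages, a relaxed molecular clock, and an (optionally approximate)
amino-acid sequence likelihood. This note records the model, the numerical
choices, and what the synthetic data used in the test suite does and does
not establish.

## Time scale and parameterization

Node ages `t` are measured backwards from the present in units of 100 Myr
(tips at 0); file input/output is in Ma and converted at the boundary.
Rates are in substitutions/site/100 Myr, so a branch length in
substitutions/site is `duration x rate`. The parameter vector of a
posterior run is: the internal-node ages, the per-branch (IR) or per-node
(AR) rates for each partition, and per-partition hyperparameters
(mean/ancestral rate `mu`, rate variance `sigma2` or drift `nu`).

## Fossil calibration densities

Four families encode different readings of the fossil record for a clade
whose oldest confident fossil gives a minimum age `t_min` and whose
stratigraphic context gives a maximum `t_max`:

* **Soft-bound uniform** — density `(1 - p_L - p_U)/(t_max - t_min)` between
  the bounds, a power-decay tail on `(0, t_min)` carrying mass `p_L`, and an
  exponential tail above `t_max` carrying `p_U`; both tails are matched
  continuously to the interior height, so the density integrates to 1
  exactly. Defaults `p_L = p_U = 0.025` (conventional soft-bound practice;
  configurable).
* **Skew-normal** — an optimistic reading: mode close to `t_min`, light tail
  into the past. Location, scale and shape are solved numerically so that
  `CDF(t_min) = p_L` and `CDF(t_max) = 1 - p_U` hold exactly, with the
  shape chosen (by 1-D root finding over the quantile-matched family) to
  put the mode at `t_min + 0.1 (t_max - t_min)`; the resulting shape is
  positive and the mode always sits in the first 20% of the bound range.
  Forcing shape 0 reduces the family to a quantile-matched normal.
* **Truncated Cauchy** (long and short tailed) — a pessimistic reading with
  heavy mass into the past: for `t > t_min` a Cauchy with mode
  `t_min (1 + p)` and half-width `c t_min`, renormalized over
  `(t_min, inf)`; below `t_min` a power-decay tail with mass `p_L`. The
  tail-offset/scale defaults are `p = 0.1` with `c = 1.0` (long) and
  `c = 0.2` (short); both are configurable in the run setup so published
  values can be substituted. The below-minimum tail uses the same
  power-decay form as the soft-uniform lower tail so that every family
  normalizes exactly on `(0, inf)`.

For matched bounds, upper-tail mass orders as
cauchy-long > cauchy-short > skew-normal; this ordering is tested.

Calibration **strategies**: S1 applies soft-uniform everywhere; S2/S3/S4
switch 14 phylum and superphylum crown nodes to skew-normal / long
Cauchy / short Cauchy. (The primary description of the study design says
14 such nodes while its methods text says 13; this package follows the 14
highlighted rows of the packaged calibration table, and the set is
overridable.) The S1-Aldanella variant replaces the 552.85 Ma
Kimberella-based minima on the Protostomia lineage (Protostomia,
Bilateria, Eumetazoa, Metazoa) with the 532 Ma Aldanella minimum.
Minimum-only bounds are given the long-tail truncated Cauchy.

## Prior on node ages

Calibrated nodes carry their calibration density; every other internal
node carries the birth-death node-age kernel conditional on the root age
(birth `lambda`, death `mu`, sampling fraction `rho`; `rho = 0` is taken as
the limit, under which `lambda = mu` gives the uniform kernel
`1/t_root`). The root must be calibrated — an unbounded root age makes the
prior improper. The joint prior is the product of these terms truncated to
the parent-older-than-child region. This "multiply and truncate"
construction is a deliberate design choice: it reproduces the truncation
interactions that distort per-node marginals (the *effective prior*), and
prior-only MCMC runs expose exactly that distortion. The exact conditional
construction used by some dating programs is an alternative behind the
same interface.

The kernel CDF and quantile function are available in closed form
(including the `lambda = mu`, `rho -> 0`, and `lambda(1-rho) = mu`
degenerate branches), which the simulators use for inverse-transform
sampling.

## Relaxed clocks

* **IR (independent rates)**: branch rates i.i.d. lognormal with mean `mu`
  and log-variance `sigma2`, parameterized mean-preservingly (log-rate mean
  `log mu - sigma2/2`). The variance does not depend on branch duration;
  this is implemented literally.
* **AR (autocorrelated rates)**: node log-rates evolve by geometric
  Brownian motion: child log-rate ~ Normal(parent log-rate − dt·nu/2,
  dt·nu). The drift term keeps E[rate] constant along lineages; on a star
  phylogeny of depth `t` the tip log-rate variance is `t nu`, and at
  `t = 1` the tip distribution coincides with IR at `sigma2 = nu`. The
  ancestral (root) rate is identified with the hyperparameter `mu`
  carrying the gamma prior, and the branch rate is the arithmetic mean of
  the two endpoint node rates (a standard discretization; geometric-mean
  and midpoint alternatives exist and would change little at these scales).

Hyperpriors are gamma, defaults G(2, 40) for `mu` (mean 0.05/100 Myr =
5e-10 subst/site/year) and G(1, 10) for `sigma2`/`nu`. With `k` partitions
the per-partition values share a gamma-Dirichlet prior: gamma on the
across-partition mean, Dirichlet(1) proportions; `rate_prior_from_distance`
builds the `mu` prior from an observed pairwise distance and an assumed
divergence age (mean = distance / (2 age)).

## Sequence likelihood

Felsenstein pruning over site patterns under a reversible amino-acid model
(LG shipped as package data; Poisson equal-rates included because it
admits closed-form oracles), discrete-gamma rate variation (equal
probability categories, conditional-mean rates), and "+F" observed
frequencies with add-one smoothing (avoids zero frequencies on small
alignments). Gaps and unknown residues are fully ambiguous. Partials are
rescaled per pattern and category; branch lengths are floored at 1e-8
inside the transition-matrix computation so that conflicting residues
across a zero-length branch cannot produce exactly-zero partials (which
would leave the gradient undefined).

**Branch-length MLE** uses L-BFGS-B with an analytic gradient computed by
the standard two-sweep scheme (post-order partials, pre-order flow,
per-edge contraction with dP/db = QP); bounds keep b >= 0 and
non-convergence is reported with the final projected-gradient norm. Under
a reversible model the two root-adjacent branch lengths are identifiable
only through their sum; tests therefore compare tip-to-tip path lengths.

**Approximate likelihood** for dating is the second-order expansion
`l(b) = l(bhat) + g'(b-bhat) + (b-bhat)'H(b-bhat)/2` per partition. The
gradient is analytic; the Hessian is obtained by central finite
differences *of the analytic gradient* with per-branch step
`max(1e-4 bhat_i, 1e-6)` (one-sided at the b = 0 boundary, with a
warning), then symmetrized. Differencing the gradient rather than the
likelihood keeps the Hessian cost linear in the number of branches, which
is what makes the 54-taxon analyses fit on a desk. No branch-length
transform is applied in the expansion; a square-root-transform variant is
a known alternative and could be slotted in behind the same surface
object. Because the expansion matches value, gradient and curvature at
`bhat`, its error falls off cubically in the displacement; at 1%
displacement on a 6-taxon toy it is below 0.1 log-units, and posterior
node ages under approximate vs exact likelihood agree to within ~2% on
toy data.

## MCMC

Metropolis-within-Gibbs. Each sweep updates every internal node age
(uniform sliding window reflected into (oldest child, parent); the root
uses a positive multiplier), every rate variable per partition, the
hyperparameters (multipliers under the gamma-Dirichlet joint prior), and
ends with a mixing move rescaling all ages by `c` and all rates (and
`mu`, and `nu` under AR) by `1/c` with the exact Jacobian.

IR branch rates are sampled directly with log-space windows, and each
sweep additionally applies a *local* time/rate rescale at every internal
node: `t_v -> c t_v` with the child-branch rates rescaled so those branch
lengths are exactly invariant (only the branch above v enters the
likelihood ratio; the Jacobian is `c x prod_child (old duration / new
duration)` per partition). This moves directly along the local time-rate
ridge that single-variable updates cross slowly, and multiplies the
effective sample size of cherry-node ages several-fold. The AR
hierarchy is sampled in its **non-centered parameterization**: the state
holds standardized increments `eps_v ~ N(0, 1)` and the node log-rates
are derived as `x_v = x_parent - nu dt/2 + sqrt(nu dt) eps_v` (root
pinned to `log mu`). Sampling `(x, nu)` directly collapses into the
familiar `nu -> 0` funnel — the chain cannot leave near-clock states
because escaping requires a coordinated move of `nu` and every log-rate;
in the non-centered form `nu` and `mu` move freely with `eps` held
fixed, at the cost that an increment or age update touches the branch
lengths of the whole subtree below it (cheap: average subtree size is
O(log n)). Prior-sampling checks (the sampler run with a null
likelihood) reproduce the analytic `mu`, `nu` and node-age marginals for
both clocks.
branch lengths are invariant under this rescaling, so the likelihood term
cancels and the move directly attacks the time-rate confounding. Proposal
steps are tuned toward ~30% acceptance during burn-in only. Likelihood
deltas use rank-one updates of the cached quadratic form (approximate
path) or incremental re-pruning along the changed-edge-to-root path
(exact path). Chains are deterministic given a seed; convergence is
assessed by comparing per-parameter means across independent chains
against ESS-based Monte-Carlo standard errors (ESS via ArviZ).

Initial ages are drawn top-down to satisfy every hard minimum (and, where
feasible, maximum) bound, so chains start inside the truncated support.

## Synthetic data and what the tests show

The generators simulate: birth-death node ages by inverse-transform from
the kernel with tree shapes by random joins (all labeled histories
equally likely); IR/AR rates by their generative definitions; sites down
the tree with per-gene lognormal rate multipliers and gene-wise missing
data (whole gene absent in a taxon, mimicking supermatrix missingness).

`make_study_fixture` emulates the metazoan study at reduced scale: the
packaged 54-taxon labeled topology, the 34-bound calibration table, truth
ages drawn to satisfy every S1 hard-bound pair, IR rates with mean
0.089/100 Myr and log-variance 0.468 (study-scale posterior values used
as generative settings), and a 20-gene, 4,000-site LG+Gamma alignment
with ~15% gene-wise missing data. The scale is chosen so that full
posterior runs finish in minutes; the real study's 38,577-site
supermatrix is deliberately out of scope, so numerical posterior values
are not comparable with the study's tables — what the fixture supports
are structural and statistical properties: effective-prior truncation
(heavy-tailed strategies push mass beyond descendant maxima), coverage of
truth under matched priors, slope reduction in infinite-sites plots with
more partitions, and composite-interval behavior. The synthetic data do
not emulate alignment error, compositional heterogeneity, site-specific
selection, or topology error, so passing tests say nothing about those
real-data complications.

Analysis-scale choices in the test suite (two gamma categories for the
54-taxon runs, a few thousand MCMC sweeps, 2,000-site replicates for
coverage) are the package's desk-scale defaults; all are parameters, not
limits of the implementation.

## Known limitations

* The time prior truncates rather than renormalizes per-node; this is the
  documented design (it is the phenomenon under study), but it means the
  specified marginal densities are not exactly the sampled marginals even
  without ancestor-descendant conflicts in extreme nestings.
* Diversified/serial sampling variants of the birth-death prior are not
  implemented.
* The AR root rate equals the `mu` hyperparameter rather than carrying a
  separate diffuse prior.
* Bayes-factor comparison between clock models is out of scope; analyses
  are compared by the spread of their estimates.
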