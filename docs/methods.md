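# Methods

`hgtest` asks a single scientific question per gene: *is a phylogeny in
which a named taxon group is forced to be monophyletic significantly worse
than the unconstrained phylogeny?*  A "yes" is the statistical signature of
a horizontal (or endosymbiotic) gene transfer: the gene's history departs
from the species tree, so forcing the species-tree grouping costs
likelihood.  Two independent criteria are implemented — frequentist
site-likelihood topology tests and a Bayesian trace criterion — together
with the pre-filters applied before tree inference and a generator of
synthetic data with known truth.

## Substitution models

Amino-acid evolution is modelled as a reversible continuous-time Markov
chain, `Q_ij = s_ij π_j` for `i ≠ j`, with the diagonal completing zero row
sums and the matrix rescaled to one expected substitution per unit branch
length.  The packaged empirical matrices are LG (Le & Gascuel 2008) and WAG
(Whelan & Goldman 2001); any PAML-format `.dat` file can be plugged in, and
a Poisson (equal-rates) matrix is built in.  Transition matrices come from
the eigendecomposition of the reversibly symmetrized matrix
`diag(π)^{1/2} Q diag(π)^{-1/2}`, which is exact and cheap at 20×20.

Rate heterogeneity follows the standard `+I+G` construction: a zero-rate
invariant category of weight `p_inv` plus `n_cat` (default 4) equal-weight
discrete-gamma categories.  Category rates are the *mean* of each gamma
quantile slice (not the median), computed through the shape-`α+1` CDF, so
the unit-mean constraint holds exactly without renormalization.  `α` and
`p_inv` are free configuration parameters (default 1.0 and 0.1 when `+G` /
`+I` are requested without values); the package deliberately does not do
model selection.

## Likelihood engine

Felsenstein pruning over pattern-compressed alignment columns, with gaps,
`X` and `?` treated as missing data (partial likelihood 1 in every state).
Per-(category, pattern) log-scaling is applied only when a partial value
threatens underflow, and a site configuration of probability zero
(conflicting states across a zero-length path) yields `-inf` rather than an
exception so that downstream resampling stays well defined.  Likelihoods
are natural logs throughout.

Branch lengths are optimized coordinate-wise with a bounded 1-D method per
edge, lengths confined to [0, 10] expected substitutions per site.  The 1-D
profile of an edge is evaluated in the eigenbasis: with inside partials `u`
and outside partials `o` rotated once per edge, the likelihood as a
function of that edge's length is a small matrix–vector product, so each
Brent evaluation is essentially free.  A sweep reuses the round-start
partials for all edges (cheap, very occasionally non-monotone — then the
round is redone with per-edge refreshed partials), and convergence is
confirmed by a final exact Gauss–Seidel round.  Default tolerance 1e-6 lnL
units, at most 20 rounds.

A caveat found while validating: under the symmetric binary toy model with
long branches the likelihood surface has ridges (branch lengths are not
identifiable near saturation), and *any* coordinate optimizer will stop at
slightly different points on the ridge.  Closed-form and oracle tests for
that model therefore use short branches.

## Tree search and constraints

A monophyly constraint is a set of taxon groups, each required to be one
side of an unrooted bipartition; overlapping groups must be nested.
Exhaustive search enumerates all `(2n−5)!!` unrooted topologies (allowed up
to 8 taxa), filters by constraint compatibility, optimizes branch lengths
on each and returns the argmax.  The NNI mode hill-climbs from a
constraint-compatible starting tree (constrained groups nested as
caterpillar subtrees): all constraint-respecting nearest-neighbour
interchanges are scored with a two-round coarse optimization, the best two
candidates are optimized fully, and the search stops when neither improves
the current tree.  Coarse scores systematically underestimate a
candidate's optimum, which is why acceptance is decided only after full
optimization.

A transfer event is emulated by subtree prune-and-regraft: the recipient's
pendant edge is pruned and regrafted onto the edge subtending the donor
clade.

## Topology tests (RELL / KH / AU)

All tests consume a trees × sites matrix of site log-likelihoods.  RELL
replicates draw `round(scale · n)` site indices with replacement and sum
per-tree site values — no re-optimization.  The KH test compares two trees:
the observed total difference `δ` against centered replicate differences,
two-sided by default (a one-sided flag exists since a constraint is a
directional hypothesis), with add-one smoothing so `p ≥ 1/(n_rep+1)`.

The AU test measures the bootstrap proportion `bp(r)` of each tree being
best at ten replicate-size scales `r ∈ {0.5, …, 1.4}` (10,000 replicates
per scale by default, ties broken toward the lowest tree index and
flagged).  The probit-transformed curve `z(r) = Φ⁻¹(1 − bp(r))` is fitted
by weighted least squares to `d·√r + c/√r`, and `p_AU = 1 − Φ(d − c)`.
Only scales with informative proportions (strictly between 0 and 1) enter
the fit: a bp pinned at 0 or 1 contributes no usable probit value, and
fitting its clamped stand-in flattens the curve and drags `d − c` toward 0
— exactly the regime (one tree overwhelmingly better) where the test must
be decisive.  With fewer than two informative scales the tree is
essentially always or never best and receives the smoothed extreme
p-value, with a `degenerate_fit` flag.

## Bayesian trace criterion

From the stationary phase of an MCMC log-likelihood trace (first 25% of
samples discarded by default) two statistics are computed:

* `H = log n − logsumexp(−lnL_i)` — the log of the harmonic mean of the
  sampled likelihoods, a log marginal-likelihood estimate, computed in log
  space (safe for |lnL| up to ~1e5).  Note this is *not* the harmonic mean
  of the log-likelihoods; only the likelihood-space reading estimates a
  marginal likelihood and satisfies the −2 ratio below.
* `AICM = 2s² − 2·mean` of the stationary log-likelihoods (sample variance,
  n−1), lower better.

An unconstrained/constrained pair is significant when `ΔH > 3·SD` **and**
`−ΔAICM > 6·SD`, with SD the larger of the two traces' stationary standard
deviations.  For Gaussian traces `H ≈ m − s²/2`, so with equal variances
`ΔAICM/ΔH → −2`; the report exposes the ratio as a consistency diagnostic.
The harmonic-mean estimator is extreme-value dominated when the trace SD is
large (at SD 12 the estimate is effectively set by the smallest lnL
sample), so the ratio carries a few percent of Monte-Carlo spread per pair
even with 37,500 stationary samples — the acceptance computation averages
20 replicate pairs.

Trace diagnostics: ESS by the initial-positive-sequence autocorrelation
estimator, and a Gaussianity screen (|skewness| < 0.5 and |excess
kurtosis| < 1 by default), mirroring the visual stationarity checks usually
done in a trace viewer.  ESS is reported but does not gate comparisons.

## Pre-filters

* Dereplication: greedy scan in input order; a record is kept only if its
  identity to every kept record is ≤ 0.90 (configurable).  Identity =
  matches / columns where neither sequence is gapped, `X` never matches,
  zero overlap counts as 0.  Unaligned pairs are globally aligned first
  (Biopython `PairwiseAligner`) and the same column convention applied.
* Column extraction: keep alignment columns whose per-column consistency
  score (integer 0–9) lies in a window, 5–9 by default.

## Synthetic data

Species trees: uniform random resolved topology (random stepwise addition)
with i.i.d. Exponential(mean 0.15) branch lengths.  Alignments: per-site
rate category, root state from π, states propagated through each branch's
transition matrix; fully determined by a seed.  A transfer scenario regrafts
a random recipient onto a random donor clade that is disjoint from the
recipient's "home group" (recipient + smaller sister subtree) and at least
two edges away — counted strictly between the attachment node and the
regraft edge, so at least two edges are genuinely crossed.  The monophyly
constraint handed to the pipeline is the home group: true by construction
in null scenarios, false under a transfer, making type-I error and power
directly measurable.  Trace pairs are stationary Gaussian AR(1) series with
stated means, shared SD and autocorrelation.

What the generator does *not* emulate: indels, alignment uncertainty,
among-gene rate variation, model misspecification (data are simulated under
the analysis model), multiple transfers per gene, and real MCMC dynamics
(traces are AR(1) by fiat).  Passing tests therefore demonstrate the
statistical machinery under its own assumptions, not robustness to real
protein-family data.

## Pipeline and experiment driver

Per gene: optional dereplication → optional column extraction → constrained
then unconstrained ML search (NNI by default; the unconstrained search
starts from the constrained optimum, and the constrained lnL can never
exceed the unconstrained one) → site-likelihood matrix for the two trees →
KH + AU → optional Bayesian rule on a supplied trace pair.  The constraint
is "rejected" when both KH and AU fall below α = 0.05 and, when traces are
present, the Bayesian rule is also significant (conjunction; an any-of flag
exists).  If both searches return the same topology the verdict is "not
rejected" without resampling.  Reports are deterministic JSON given a seed.

Problem sizes used by the validation experiments: 6 taxa, 1000 sites and 50
scenarios for power; 1000 null site-likelihood simulations (200 sites, 499
replicates) for KH calibration; 1000 trace pairs of 50,000 samples for the
Bayesian false-positive rate.  These desk-scale sizes keep the full suite
in the minutes range while leaving the binomial confidence intervals tight
enough to be meaningful.

## Known limitations

* `α` and `p_inv` are fixed during tree search (set once, optionally by
  profile likelihood on the unconstrained tree) rather than re-optimized
  per constrained topology.
* NNI hill-climbing has no guarantee against local optima; the exhaustive
  mode is the reference below 9 taxa.
* The harmonic-mean marginal-likelihood estimator is known to be unstable;
  it is implemented because it is the statistic the decision rule is
  defined on, not because it is the best available estimator.
* One transfer event per scenario; donors are clades of the current tree.
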