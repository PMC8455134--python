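# Methods

This note documents the models implemented in famevol, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer would want
written down.

## Trees and branches

A species tree is rooted and time-calibrated, with branch lengths in
millions of years (My).  Node IDs are assigned by a deterministic post-order
traversal of the input Newick, so IDs are stable across runs and can be
serialized.  A branch is identified by its child node — "the branch leading
to X" — and the root has no branch.  Branch durations must be strictly
positive; zero-length input branches are rejected unless the caller opts in
to an epsilon substitution, because both the Dollo accounting (losses per
branch) and the birth-death kernel (α = λt/(1+λt)) degenerate at t = 0.
Basal polytomies are rejected by default (they usually indicate an unrooted
tree); when explicitly allowed, every child of a polytomy is treated
independently.

## Dollo reconstruction

The single-origin / multiple-loss model places each family's origin at the
MRCA of the species that possess it.  With gains costed infinitely above
losses and no outgroup evidence, this is the unique minimum-loss placement:
any deeper origin adds losses, any shallower one is inconsistent with a
single gain.  The test suite proves minimality by exhaustive enumeration of
all origins and internal presence assignments on every rooted binary shape
with up to six tips.

Per-node accounting follows the conventions of gain/loss summaries drawn on
a tree figure: `total_present`, `novel` (origins on the branch), `lost` and
`unique_lost` (families lost on that branch and nowhere else, tree-wide),
`core` (families present in every descendant tip) and `novel_core`.  Losses
are additionally reported stratified by the origin node of the lost family.
Both the per-family loss count (number of maximal absent subtrees under the
origin) and the per-(branch, origin) event counts are emitted, since summary
figures can be read either way.

Origins deeper than the sampled root are invisible: a family present in the
outgroup and all ingroups is simply "present at the root".  Likewise, when
losses eliminate an entire child subtree of the true origin, the MRCA of the
survivors is strictly below the origin and no parsimony method can recover
the deeper placement; the recovery test therefore asserts exact recovery
*conditional* on the origin remaining spanned by surviving tips (which holds
at 100%) and a looser unconditional bound.

## Birth-death family size

Family size follows the linear birth-death process with equal per-gene gain
and loss rate λ (per gene per My), the classic single-parameter model for
gene-family counts.  The transition probability over a branch of duration t
has the closed form given in the README, with size 0 absorbing.  Separate
birth and death rates, among-family rate variation, and annotation
measurement error are deliberately out of scope.

Numerics: the kernel is evaluated from cached log-binomial tables with a
signed summation over the index j.  Terms alternate in sign only when
λt > 1; the implementation is accurate for the λt ≲ 1 regime this package
targets (vertebrate-scale rates of ~1e-3 /gene/My on branches of tens to
hundreds of My).  Rows are truncated at `s_max` (default 100, matching the
copy-number filter) and renormalized; the pre-renormalization deficit is
monitored and is < 1e-8 for the sizes that pass the filter.  The martingale
property E[child | parent] = parent is verified to 1e-8 under ample
truncation.

The likelihood uses Felsenstein pruning over sizes 0..s_max with per-row
scaling.  The root prior defaults to geometric (p = 0.5) truncated to
1..s_max — a documented choice, not an inference; point-mass and uniform
priors are available.  Because the observation filter keeps only families
present in ≥ 2 species, the likelihood conditions on ≥ 2 non-extinct tips;
the conditioning probability is computed exactly from N+1 auxiliary pruning
passes (all-extinct and each leave-one-out pattern).  Ancestral sizes are
*marginal* posterior modes from the up-down algorithm (ties broken toward
the smaller size); marginal modes are well-defined per node and testable by
exhaustive enumeration, unlike a joint max-product path.  The conditioning
constant cancels in per-node marginals and is omitted there.

Fitting maximizes the summed per-family log-likelihood over one λ per branch
class on a log10 scale within [1e-8, 0.3]: Brent's bounded method for one
class, Nelder–Mead restarted from five seeded random starts for several
classes.  Non-convergence is flagged on the result, never silent.

The likelihood-ratio test between nested class maps is calibrated by
parametric bootstrap: datasets of equal family count are simulated under the
fitted null (same prior and conditioning, via the shared kernel sampler) and
both models are refitted; p is the fraction of replicates with a statistic
at least as large as observed, with p = 0 reported as "< 1/n_reps".  (The
opposite orientation — counting *smaller* replicates — would assign extreme
observations p ≈ 1 and is treated as a misstatement wherever encountered.)
Bootstrap refits use coarser optimizer tolerances (5e-3 in log10 λ) than the
headline fits; the resulting jitter in each replicate's statistic is two
orders of magnitude below the spread of the null distribution itself.

Per-branch shift p-values are the probability-ordering tail of the fitted
kernel row at the reconstructed (parent, child) sizes: p = total probability
of child states no more likely than the one observed.  This is the package's
exact-test stand-in with the same contract as the branch tests of
birth-death tools (small p ⇔ improbable transition); p < 0.05 flags a shift.
Branch rates are |size(parent) − size(child)| / t in copies per My; the
absolute value is used because mean rates are compared as magnitudes.

## Enrichment statistics

Representative family annotation uses the 75%/75% rule: a term labels a
family iff ≥ 75% of the family's proteins carry it and ≥ 75% of the family's
taxa have at least one carrying protein; unclustered proteins can be
promoted to singleton families.  Terms are opaque strings — no ontology
graph propagation.

The exact 2×2 test is two-sided by the probability-ordering (minimum-
likelihood) rule, with a 1e-7 relative tolerance for probability ties —
the convention of the standard implementations; mid-p or doubling rules
differ in the third decimal.  The reported odds ratio is the sample OR
(a·d)/(b·c) with a 0.5 continuity correction when any cell is zero; it is
reproducible without iterative estimation, but differs slightly from a
conditional-MLE OR, which matters when comparing to ORs computed elsewhere.
Benjamini–Hochberg correction is applied within each comparison (per branch
and annotation type), and the universe can be all families or annotated
families only (both are supported; the choice is the caller's).

## Giant-branch analyses

From the families × branches shift table, three family sets are built: all
shifted (any branch), shifted on a focal branch set, and shifted exclusively
on the set.  Enrichment of an external family set (e.g. cancer orthologs) is
tested on two universes: all families ("do cancer families shift more?") and
all shifted families ("do cancer families shift *on these branches*
specifically?").

Two controls guard the focal test.  The sister control repeats it with the
non-focal sister branches.  A caution discovered during calibration and
worth knowing: restricting the universe to shifted families induces a
collider — under a focal-only effect, non-focal-shifted families are
recruited into the universe preferentially when they carry the label, which
*depresses* the sister OR below 1 rather than inflating it.  The specificity
calibration therefore uses the all-families universe, where independence is
exact; a mildly sub-unit sister OR on the shifted universe is expected
behaviour, not evidence of a sister effect.

The permutation null redraws k (default 6) distinct branches uniformly from
all branches of the tree, rebuilds the shifted-on-set families and
recomputes the OR on the same universe; p is the fraction of null ORs at
least as large as observed (rank-based, hence invariant to monotone
transforms of the statistic).  Degenerate permuted tables contribute OR = 1
and are counted.  The focal set itself can be drawn — "without replacement"
applies within a draw only.

The interaction model regresses per-(family, branch) rates on
giant × cancer with a random intercept per family.  It is fitted by maximum
likelihood with the variance ratio θ = σ_u²/σ_ε² profiled out: the Woodbury
identity reduces each group's GLS solve to closed-form sufficient
statistics, leaving a 1-D bounded search over θ with the θ = 0 boundary
evaluated explicitly — at that boundary the estimator *is* OLS, exactly.
(A general-purpose mixed-model optimizer was not used because the standard
implementation fails with a singular Hessian precisely at this boundary.)
Wald z tests use a normal reference; with thousands of observations the
difference from finite-df corrections is negligible and is documented here
rather than modelled.  Rates enter untransformed by default; a log1p option
exists.  Stratified rate ratios report
mean(giant-branch rates)/mean(other-branch rates) separately for the
labelled and unlabelled strata, pooling (family, branch) observations.

## Synthetic data

The generator is the package's study-conditions oracle, not a convenience
fixture.  Defaults: 2000 families; background λ = 6e-4 /gene/My (the order
of magnitude of vertebrate-wide estimates); a two-fold multiplier on the
designated giant branches; geometric(0.5) root size conditioned ≥ 1; 5% of
families cancer-labelled with a 3:1 odds tilt; per-branch loss probability
0.1 for presence/absence simulation.  Trees are Yule trees rescaled to a
450 My root depth, the order of the vertebrate crown age.

Design choices worth stating:

- **Shared kernel.**  Count simulation samples child sizes by inverse CDF
  from the *same* truncated, renormalized kernel rows the likelihood uses,
  so parameter-recovery tests isolate the estimator — there is no
  simulator/model mismatch term.  Families surviving in fewer than two tips
  are redrawn, matching the likelihood's conditioning.
- **Per-branch Bernoulli losses** (with a per-My alternative) keep the
  presence generator exactly in the model class the Dollo reconstruction
  assumes.  A family may also be lost on the remainder of its own origin
  branch, in which case it is unobservable and redrawn; this makes the
  all-loss limit properly degenerate (bounded retries, then an error).
- **Ground-truth shifts.**  A family counts as "shifted on a giant branch"
  when some giant-branch jump is ≥ 2 copies; single-copy drift is the
  expected background at these rates and would dilute the label-shift
  coupling to nothing.  Cancer labels are then drawn without replacement
  with odds multiplied by the configured effect for shifted families —
  effect 1.0 makes the label exactly independent; effect → ∞ labels every
  shifted family first.
- **Annotations** are drawn at family level from per-term frequencies
  (log-uniform in [0.005, 0.2]) and inherited by proteins with 90% fidelity;
  terms are opaque and carry no ontology structure.

What the generator does not emulate, and hence what green tests do not show
about real data: orthology-inference errors (over-split or merged families),
annotation false negatives, correlated loss across related families,
among-family rate variation, lineage-specific root priors, and assembly or
annotation artifacts that masquerade as losses.  Conclusions about method
correctness transfer; conclusions about robustness to upstream error do not.

## Problem sizes used in tests and the acceptance script

The test suite proves exactness on exhaustively enumerable sizes (trees to
six tips; all 2×2 margins to n = 60; birth-death enumeration on trees to
four tips at s_max ≤ 10) and calibrates stochastic procedures at sizes
chosen to keep the full suite in the tens of minutes on one core: rate
recovery on 20 datasets of 2000 families × 10 tips; bootstrap and
permutation type-I error over 50 null seeds at 100 resamples each (80–600
families); Wald coverage over 200 seeds of 150 families × 10 branches.  The
acceptance script runs the default study conditions at 1200 families on a
12-tip tree with 200 bootstrap replicates and 100 permutations.  These sizes
are the package's reproducibility settings; the statistical properties they
check are size-free.

## Known limitations

- The kernel's signed summation loses precision for λt ≳ 1; rates and branch
  lengths far outside the calibrated regime need a different evaluation
  scheme (e.g. eigendecomposition of the truncated generator).
- Family-level shift status is derived from branch p-values (any branch
  p < 0.05); no family-wide multiple-testing correction is applied, matching
  the branch-test convention it mirrors.
- The five-class rate model is not implemented; fits with many sparse
  classes are known to be unstable in this model family.
- Polytomies are accepted only on request and are handled child-wise; Dollo
  minimality is proven for binary shapes.
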