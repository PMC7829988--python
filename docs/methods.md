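# Methods

## The problem

Amplicon surveys of host-associated microbiomes rarely agree at the level of
exact sequence variants: the same organism sequenced in two studies often
yields distinct ASV identifiers, and most individual ASVs are rare, so a
"core microbiome" defined by ASV prevalence alone is tiny and threshold
dependent.  `coreclades` implements an ecophylogenetic alternative: it asks,
for every monophyletic clade in an ASV phylogeny, whether the clade —
treated as a single taxonomic unit whose abundance in a sample is the sum of
its member tips' counts — is present in more samples than expected when tip
labels are assigned to the tree at random.  Clades that beat that null are
*core clades*; their response to environmental exposures is then profiled
with per-study negative-binomial regressions.

## Core-clade test

Let the rarefied count table be `X` (samples × ASVs) and `T` a rooted
phylogeny whose tips are the ASV ids.  For each internal node `c` with tip
set `L(c)`:

- clade abundance in sample `s`: `A(c, s) = Σ_{t ∈ L(c)} X[s, t]`;
- observed prevalence: `prev(c) = #{s : A(c, s) > 0} / #samples`, computed
  over the selected (by default control/unexposed) samples pooled across
  studies;
- null distribution: for each of `n_perm` replicates (default 999) a single
  uniform permutation of the tip↔ASV-label assignment is drawn, shared by
  all clades, and every clade's prevalence is recomputed.  Null mean and
  SD (sample SD, ddof = 1) are accumulated per clade;
- test: `z = (prev − null_mean) / null_sd` with a one-sided upper-tail
  normal p-value — "core" means *more* prevalent than chance, so the
  lower tail is irrelevant — followed by Benjamini–Hochberg FDR across all
  clades; `q < 0.05` (default) and `prev > null_mean` together flag a clade
  as core.  An exact permutation-rank p-value
  `(1 + #{perm ≥ obs}) / (n_perm + 1)` is emitted alongside as a
  diagnostic.

Because the permutation only relabels tips, the null distribution of a
clade's prevalence depends on its tip count alone; equal-size clades share a
null, which the test suite exploits as a consistency check.

Degenerate nulls (`null_sd = 0`, e.g. the root clade, whose prevalence is
permutation invariant) use a conservative convention: `p = 1/(n_perm + 1)`
when the observation exceeds the null mean, else `p = 1`.

### When the test has power

The null SD of a small clade's prevalence is driven by the chance that a
random label assignment hands it a high-prevalence tip.  If prevalent tips
make up a fraction `f` of all tips, a cherry's z-score scales roughly as
`(1 − 2f)/√(2f)`: the test separates planted cores from the null only when
prevalent tips are a small minority (a few percent).  This is exactly the
regime of real amplicon collections — thousands of ASVs, most of them rare —
and the synthetic defaults are chosen to reproduce it (2000 tips, ~35
planted-core member tips ≈ 1.7%).  On small trees where high-occupancy tips
are a sizeable fraction, the same planted clades are *not* detectable; tests
and the acceptance checks therefore run the recovery analyses at the
2000-tip scale.

## ASV merging and rarefaction

ASVs called independently per study are merged before analysis: a sequence
equal to, or a perfect contiguous substring of, another sequence is
agglomerated into the *maximal* representative (one that is not a proper
substring of any other retained sequence), summing counts per sample.
Deterministic tie-breaks: among identical sequences the lexicographically
smallest ASV id is the representative; a sequence contained in several
non-nested representatives joins the longest, then lexicographic.  Matching
is forward-strand and case-insensitive — all emulated studies target the
same amplicon — with an opt-in reverse-complement flag.  Merging is
idempotent and conserves per-sample totals.

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a fixed depth, default 1000 reads; samples below depth
are dropped, as are ASV columns left all-zero.  Merging runs before
rarefaction; the run report records both stages' dimensions.

## Exposure sensitivity

For each study and each core clade, clade abundance is regressed on the
sample's exposure condition with a log-link negative-binomial model
(NB2; maximum likelihood for coefficients and dispersion jointly, the
`glm.nb` contract — statsmodels' ML optimiser is used rather than a bespoke
IRLS loop).  The control arm is the base level, so each non-control
coefficient is the log fold change in expected clade abundance versus
control; Wald p-values are BH-corrected within study across all clade ×
exposure-level tests (configurable to a global family), and `q < 0.1`
(default) flags the clade as sensitive to that exposure.  Because inputs
are rarefied (equal totals), no offset term is used; a log-total offset is
available for raw counts.  All-zero responses and responses >95% zero are
not fitted (`degenerate` / `insufficient_signal`); non-convergence is
flagged and the p-value withheld.

Since samples are rarefied to a fixed total, a genuine increase in one
clade necessarily depresses the remaining clades (compositional closure),
and ancestors of an affected clade shift with their descendants.  Sensitive
calls beyond the directly planted clades are therefore expected on synthetic
data; calibration is assessed on null arms — exposure levels with no true
effect — where every call is false by construction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
providing planted ground truth for every stage:

- **Tree**: random sequential pairwise joins (uniform over partners) with
  exponential(1) branch lengths — exchangeable topologies, strictly
  positive branch lengths.  The real analysis would consume an inferred
  phylogeny; topological realism beyond exchangeability is not attempted.
- **Design**: `n_studies` studies (study-scale default 8) of unequal sizes,
  each with one `control` arm plus that study's exposure arms, samples split
  evenly.  Facility and age columns are carried as plumbing.
- **Occupancy**: each tip is present in a sample independently with
  probability `core_occupancy` (default 0.9) for members of planted core
  clades and `background_occupancy` (default 0.05) otherwise.  Planted
  cores are disjoint internal clades of 2–10 tips, mimicking recently
  diverged clades.
- **Counts**: a tip's base relative abundance is log-normal
  (`abundance_logmean = 0`, `abundance_logsd = 1`), fixed per tip;
  within a sample, present tips' abundances are normalised and scaled to
  `depth_mean` (default 5000 reads) and realised counts are
  gamma-mixed Poisson, i.e. negative binomial with size `nb_dispersion`
  (default 2) — sparse, over-dispersed counts.
- **Exposures**: each arm multiplies the affected clades' member-tip
  expected counts by `exp(log_fold_change)` after normalisation, a clean
  multiplicative shift on clade abundance.  The study-scale configuration
  plants nine arms with two- to four-fold effects in both directions, one
  of which ("ethanol") carries no effect and serves as the built-in null
  arm.

What the generator does **not** emulate: phylogenetic autocorrelation of
abundances, study-specific community composition, age-driven prevalence
structure, chimeras, or taxonomy.  Passing tests therefore demonstrate that
the statistical machinery is correct under its stated assumptions, not that
those assumptions hold in any particular real collection.

Truth-based scoring matches planted clades to analysis-tree clades by tip
set (ids are renumbered when tips are pruned).  Core-call FDP counts only
called clades containing *no* planted-core tip as false, since ancestors of
a planted clade genuinely exceed the null.

## Numerical and design choices

- Clade ids `node1..nodeK` by deterministic postorder; stable across newick
  round-trips.  `min_tips = 2`: a single tip is not a clade for this test.
- Midpoint rooting is implemented by double-sweep diameter search plus
  rerooting on the midpoint edge; the midpoint of a tree metric is unique,
  so the operation is idempotent, and it conserves total branch length to
  1e−9.  (The wrapped tree library's own midpoint rooting was not
  idempotent on trees whose midpoint falls at the current root.)
- Within-clade divergence = arithmetic mean of all unordered pairwise
  tip-to-tip path lengths, computed in one postorder pass.
- Top-quartile selection uses linear-interpolation (type-7) percentiles;
  ties at the threshold are included.
- Prevalence-profile clustering: average-linkage hierarchical clustering on
  Euclidean distance, plus k-means (k = 3 by default, fixed seed); both
  labelings are reported.
- All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds from one root generator and logs them, so every table is
  reproducible bit-for-bit.
- Tips present in the tree but absent from the table are pruned with a
  warning (mirrors guide-sequence removal); table ASVs missing from the
  tree are a hard error by default.

## Problem sizes used in the checks

Recovery and calibration analyses run at 100–2000 tips, 100–300 samples,
and 999 permutations (5000 where Monte-Carlo moments are compared to
exhaustive enumeration on 5-tip trees); negative-binomial recovery uses 50
replicates at 100 samples per arm.  These sizes were chosen so each check
exercises the regime in which its oracle is exact or its expected behaviour
is derivable.

## Known limitations

- The permutation null randomises labels only; it does not condition on
  per-sample richness or abundance structure beyond what the fixed count
  table provides.
- The normal-approximation z-test is kept as the primary test; for very
  small sample counts the exact permutation-rank p-value is the safer
  diagnostic.
- NB fits on arms with very few samples (<5 per level) are fragile;
  records carry a status field rather than silently dropping.
- Compositional closure after rarefaction means exposure coefficients mix
  direct effects with spillover; interpreting individual betas causally
  requires external information.
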