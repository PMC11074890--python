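# Methods

This note documents the statistical model, the numerical choices and the
open design decisions behind `reasonnet`, in the spirit of the methods
documentation that accompanies packages like statsmodels or msprime. It
describes what the code computes; every number quoted here is produced by
the test suite or `scripts/acceptance.py` at run time.

## Participant-normalized co-mention weighting

The central quantity is a symmetric nonnegative reason-by-reason matrix
A built from respondents' deduplicated reason sets. Each respondent
contributes total weight exactly 1:

- one reason mentioned → weight 1 on that reason alone;
- two reasons → the unique pair receives weight 1;
- k ≥ 3 reasons → each of the C(k, 2) unordered pairs receives 1/C(k, 2)
  (three reasons → 1/3 per pair).

This normalization prevents verbose respondents from dominating the network:
whether someone names one reason or five, they add the same mass. Per-pair
weights are stored once, symmetrically (A[i,j] = A[j,i] = the pair weight,
not half each), so the conservation identity is

    sum over upper triangle of A + diagonal mass = number of respondents.

Accumulation uses exact rational arithmetic (`fractions.Fraction`) per
respondent and converts to floats only when the matrix is finalized, so
conservation holds to floating-point rounding (the randomized suite checks
|error| < 1e-9 over 1000 generated data sets; observed errors are ~1e-14).

**Sole mentions and the diagonal.** Whether the weight-1 "sole mention"
enters the adjacency matrix is genuinely ambiguous in this analysis
tradition: it clearly drives node *size* in the standard figures, but a
self-loop also feeds the spectral ranking (a frequently-sole-mentioned
reason gains centrality even with few co-mentions). The default,
`diagonal_mode="self_weight"`, places sole-mention weight on the diagonal,
consistent with reading the centrality as reflecting "how frequently the
node occurred" as well as its links; `diagonal_mode="zero"` keeps the
diagonal empty (sole mentions tracked in a side vector only) for
sensitivity analysis. The CLI exposes both; edge exports are identical in
both modes, centralities differ.

## Eigenvector centrality by power iteration

Reason importance is the leading eigenvector x of A (A x = λ x). The
implementation is power iteration from the uniform positive start vector,
capped at 500 iterations with an L1 convergence tolerance of 1e-10 on the
normalized iterates; λ is the Rayleigh quotient at termination. The start
vector has positive overlap with the Perron vector of any nonnegative A, so
the limit is the nonnegative Perron direction.

Two numerical points:

- **Spectral shift.** The iteration actually multiplies by A + cI with
  c = 0.1 × (largest row sum). This leaves the eigenvectors unchanged but
  makes the Perron eigenvalue strictly dominant in magnitude: on bipartite
  graphs (e.g. a star), λ_min = −λ_max and the unshifted iteration
  oscillates forever between two mixtures. With the shift, the star K(1,4)
  converges to the closed form (center 1/√2, leaves 1/(2√2), λ = 2), and a
  dense-eigendecomposition oracle check over 200 random symmetric
  nonnegative matrices (sizes 2–12) agrees to better than 1e-6 whenever the
  spectral gap exceeds 1e-3·λ1. The shift scales with the matrix, so
  centrality is invariant to rescaling A, and the reported λ is always the
  Rayleigh quotient of the *unshifted* matrix.
- **Degenerate gaps.** When λ1 − λ2 ≤ 1e-3·λ1 (e.g. disconnected components
  of equal strength), no power method can isolate a unique leading
  direction; the result carries a `gap_degenerate` flag, estimated by a
  short deflated iteration. Non-convergence within the iteration cap is
  likewise reported in the diagnostics, never fatal.

**Normalization.** The default output norm is L2 (unit Euclidean length),
the common convention for eigenvector centrality and the one under which
single-reason dominance yields values approaching but below 1; a max-norm
option (`norm="max"`) rescales the peak to 1 instead. Normalized values are
directly comparable across the per-age-bin networks because each stratum's
vector is rescaled to the same norm.

**Ranking.** Ties in centrality break by codebook position (a fixed,
documented order, descending published mention frequency), so rankings are
deterministic; an all-zero vector is ranked but flagged degenerate.

## Codebooks and the extended 5C mapping

The shipped vocabularies contain 10 acceptance and 10 resistance reasons,
each mapped to one or more categories of the 5C vaccine-hesitancy model
(complacency, confidence, convenience, calculation, collective
responsibility) extended with a sixth *context* category covering vaccine
mandates, (no) incentives and medical preference. Reasons appearing in both
groups (vaccine mandates, social norms) carry distinct codes per group
because their semantics differ (motivator vs demotivator). Codes are
snake_case identifiers invented for the package; labels carry the survey
wording. The mapping places medical preference in both *confidence* and
*context*, following the footnote of the source coding table that names it
among the context reasons (the check-mark grid itself marks only
confidence); this is the one cell where the two readings of that table
disagree.

## Synthetic response generator

Respondent-level co-mention data for the motivating study are not public,
so the generator stands in for them, and its defaults are chosen to emulate
that study's conditions:

- sample sizes 5559 (acceptance) and 982 (resistance);
- marginal salience proportional to the published per-reason mention counts
  (3689 : 2354 : … : 15 for acceptance; 501 : … : 6 for resistance);
- uniform pairwise affinity (the published analysis reports no pairwise
  parameters to emulate);
- the number of reasons per respondent drawn from {1: 0.55, 2: 0.30,
  3: 0.15} — sole mentions dominate, consistent with the study's
  description of many reasons as mainly sole-mentioned; the exact
  distribution is this package's documented choice;
- age-bin and demographic marginals matching the published sample
  composition.

Sampling is sequential and conditional: the first reason is drawn with
probability ∝ salience; each further reason j (without replacement) with
probability ∝ salience[j] × affinity[last drawn, j]. This chain rule is
simple, fully seedable, and induces controllable pairwise co-occurrence;
it does *not* reproduce higher-order dependence (triple-wise effects) or
any real-world relationship between demographics and reasons unless an age
profile plants one. One integer seed drives a single `numpy` generator, so
identical configurations serialize byte-identically.

`planted_truth` converts a configuration into its implied dominance
ordering — salience × total off-diagonal affinity — used solely as the
recovery target in tests: with one reason planted at ×5 salience and
affinity at n = 5000, the eigencentrality ranking recovers it first in
≥ 95 of 100 seeds (observed: 100/100); a reason planted only in one age
bin tops only that bin's stratified ranking.

What passing these tests shows is that the *pipeline* recovers structure
the generator plants at realistic sample sizes and skew; it cannot validate
substantive conclusions about real survey populations, whose dependence
structure the generator only caricatures.

## Stratification and group comparison

Age-stratified analysis rebuilds the matrix and recomputes normalized
centrality within each of the six survey age bins (18-24, 25-34, 35-44,
45-54, 55-64, 65+). Respondents with unknown age stay in the pooled network
but join no stratum — the published analysis does not state its handling,
and this rule preserves the pooled sample size while keeping the strata
additive: the entrywise sum of stratum matrices plus the unknown-age matrix
equals the pooled matrix exactly.

Demographic composition of the two outcome groups is compared with the
Pearson chi-square test of homogeneity (via `scipy.stats.chi2_contingency`,
continuity correction disabled — the named test is Pearson's, and a Yates
correction would change 2×2 results). Expected cell counts below 5 trigger
the conventional small-sample warning. Column percentages in the
demographic table use group totals as denominators, which reproduces the
published percentages from the published counts (female 55.8% / 56.1%,
chronic condition 27.8%; the published sex comparison p = .87 is likewise
recovered).

## Figures and reproducibility

Network figures use a force-directed (spring) layout under a fixed seed;
node area tracks sole-mention weight, edge width the co-mention weight, and
labels carry the normalized eigencentrality — matching the conventions of
the figures this analysis style produces. The grouped bar chart shows
centrality per reason per age bin. SVG output pins matplotlib's hash salt
and drops the date metadata, so identical inputs and seeds yield
byte-identical files; the run report (JSON) echoes the full configuration,
seed included, and re-running from that echo reproduces every artifact.

## Problem sizes in the checked runs

The randomized suites run at: 1000 generated data sets (n ≤ 40 each) for
conservation; 200 random matrices for the eigensolver oracle; 100 seeds at
n = 5000 for planted recovery; full published scale (n = 5559 / 982) for
the survey-scale runs. These sizes make the whole suite complete in about
a minute while leaving the sampling-error bounds meaningful.

## Known limitations

- The co-mention network is descriptive: edges encode co-mention, not
  causation or even partial association controlling for other reasons.
- Power iteration reports, but does not resolve, degenerate spectral gaps;
  disconnected networks of comparable mass have no unique ranking.
- The generator's chain sampling reproduces pairwise affinity only
  approximately (conditioning is on the last-drawn reason, not the full
  set) and models no respondent-level heterogeneity beyond age profiles.
- The "other" bucket for out-of-vocabulary codes is a reading convenience;
  analyses including it rank a heterogeneous remainder category alongside
  substantive reasons.
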