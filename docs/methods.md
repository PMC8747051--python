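# Methods

This note records the modelling choices behind `hhnet`: what each
constructed variable means, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical conventions.

## From roster to ego network

A survey roster records, for every household member, only the relationship
to the household *head*. The respondent's ego network is therefore built in
two steps.

**Ego ties.** The respondent is assumed to interact with everyone she lives
with, so her tie to each alter has weight 1 regardless of kinship. Alters
default to the de jure listing (usual residents); a switch restricts to de
facto members (present the night before the interview). Visitors — listed
but not usual residents — are excluded from the network by default while
still contributing to the de jure diversity index below.

**Alter–alter ties.** The kinship between two non-head members is
under-determined by their two head-relative codes, so the package ships an
exhaustive 91-row rule table (`resources/relatedness_rules.csv`) assigning
each unordered code pair a coefficient of relatedness r ∈ {0, 0.125, 0.25,
0.5}. Anchor values are genealogical: head × child/parent/sibling = 0.5,
head × grandchild = 0.25, head × niece/nephew = 0.125, and any pair
involving a non-relative, adopted/foster/step or unspecified member = 0.
In-marrying members are blood-tied only down the line: a spouse to the
couple's children (0.5) and grandchildren (0.25) and to her own parents
(coded parent-in-law, 0.5), never to the head's side. Ambiguous pairs
resolve to a single documented default — two children of the head are
siblings (0.5); a child × grandchild pair is scored as aunt/uncle (0.25)
rather than parent; grandchild × grandchild as siblings (0.5) although they
may be cousins; sibling × niece/nephew as the generic aunt/uncle type
(0.125). "Another relative" is treated as a distant blood relative (0.125
with the head's blood kin, 0 with in-laws). The table is a loadable CSV
precisely so a user with stronger pedigree information can override it.
An optional flag additionally scores married couples (head–spouse,
child–child-in-law, parent pairs) as tied at weight 1; the default is
blood-only, matching the coefficient table.

Weights enter the tie matrix as w = r / 0.5, so a parent–child tie is 1 and
the alphabet of alter–alter weights is {0, 0.25, 0.5, 1}. Alter ties are
undirected: the half-matrix over unordered pairs is computed once and
mirrored.

## Structural variables

All Burt measures use proportional tie strengths
p<sub>ij</sub> = z<sub>ij</sub> / Σ<sub>k</sub> z<sub>ik</sub> on the
weighted network (a switch binarizes ties first).

* **degree** — number of alters.
* **effective size** ES = Σ<sub>j</sub>[1 − Σ<sub>q≠i,j</sub>
  p<sub>iq</sub> m<sub>jq</sub>], with m<sub>jq</sub> alter j's tie to q
  divided by j's strongest tie. Because every alter's tie to the ego is 1,
  ES is bounded in [1, degree]: 1 for a complete kin clique, the degree
  when no alter pair is related. The implementation clamps float noise to
  those analytic bounds. ES is also dichotomized at 3 (the typical cohort
  median; configurable) into low (≤ 3) / high (> 3).
* **constraint** — Burt's aggregate C = Σ<sub>j</sub>(p<sub>ij</sub> +
  Σ<sub>q</sub> p<sub>iq</sub>p<sub>qj</sub>)². Raw C does not span [0, 1]:
  an empty alter graph of n alters gives exactly 1/n, a complete weight-1
  clique gives (2n−1)²/n³ (which exceeds 1 for n ≤ 3). Because the
  variable's published contract is "0 when all alters are unrelated, 1 when
  all are related", the package reports, alongside raw C, the minimal
  per-degree affine rescaling
  C′ = (C − 1/n) / ((2n−1)²/n³ − 1/n), clamped to [0, 1].
  Note the two scales answer different questions: C′ is the contract
  variable used as the model exposure, while raw C is what classical
  ego-network software prints — a typical mostly-kin household of degree
  5–6 sits near raw 0.55 (a degree-6 complete clique is exactly 0.560) and
  the descriptive table therefore reports both columns.
* **density** — mean alter–alter weight over the n(n−1)/2 pairs.
* **efficiency** — ES / degree.
* **hierarchy** — Coleman–Theil concentration of the dyadic constraints
  c<sub>ij</sub>: Σ (c/ĉ)ln(c/ĉ) / (n ln n); 0 when all dyadic constraints
  are equal.

Degree-1 conventions (documented, returned without error): ES = 1,
C′ = 1, hierarchy = 0, density = 0.

Strengthening an alter–alter tie can never increase ES, and the test suite
checks this. Aggregate constraint, although increasing in density in the
typical case, is *not* globally monotone in a single tie weight (row
normalization can dilute other ties more than the new tie adds); only its
endpoint contract is asserted.

**Variable reduction.** The six structural variables are strongly
inter-correlated. `reduce_structural_set` standardizes them,
eigendecomposes the correlation matrix, and per leading component (Kaiser
criterion, eigenvalue > 1 with a 1e-9 numeric tolerance) retains the
variable with the largest absolute loading, ties broken by a fixed
canonical order; constant columns are dropped with a warning, and if no
component leads (identity-like correlation) the conventional
{degree, effective size, constraint} trio is returned. On the calibrated
synthetic cohort two components lead — a redundancy axis (density,
constraint, ES, efficiency, hierarchy) and a size axis (degree) — so the
rule retains {density, degree} there; the pipeline's default exposure set
is nevertheless the conventional trio, which is what analysts of these
surveys model. The reduction is a tool for exploring one's own data, not a
gate in the pipeline.

## Compositional variables

The IQV is the Gibbs–Martin index normalized by the codebook category
count: IQV = K/(K−1) (1 − Σ p<sub>k</sub>²). K is the number of *possible*
categories (2 for sex and education, 12 for kinship by default), not the
number observed — otherwise a one-category household would be undefined —
and this normalization is what makes values comparable across variables
with different K. Equivalently it is the fraction of unordered member
pairs that differ on the attribute, normalized by the fractional
even-split maximum; the test suite checks that identity by exhaustive pair
counting. Values are clamped to [0, 1]. The respondent's own attributes
are excluded from every multiset: the indices describe her network, not
her.

Residence diversity uses two binary IQVs: de jure (usual resident vs
visitor, over everyone listed) and de facto (slept here vs away, over
usual residents). Both are median-split into diversity present/absent
flags, with the weighted median computed per survey round on the analysis
cohort (an override pools rounds). In cohorts where > 50% of households
have IQV 0 the median is 0 and the flag reduces to "any visitor" / "any
member away", which is the intended reading.

Age diversity is the sample SD (ddof = 1) of alter ages in years; a single
alter gives 0, all-missing ages give NaN.

## Outcome coding

The dietary-diversity score counts the 8 recall groups (breast milk;
grains/roots/tubers; legumes/nuts; dairy; flesh foods and eggs;
vitamin-A-rich fruits/vegetables; other fruits/vegetables; other solids);
MDD is met at ≥ 5. Breast milk counts as a group by default; a flag
switches to the 7-group variant (threshold 4) for analyses that treat
breast milk separately. Any missing flag codes the outcome missing rather
than guessing. MMF follows the age- and breastfeeding-specific minima (2 /
3 / 4 with ≥ 1 solid feed); milk feeds count toward the non-breastfed
4-feed minimum because the recall's feed count includes them. Ages outside
6–23 months are a hard error — the indicator is undefined there.

Survey rounds differ in which recall items exist: by default MDD is masked
for the 2000 round and MMF for 2005 (the sources conflict on whether 2000
or 2011 lacked the diversity items; the table footnote listing 2000 is
followed and the mask is configurable). Masked cells propagate to the
association tables as "unavailable" rather than silently vanishing.

Eligibility is last-born children aged 6–23 completed months in households
with an interviewed respondent. The upper bound is configurable; 23 is the
default because the MMF age bands end there. The selection emits a flow
dictionary whose exclusion counts partition the input exactly.

## Statistical models

**Per-round models.** Weight-scaled maximum likelihood logistic regression
(binomial GLM with variance weights; weights normalized to sum to the
analysed n, making weight-2 equivalent to duplication). Standard errors
are sandwich estimates clustered on the primary sampling unit; with fewer
than two clusters the fit falls back to heteroscedasticity-robust errors
and flags it. Exactly one exposure per model, crude and adjusted for the
respondent/household covariates (age, education, residence, coresidence
with husband, head sex, wealth tercile, earnings), because the exposures
are mutually correlated. Listwise deletion with a reported count.
|coefficient| > 12 flags probable separation; the fit is returned flagged,
not discarded.

**Pooled model.** Logistic regression with a Gaussian random intercept on
the survey round, fitted by maximizing the exact marginal likelihood with
adaptive Gauss–Hermite quadrature (default 15 nodes; the integrand is
re-centred at its mode and re-scaled by its curvature per group, computed
by a safeguarded Newton iteration, so accuracy is retained for large
groups where naive quadrature fails). Optimization is L-BFGS-B over
(β, log σ) with log σ bounded in [log 1e-6, log 10]; σ < 1e-3 is flagged
as a boundary fit, in which case the fixed effects coincide with the plain
pooled logistic. Sampling weights enter as normalized pseudo-likelihood
scaling of the observation log-likelihood terms (the weighted and
unweighted pooled fits can both be requested, since survey-weighting
conventions for mixed models differ). Covariances come from the inverse
observed information (numerical Hessian); if the boundary makes the full
Hessian singular the β block is computed at fixed σ and flagged. With only
3–4 rounds the variance component is estimated very noisily and is often
at the boundary; that is a property of the design, reported honestly via
`sigma_u` and its flag.

**Marginal effects.** For a continuous exposure: the average over the
estimation sample of P(y=1 | x<sub>i</sub>, exposure + 1 weighted SD) −
P(y=1 | x<sub>i</sub>), × 100 — a discrete one-SD shift, not a derivative.
For categorical exposures: the average difference between each level and
the reference. Predictions from the pooled model set the random intercept
to its mean of zero. Confidence intervals are delta-method, propagating
the coefficient covariance through the averaged prediction gradient.

## Synthetic generator

The generator's defaults are the study conditions the pipeline is tested
under, chosen once:

* four rounds with sample shares 0.30 / 0.13 / 0.28 / 0.29 mirroring the
  published per-round ns; 20% urban;
* archetype mix per residence (rural: 42% nuclear, 40% three-generation
  extended, 18% with non-relatives; urban: 68 / 12 / 20), with nuclear
  households frequently carrying an attached relative — strictly nuclear
  rosters are a minority, as in real rosters;
* one eligible last-born child aged 6–23 months per household (the
  analysis uses last-born children only, so multi-eligible households add
  only linkage complexity);
* visitors at rate 0.11, usual residents away at 0.14 (matching the
  ~10–15% diversity-present shares); 15% female-headed households;
* log-normal weights (σ = 0.4) normalized to mean 1; clusters assigned in
  blocks of 25 households so clustered standard errors are exercised;
* outcomes drawn from a logistic model on standardized exposures with
  per-round intercepts set to the published prevalences (MDD ≈ 4–12%, MMF
  ≈ 43–50%), modest default coefficients (MDD: degree 0.05, constraint
  0.10, age SD 0.15 per SD; MMF: degree −0.15, constraint 0.30), and a
  round random intercept of SD 0.3.

Recall records are back-filled to be exactly consistent with the drawn
indicators (a met MDD gets a random 5–8-group subset, breast-milk flag
tied to breastfeeding status; feed counts drawn inside the met/unmet band
for the child's age and breastfeeding status), so re-coding them recovers
the drawn outcomes with zero mismatches — the pipeline's global round-trip
check.

Under these defaults the cohort reproduces the typical published network:
median degree 5 and raw Burt constraint median ≈ 0.55 with quartiles
inside (0.44, 0.65). Known departures from real data: the age SD of
three-generation households sits at the upper edge of the published
typical range (median ≈ 17 vs ≈ 13–17), because the archetypes span full
generation gaps; the correlation structure among the six structural
metrics is tighter than in real rosters (see the PCA note above); and the
two-stage sampling frame, regional strata and wealth-index construction
are not emulated — weights and clusters are structurally plausible, not
design-faithful. Passing tests therefore demonstrate correctness of the
constructed variables, coders and estimators under realistic marginals,
not population fidelity of any specific covariance.

## Numerical conventions and limitations

* Tie weights, IQVs and rescaled constraint are clamped to their analytic
  ranges to absorb float noise; CSV IO writes floats with `%.17g` and
  parses with correctly-rounded round-trip precision so write→read is
  bit-exact.
* Unknown relationship codes are kept as `unspecified` (counted, warned),
  which scores 0 relatedness — a conservative choice that can only
  understate constraint.
* The quadrature model supports a single random-intercept level (the
  survey round); nested cluster-level random effects are out of scope —
  cluster correlation is handled by the sandwich in the per-round models.
* No multiple-testing correction is applied across the exposure-by-outcome
  grid; the tables report per-model Wald inference with significance
  stars at 0.05 / 0.01 / 0.001.
* Polygynous households and pedigree reconstruction beyond pairwise code
  lookup are not attempted; the rule table is the contract.
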