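# Methods

This note documents the models, parameters and design choices behind
`famrisk`, and what the synthetic generators do and do not emulate.

## Pedigree model

The assessment covers twelve blood-relative roles: mother, father, the
four grandparents, aunts/uncles and their children on each parental side,
and the proband's siblings and children. Spouses and in-laws are excluded
— only blood relatives contribute to familial risk. Two derived, total
classifications drive everything downstream:

* **Family side.** Mother's side = mother, maternal grandparents,
  maternal aunts/uncles and their children; father's side symmetric;
  "your side" = the proband's siblings and children. The three sides
  partition the twelve roles.
* **Degree class.** Mother, father, siblings and children are first-degree
  relatives (FDR); the remaining eight roles are treated as second-degree
  (SDR) for this assessment. Aunts'/uncles' children are genealogically
  the proband's first cousins (third-degree); they are kept in the SDR
  bucket because the intake asks about them alongside their parents, and
  the grouping — not genealogical exactness — is what the rules consume.
  The role names say what they are (`*_aunt_uncle_child`); intake
  interfaces may label them "nieces and nephews" as lay questionnaires do.

Validation is non-destructive and returns violations as data: duplicate
unique roles, duplicate `(role, member_index)` pairs, group pools over the
cap (default 7 per pool), a diagnosis age on an unaffected relative, ages
outside (0, 120], and history flags on an unaffected relative.

Pedigrees serialise to a versioned JSON document (draft-07 schema in
`src/famrisk/schema/`) and to a PED-inspired tab-separated table
(`role member_index affected age_dx multiple_polyps other_cancers
multiple_crc`, booleans 0/1, unknown age `.`, UTF-8, LF). Both formats
round-trip exactly; general pedigree graphs (half-siblings, consanguinity,
genotypes) are out of scope.

## Lifetime-risk rule engine

The engine assigns one of four strictly ordered categories — average,
slightly increased, moderately increased, potentially high — as the
maximum over six rules (R1, R2a/R2b, R3a/R3b/R3c; see the module
docstring for the table). The published guideline's exact boundary wording
is not in the public domain in machine-readable form, so the default
`RuleTable` is a reconstruction of the standard familial-CRC criteria and
is deliberately fully config-overridable; deployments should review the
defaults against the current local guideline.

Parameters (defaults): primary age cutoff 55 y, high-risk cutoff 50 y,
Amsterdam-style cluster minimum 3 relatives over ≥ 2 generations, small
cluster minimum 2 relatives. Age comparisons are strict `<` ("diagnosed
before age X"), matching "under 55"-style phrasing.

Documented edge decisions:

* **Unknown diagnosis age** counts as *not* early-onset. A single affected
  FDR with unknown age therefore lands in *slightly increased* (R1), not
  average; an unknown age never satisfies an early-onset predicate. This
  keeps category rank monotone in added relatives.
* **"Your side" counts toward both parental sides** for same-side
  clustering: the proband's siblings and children are blood relatives of
  both lineages, so a sibling plus a maternal aunt can form a mother-side
  cluster. This prevents false downgrades and is asserted by the oracle
  suite.
* A cluster rule satisfied on both sides is reported once, with the union
  of matching relatives; the trace is sorted by rule id, so assessments
  are byte-deterministic.
* The proband's own history (IBD, prior polyps) is carried as free text in
  `proband_note` and deliberately excluded from scoring.

Correctness is established structurally rather than against published
case-level outputs: an independent brute-force evaluator (naive re-check
of every predicate, no shared code, its own role tables) agrees with the
engine on 10,000 random pedigrees, an exhaustive sweep over all pedigrees
of up to two relatives from the role × age × flag grid reaches exactly the
four categories, and category rank is monotone under adding an affected
relative.

## Intake modes

The sequential questionnaire's base traversal is 6 named screening pages +
4 group-count pages + 1 confirm page = 11 pages; each affirmative
screening answer inserts one detail page and a group count of *k* inserts
*k* detail pages, giving the 45-page maximum at the cap of 7 per pool
(11 + 6 + 4×7). This calibration — pooling each side's aunts/uncles with
their children on one count page (the relationship is asked on the detail
page) and a cap of 7 — is the unique simple page inventory reproducing
both bounds; introduction/instruction pages are not counted because only
pages that collect answers are of interest. Restarting from the confirm
page clears the answers but keeps counting presented pages, reproducing
the behaviour of a user who starts over.

The diagram intake takes the same information as one form (ten blocks: six
named relatives, four group lists) with confirm-guarded reset semantics.
Both modes produce identical pedigrees, and `render_summary` is
byte-identical across modes — the package's testable counterpart of
"different steps, identical summary pages". No HTML rendering, sessions
or timing instrumentation are included.

## Usability statistics

The pipeline mirrors a standard two-group usability analysis, all tests
two-sided at α = 0.05:

* **Efficiency.** Per-group mean/SD of task time; Shapiro–Wilk per group
  (applied below n = 50, the small-sample regime the test is meant for);
  pooled-variance t-test (Welch by flag); the Mann–Whitney U test is
  *selected* exactly when any group's normality check rejects. Both test
  results are always reported so the gate's effect is auditable.
* **Satisfaction.** The 17 CSUQ-style items are answered on a 1–7 scale
  (1 = strongly agree). Negatively worded items are recoded x → 8 − x; the
  default instrument marks none as negative, and the set is configurable.
  Totals on the recoded scale span 17–119 (17 items × a 1–7 scale; a
  ceiling of 136 would require an 8-point scale and is arithmetically
  inconsistent with the stated anchors). Item-level missingness is tested
  with **Little's MCAR test**: pattern-grouped EM estimates the
  multivariate-normal mean μ̂ and ML covariance Σ̂, and
  d² = Σⱼ nⱼ (ȳ₍obs,j₎ − μ̂ⱼ)ᵀ Σ̂ⱼ⁻¹ (ȳ₍obs,j₎ − μ̂ⱼ) is referred to
  χ² with df = Σⱼ pⱼ − p. On complete data the test is reported as not
  applicable. A **single deterministic imputation** fills each missing
  cell with its EM conditional mean — reproducible without a seed, unlike
  stochastic regression imputation; it slightly understates item variance,
  acceptable for a single completed dataset feeding sums and reliability.
  If the MCAR test rejects, the pipeline still imputes but flags
  `imputation_justified=False`. **Cronbach's alpha** uses the standard
  k/(k−1) · (1 − Σ item variances / total variance) form with n−1
  variances. The group comparison of totals then reuses the gated
  procedure.
* **Mann–Whitney.** Exact enumeration over all C(n₁+n₂, n₁) group
  assignments (correct under ties) when both groups have ≤ 8
  observations; tie-corrected normal approximation otherwise. The exact
  branch is cross-checked against an independent exact implementation for
  all group sizes ≤ 6.

EM numerical choices: covariance initialised from mean-filled data plus a
1e-6 ridge, convergence at max-abs change < 1e-8 (≤ 500 iterations),
singular pattern blocks reported with the offending pattern. The EM/d²
path is verified against the closed-form factored-likelihood ML solution
for bivariate monotone missingness, and the test's null rejection rate is
calibrated by simulation to the nominal α within binomial error.

## Synthetic generators

`gen_pedigree` draws, per unique role, an affection Bernoulli; per group
pool, a pool size on 0..7 and per-member role and affection draws — only
affected members enter the pedigree, matching intake semantics (the tool
never records unaffected group members). Ages at diagnosis are normal
(mean 62, SD 13 — a realistic CRC onset distribution) truncated to
[25, 95] and rounded; the age is recorded with probability 0.9; flag
probabilities default to 0.04/0.06/0.03 (polyps / other related cancers /
multiple primary CRC).

`gen_study` emulates the usability-study table. Defaults are the study
conditions: 90 participants, 45 per interface group assigned by a seeded
shuffle of a prepared label pool; age-band counts (8, 9, 9, 29, 21, 9, 5);
41 male; web-use counts (11, 2, 7, 70) — kept as printed even though they
imply 78 % weekly users rather than a rounder figure; task times gaussian
with (89.2, 7.05) and (80.89, 5.19) s per group — taken as SDs as printed,
though their size relative to skewed task-time data suggests they could be
standard errors; satisfaction totals targeting (101.12, 11.9) and
(108.79, 9.08); exactly 21 participants receive 1–3 missing items,
injected completely at random. Non-default `n_total` scales every count by
largest remainder from these proportions.

Satisfaction items come from a one-factor model: for k = 17 parallel items
with loading λ and noise σₑ, the inter-item correlation
r = λ²/(λ²+σₑ²) is set from the target reliability α = kr/(1+(k−1)r)
(target 0.9) and the latent item variance from the target total SD. The
latent item mean is then calibrated by root-finding so that the
*discretised* responses (rounded, clipped to 1..7) reproduce the target
total mean in expectation — so group means are unbiased by construction,
while clipping at the 7-point ceiling shrinks the realised total SD below
its target (an exact-SD promise is deliberately not made; reliability
lands near, not exactly at, 0.9). An optional skew-normal latent factor
(`satisfaction_skew`, default off) is available since the real totals were
described as skewed.

What the generators do **not** emulate: free-text comments, experimenter
observations, learning effects within the task, non-gaussian task-time
shapes, and any dependence of missingness on the data (missingness is MCAR
by construction — so a passing MCAR test here validates the test's
calibration, not the missingness mechanism of any real study). Passing
pipeline tests therefore demonstrate correct computation under known
conditions, not robustness to real-world response behaviour.

## Problem sizes in the test suite

The oracle-equivalence suite uses 10,000 random pedigrees; the category
sweep enumerates all ≤ 2-relative pedigrees over the 12 × 3 × 8 variant
grid (~41k assessments); MCAR calibration uses 400 replicates at n = 120,
p = 4; the null type-I-error check uses 1,000 replicates at n = 45 per
group; generator-moment convergence is checked at 4,500 participants.
These sizes give stable Monte-Carlo estimates while keeping the default
suite fast.

## Known limitations

* The default rule table is a reconstruction, not a transcription, of the
  guideline; boundary cases (e.g. whether two affected same-side SDR alone
  reach "moderately increased" — here they do only with an early-onset or
  Lynch-spectrum signal) must be reviewed before clinical use.
* No quantitative risk percentages or penetrance/mutation-probability
  models; the output is a category and a recommendation.
* Little's test and the EM imputation assume multivariate normality of
  the (discrete, bounded) Likert items — the usual pragmatic approximation
  for such data.
* The exact Mann–Whitney branch is limited to groups of ≤ 8 by its
  combinatorial cost.
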