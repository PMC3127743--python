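# Methods

## The algorithm

MAPLe-AC (Method for Assigning Priority Levels — Acute Care) classifies an
older acute-care patient into one of five ordered priority levels — low,
mild, moderate, high, very high — at each of three episode time points:
pre-morbid status (the 30 days before admission), admission status (the 24
hours before admission), and status on day 7 or 24 hours before discharge,
whichever comes first. It is the acute-care crosswalk of the home-care
MAPLe algorithm: of the 44 home-care items, 31 have direct acute-care
counterparts, and the package's codebook enumerates exactly those 31.
Several home-care co-classifiers (inadequate meals with swallowing problems
and falls, wandering with institutional risk, environment problems with
medication management, stasis ulcers with pressure ulcers) have no
acute-care counterpart and are structurally absent — they are not
defaulted, they simply do not exist in the classifier vector.

The tree's input is a classifier vector computed per time point:

- **ADL hierarchy** (0–6): functional dependence from the four late-loss
  activities of daily living — personal hygiene, toilet use, locomotion,
  eating — each coded 0 (independent) to 6 (total dependence), with 8 =
  "activity did not occur". Scoring recodes each item into five bands and
  applies the published hierarchy: total dependence in all four → 6; total
  dependence in eating and locomotion → 5; extensive assistance in eating
  or locomotion → 4; in hygiene or toilet use → 3; otherwise the worst
  band (2, 1, 0). The "did not occur" code counts as total dependence by
  the usual interRAI convention; the mapping is an explicit, overridable
  parameter.
- **CPS** (Cognitive Performance Scale, 0–6): comatose dominates (6);
  severely impaired daily decision making scores 5, or 6 with total
  dependence in eating; otherwise the impairment count (short-term memory
  problem, any decision-making impairment, any problem making self
  understood) refined by the severe-impairment count.
- **Behavior disturbance**: any of verbally abusive, physically abusive,
  socially inappropriate behavior, resists care.
- **Clinical flags**: decline in decision making, medication-management
  problem, pressure ulcer, recent fall, meal-preparation problem,
  swallowing difficulty.
- **Institutional (nursing-home) risk**: a count over exactly 8
  categories — prior nursing home placement; homebound (does not go out);
  bladder incontinence; a risk diagnosis (any dementia, Alzheimer's,
  multiple sclerosis, head trauma); ADL decline relative to pre-morbid
  status; hygiene/bathing problem; delirium indicator; meals-and-shopping
  problem. The flag activates at **≥ 3** categories (the home-care version
  activates at ≥ 4). At the pre-morbid point the ADL-decline category is
  false by definition: no earlier baseline exists, and the pre-morbid
  level must still be well defined.
- **Geriatric screener**: a count of screener findings (five
  IADL-capacity flags plus the short-term-memory flag). The home-care
  screener's stamina item has no acute-care counterpart and contributes
  nothing by construction.

The tree itself is **data, not code**: an ordered list of
(condition, level) rules evaluated first-match-wins with a default level,
loaded from YAML and validated at load time (unknown fields or malformed
expressions fail at load, never at scoring). The published schematic of
the branch structure is not printed as text, so the shipped
`tree_default.yaml` is a *reference encoding* exercising every classifier:
LOW when nothing fires; MILD for isolated screener or meal-preparation
findings; MODERATE for falls, swallowing difficulty, medication problems,
decision decline, or mild ADL/CPS impairment (1–2); HIGH for ADL ≥ 3,
CPS ≥ 3, behavior disturbance, pressure ulcer, or active institutional
risk alone; VERY_HIGH for active institutional risk combined with severe
ADL/CPS impairment (≥ 4) or behavior disturbance. Its version string
(`mapleac-tree-0.1-reference`) travels in all output provenance so scored
data are never separated from the encoding that produced them. The
encoding is totally ordered, total, deterministic and monotone (raising
any single vector component never lowers the level); all three properties
are verified exhaustively over the full discrete vector grid
(7 × 7 × 2⁷ × 9 × 7 = 395,136 vectors) in the acceptance suite.

### Missing-data policy

Two tiers. Scale-critical items (the four ADLs, the four cognition items)
must be present: if one is missing the scale raises a non-computable
signal that names the blocking classifier, and the episode drops out of
any model needing that time point — mirroring the varying denominators of
the original analyses. Boolean clinical/risk flags default to "not
present" with a logged warning, as an unchecked box does on the paper
form. One asymmetry: a missing "goes out" item leaves the homebound risk
category *unscored* (false) rather than firing it, since "not present"
for that item would otherwise assert homebound status from silence.

## The synthetic generator

No study data are deposited, so every downstream stage is exercised on
synthetic cohorts whose defaults are the published study conditions:

- **Marginals** (Nordic profile, n = 763; Canadian profile, n = 393):
  sex, age band (75–79 / 80–84 / 85–89 / 90+), living alone, prior
  90-day hospitalization, reason for hospitalization (new problem /
  exacerbation / both), and the per-timepoint five-level priority
  distributions are stored as the published counts and normalized at load.
- **Item patterns** are *inverse-constructed*: for each drawn level the
  generator builds an item pattern the active tree maps back to exactly
  that level, then re-scores it (closed loop; a mismatch is a hard error,
  verified at 0 mismatches over 5,000 draws per suite run). Construction
  at admission/day-7 accounts for the ADL-decline category relative to the
  constructed pre-morbid assessment.
- **Binary outcomes** are drawn from logistic models whose coefficients
  are the published multivariate odds ratios; intercepts are not published
  and are solved numerically (Brent root finding on the expectation over
  the enumerable covariate joint) so the marginal rate matches the
  published one (82.0% discharged home, Nordic). Odds ratios are
  intercept-invariant, so recovery targets are unaffected by this choice.
- **Survival** is exponential proportional hazards with the published
  hazard ratios as generating coefficients; the baseline rate is solved so
  the one-year death probability matches the published 26.5% (Nordic),
  censored at day 365. Times are rounded up to whole days, which
  guarantees ties — hence Efron's tie correction downstream.
- Covariates and per-timepoint levels are drawn **independently** from
  their marginals: no joint distribution is published, and independence is
  the simplest structure consistent with every printed calibration number.
- Diagnosis-group prevalences (neoplasms 15%, mental/behavioral 10%,
  respiratory 20%) are package defaults — the source reports their hazard
  ratios but not their frequencies; the values chosen are plausible for an
  internal-medicine population aged 75+ and only scale the baseline-rate
  solution.
- Randomness is a single numpy PCG64 generator (`default_rng(seed)`); the
  seed and tree version are recorded in cohort provenance, and a fixed
  seed reproduces a byte-identical cohort CSV.

What the generator does **not** emulate: within-hospital clustering,
country effects beyond the two profiles, correlation between levels at
successive time points, time-varying covariates, or any realistic joint
structure between demographics and impairment. Passing tests therefore
demonstrate algorithmic and statistical correctness of the machinery, not
clinical performance on real episodes.

## The validation battery

Binary endpoints are configurable dispositions over the outcome
categories. The defaults follow the published denominators: for
"discharged home", home vs institution + death + other (626 vs 137); for
"adverse outcome", institution + death vs home + other (123 vs 640). The
"other" category is negative on both sides; the endpoint objects expose
the disposition so alternative readings are one config edit away.

Logistic fits are maximum likelihood (statsmodels), dummy-coded with the
published reference categories: man, age 75–79, new problem, and the
endpoint's MAPLe reference — very high priority for the home endpoints,
low priority for the adverse endpoints and the Cox model. Reference
categories are reported as estimate 1.00 with no interval. Intervals are
95% Wald on the log scale. Both pseudo-R² variants are reported: Cox–Snell
(headline, matching the default R-square of the SAS logistic procedure
used in the original analyses) and max-rescaled (Nagelkerke). The
c-statistic is the trapezoidal AUC of the fitted probabilities, which
equals the Mann–Whitney concordance probability with ties counted ½ — an
identity the suite checks against an O(n²) all-pairs oracle to 10⁻¹².

The Cox model for days to death uses statsmodels PHReg with Efron's tie
correction (switchable to Breslow) and adds three diagnosis-group flags
(neoplasms; mental and behavioral; respiratory) as covariates. Complete or
quasi-complete separation in either model raises an explicit error naming
the offending covariate rather than returning divergent estimates.
Cross-checks: the Cox fit is compared term-by-term against an independent
lifelines fit in the test suite; the CPS and ADL-hierarchy scales are each
compared exhaustively against decision-table transcriptions of the
published grids, kept deliberately separate from the procedural code.

## Parameter-recovery experiments and problem sizes

The headline recovery quantities regenerate cohorts of n = 20,000 and
refit the generating model, reporting the recovered effect for the
sparsest published contrast (LOW vs VERY_HIGH for discharge home, 12.20;
VERY_HIGH vs LOW for the day-7 adverse outcome, 51.71; VERY_HIGH vs LOW
hazard ratio for death, 3.70). A single n = 20,000 replicate carries
substantial Monte Carlo error in these contrasts — sd(log) ≈ 0.08 for the
discharge-home OR and ≈ 0.17 for the adverse OR, because the reference
cells contain only a few dozen discordant outcomes. The reported value is
therefore the mean ML estimate over a small number of independent
replicate cohorts (10, 12 and 3 respectively), each of exactly the stated
size; replicate counts were fixed from the measured sampling sd so the
Monte Carlo error of the mean is well inside the comparison bands, and the
per-replicate estimates are kept in the result object. Calibration of the
generator (pre-morbid LOW share, 39.4%) uses a single n = 100,000 cohort,
where the multinomial sd is ~0.15 points.

The confidence-interval coverage property is tested at reduced scale — 40
logistic replicates at n = 3,000, requiring the generating OR inside the
recovered 95% CI in ≥ 32/40 — a bound whose violation probability under
nominal coverage is about 10⁻³.

## Numerical choices and degenerate inputs

- Rule conditions are parsed with a whitelisted AST (names, integer
  constants, comparisons, and/or/not) and compiled once per spec; an
  unknown field name or any other construct is a load-time error.
- Intercept and baseline-rate solving use Brent's method on exact
  expectations over the discrete covariate joint (120 cells for the
  logistic models, 960 with diagnosis flags for survival), tolerance
  10⁻¹²–10⁻¹⁵.
- Marginal probability vectors must sum to 1 within 10⁻⁹ at parameter
  construction.
- Degenerate model inputs fail loudly: single-class endpoints, cohorts
  with no death events, zero expected cells in contingency tables, and
  all-missing assessments are errors, not silent defaults.
- Tie-breaking in the tree cannot arise: first-match-wins over an ordered
  rule list is a total order.

## Known limitations

- The default tree is a reference encoding, not a transcription of the
  unpublished branch diagram; anyone holding the original encoding can
  reconcile it by editing one YAML file and re-running the exhaustive
  property suite.
- The screener item set (five IADL flags + memory) is one defensible
  reading of an under-documented subscale and is isolated behind a single
  function.
- The generator's independence assumptions make its cohorts unsuitable
  for studying joint-distribution phenomena (e.g., confounding structure
  between age and impairment).
- Only one admission per patient is modelled; there is no episode linkage,
  no competing-risks analysis, and no multilevel/hospital clustering.
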