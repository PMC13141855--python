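# Methods

`eadiff` quantifies how well individual clinical features discriminate
episodic ataxia type 1 (EA1, pathogenic *KCNA1* variants) from type 2
(EA2, pathogenic *CACNA1A*), and turns the best discriminators into a
sequential bedside rule set for settings where genetic testing is
unavailable. This note records the models, conventions and design choices
behind each stage, and what the shipped synthetic data can and cannot show.

## Data model and missingness

Every phenotype feature is tri-state: present, absent, or unknown. Unknown
removes the subject from that feature's denominator (complete-case
analysis); it is never coerced to absent. This mirrors the reality of
literature-curated cohorts, where case reports mention only a subset of
signs. The uniqueness key is `(source_ref, subject_id)` so cohorts merged
from several publications cannot collide. A record may lack a diagnosis —
the classifier's target use case is genotype-unknown patients — but all
diagnostic-accuracy computations reject unlabeled cases.

## Feature engineering

Reported attack durations and frequencies are first range-collapsed (a
range keeps its largest value, a mean-only report keeps the mean), then
binned:

* duration: brief <= 10 min < intermediate <= 60 min < prolonged < 1 day
  <= protracted;
* frequency (attacks per month): daily >= 30 > weekly >= 30/7 > monthly
  >= 1 > rare/sporadic.

The 30-day-month / 7-day-week convention makes frequency binning
deterministic; the boundary inequalities are closed on the side stated
above (10 and 60 min belong to the lower category, 1440 min to
protracted). Two derived binary columns, `brief_attacks` and
`daily_attacks`, mark the extreme categories.

Free-text triggers map case-insensitively through an editable YAML synonym
dictionary onto a three-way taxonomy — kinesigenic (movement-initiation),
exercise-induced, and non-kinesigenic with thirteen subtypes (alcohol,
tobacco, sleep deprivation, physiological stress = fever/illness/infection,
fatigue, fasting, caffeine, startle, heat, anxiety, menstruation,
excitement, other). Unmatched labels fall back to non-kinesigenic/other
with a warning. Exercise-induced is kept as its own category and counts
toward neither the kinesigenic nor the non-kinesigenic column.

The composite `peripheral_muscular_interictal` column is present when any
of clinical myokymia, neuromyotonia, EMG myokymia or another stated
peripheral muscular sign is present, unknown only when all components are
unknown, absent otherwise. The any-of reading is the only one consistent
with the composite's sensitivity (82.5%) exceeding every component's.

## Variant grouping

Only pathogenic / likely-pathogenic variants (ACMG five-tier) are
diagnostic; repeat expansions (the SCA6 mechanism) are excluded outright.
Functional grouping: truncating variants (nonsense, frameshift,
out-of-frame deletion, or splice curated as producing a premature stop)
with NMD predicted are LoF-haploinsufficient; variants with a
decreased-function study or a dominant-negative flag are LoF
non-haploinsufficient (the flag is retained); increased-function studies
give GoF; everything else that yields a translated product is "unknown".
NMD prediction is a curator-supplied input flag, not computed — deriving it
would need transcript coordinates that are out of scope — and splice
variants without the flag stay "unknown". An increased-function study on an
NMD-predicted truncation or a dominant-negative variant is rejected as
contradictory evidence.

## Statistics

* Sensitivity, specificity and accuracy come from the 2x2 table of
  diagnosis x feature on complete cases.
* A single binary feature's ROC has one interior operating point, so
  AUC = (sensitivity + specificity)/2 exactly; ordinal features get one
  cumulative-threshold point per level and a trapezoidal AUC. The
  orientation (`lower_favors_target`) states which end of the ordering the
  target group concentrates on.
* AUC confidence intervals use the Hanley–McNeil standard error with a
  normal quantile, clipped to [0, 1]. The source tables' CI method is not
  stated (SPSS defaults to a nonparametric SE), so exact CI agreement is
  not expected — containment and comparable width are.
* Group association: Pearson chi-square without continuity correction,
  switching to the two-sided Fisher exact test when any expected cell is
  below 5 or any observed cell is zero (where the chi-square approximation
  degenerates). The published tables' chi-square/Fisher labels do not
  follow any single reconstructible rule, so only the p-values themselves
  are treated as anchored.
* Continuous comparisons: Shapiro–Wilk at alpha 0.05 per group gates a
  Welch t-test (both normal) versus Mann–Whitney U. The Mann–Whitney
  implementation is exact on small tie-free samples and uses the normal
  approximation with tie correction otherwise; the exact branch is verified
  in the tests against exhaustive permutation enumeration, and the Fisher
  branch against hypergeometric tail enumeration.
* Reports round percentages half-up to one decimal and AUCs to three
  decimals.

Two conventions resolve internal inconsistencies in the published
fractions: the kinesigenic EA2 denominator is 114 (the trigger-evaluable
N = 193 minus 79 EA1 subjects; 6/114 reproduces both the printed 5.3% and
the 94.7% specificity), and the startle EA1 numerator is 38/77 (the printed
49.4% sensitivity, 100% specificity and 0.747 AUC are self-consistent only
with 38). Counts, not percentages, are authoritative throughout.

## Feature selection and the sequential classifier

Selection keeps features with p < 0.05 whose AUC 95% CI lower bound
exceeds 0.5, then restricts to specificity > 90%, and finally removes an
expert-consensus exclusion list (default: the fatigue trigger, too
subjective to curate; ictal gastrointestinal symptoms, too heterogeneous).
Output is ordered by descending specificity with sensitivity and name as
tie-breaks, making it invariant to input order.

The shipped rule set applies high-specificity features sequentially
(first match wins): brief attacks -> EA1; interictal peripheral muscular
signs -> EA1; interictal nystagmus -> EA2; ictal headache -> EA2;
kinesigenic or startle trigger -> EA1; interictal ataxia -> EA2;
prolonged-or-protracted duration -> EA2. The published flowchart's exact
branch topology is not recoverable from text, so this ordering — by the
specificity evidence — is the package's own reconstruction; the rule set is
fully overridable from a YAML/JSON file so a user with the original figure
can encode it verbatim. Rules whose feature is unknown are skipped and
recorded in the trace; a case no rule decides is *indeterminate*, a
first-class decision-support outcome that counts as a miss in sensitivity.
An alternative `specificity_weighted_vote` conflict policy is provided for
sensitivity analysis of the rule-order assumption.

## Synthetic data

Two generators stand in for the curated per-subject tables, which live in
supplementary material and are not redistributed.

**Core prevalence fixture** (`core_prevalence_fixture`): a deterministic
370-case cohort (94 EA1, 276 EA2) whose every per-feature marginal count
equals the published count — duration categories 61/9/9/2 vs 11/33/119/20,
frequency categories 25/25/7/9 vs 22/72/34/10, all trigger fractions, all
ictal/interictal sign fractions, drug responses (e.g. acetazolamide 17/33
vs 139/162), and the CACNA1A haploinsufficient/non-haploinsufficient split
with its per-feature evaluable denominators (168/78, 115/58, 76/38,
136/84). Sign counts not printed directly were reconstructed as the unique
integer solutions to the printed N / sensitivity / specificity triples and
validated by reproducing every printed AUC to three decimals. The overall
haploinsufficient total (190 of 276) is a construction choice — only the
per-feature denominators are published — set just large enough to realize
all of them. Joint co-occurrence of features within a case is arbitrary
but fixed; any statistic depending on more than one feature jointly
(beyond the composites constructed to match) is not anchored. Ages of
onset are deterministic quantile interpolations hitting the published
medians, IQRs and ranges.

**Sampling generator** (`generate_cohort` with `study_spec`): per group,
independent Bernoulli features at the published prevalences, categorical
duration/frequency with a raw value drawn uniformly inside the drawn
category's interval (protracted capped at 7 days), log-normal age of onset
matched to the published median and IQR on the log scale, and missingness
applied after sampling at the published rates (trigger availability is a
block: 15/94 and 162/276 of subjects lack all trigger data). Because the
published quartiles are not log-symmetric (4/10 vs median 7), the fitted
log-normal reproduces the median exactly but its own implied quartiles,
not the printed ones; parameter-recovery tests compare against the fitted
distribution. Features are independent within a group by default — the
publication reports only marginals — with an optional pairwise
Gaussian-copula correlation plan for stress tests. Everything is driven by
one `numpy` `default_rng(seed)`, so a spec plus seed reproduces a cohort
byte-for-byte.

What passing tests show: the pipeline arithmetic is exact on the published
marginals, and the classifier behaves as published *under feature
independence*. What they do not show: performance under realistic feature
co-occurrence, reporting and publication bias, or curation error — none of
which the publication quantifies.

## Problem sizes and determinism

Default verification sizes: parameter recovery at 5,000 subjects per
group; classifier operating-point checks at 300 per group over 20 seeds
(fully observed cohorts), where the default rule set attains EA2
sensitivity around 0.87–0.90 with a wrong-label rate near 0.05, comfortably
inside the >= 0.80 / <= 0.10 bands the tests assert. The published
test-cohort figure (87.5% EA2 sensitivity on 24 cases) depends on
case-level supplementary data and the unpublished flowchart topology, so
it is checked as this synthetic operating-point property rather than
reproduced. The ordinal duration AUC from the four published category
counts is 0.874; the published continuous-duration estimate is 0.88 with
its optimal cut-off at 10 minutes — the categorical reconstruction is the
testable surface, and the small gap is expected from binning.

## Known limitations

* The rule order is a reconstruction; users with the original flowchart
  should encode it via a rule-set file.
* Complete-case denominators assume missingness is non-informative, which
  literature curation cannot guarantee.
* The synthetic generator models no inter-feature dependence by default;
  classifier performance estimates inherit that assumption.
* No multiple-testing correction is applied (matching the source
  analysis); per-feature p-values should be read accordingly.
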