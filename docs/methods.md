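# Methods

## Clinical discretization

Severity classes of the apnea–hypopnea index (AHI, events/h) are the
standard right-open bands: norm < 5 ≤ mild < 15 ≤ mod < 30 ≤ sev. The six
risk-compatibility parameters and their cutoffs (all configurable through
`DiscretizationRules`) are:

| parameter   | classes        | rule (default)                          |
|-------------|----------------|-----------------------------------------|
| gender      | M / F          | as recorded                              |
| age group   | 0–3            | (−∞,20], (20,40], (40,60], (60,∞) years |
| hypertension| HBP / LBP      | systolic > 140 or diastolic > 90 mmHg   |
| obesity     | obese / not    | BMI > 30 kg/m² (strict)                 |
| neck        | thick / thin   | NC ≥ 40 cm (women), ≥ 43 cm (men)       |
| sleepiness  | yes / no       | Epworth score ≥ 11                      |

The age-group boundaries are printed ambiguously in most clinical
sources ("≤20", "20–40", …); we resolve them as half-open intervals
closed on the right, honouring the explicit "≤ 20" for the first group,
and expose them in the configuration. An explicit hypertension flag can
replace raw blood-pressure values, so cohorts distributed only as summary
tables remain usable. Records that violate the invariants (ESS outside
0–24, non-positive BMI/NC, negative AHI, no BP information) are rejected
with a logged reason; there is no imputation.

## Network and communities

Patients are linked when they share ≥ 4 of 6 parameter classes; the edge
weight is the shared-class count (4–6 after filtering), all parameters
weighted equally. Isolated patients stay in the node set — the downstream
community analysis covers the whole cohort, with singletons as their own
communities. A threshold sweep (1..6) reports density, component
structure, giant-component size and community count so the
strictness/fragmentation trade-off is visible rather than assumed.

Modularity (weighted by default; an unweighted flag is available, and
both paths are tested) is maximized by Louvain local moves
(`networkx.community.louvain_communities`) restarted from several seeded
shuffles, each polished by alternating steepest single-node moves on the
flat graph and greedy community-pair merges until a fixed point; the best
restart wins. The procedure is deterministic given the seed: the graph is
canonicalized to sorted node order first, so results do not depend on
input construction order. Returned community ids are ordered by
decreasing size (ties: smallest member id). Resolution is fixed at 1 by
default; the community count is an outcome, not a constraint. On graphs
of ≤ 10 nodes an exhaustive set-partition oracle (Bell-number
enumeration) provides the global optimum for testing; the heuristic is
held to within 0.02 modularity of it on random small graphs.

The layout integrates attraction |d|^a along edges against repulsion
|d|^r over all node pairs (a = 1, r = −1, the log-energy limit for the
repulsion term), by gradient descent with a backtracking step size, so
the recorded energy trace is non-increasing by construction. No
Barnes–Hut acceleration or gravity term is used — at the cohort sizes
involved (≈ 150 nodes) exact pairwise forces are cheap. For exponents
above −1 the energy minima of this family co-locate modularity
communities; the agreement ratio (mean intra- over mean inter-community
distance, < 1 meaning spatial clustering) quantifies this per run.

## Response classes and the NC threshold

A community's AHI improvement is, by default, the share of its
severe-before patients reclassified to norm/mild after the treatment
night. An alternative mode (relative drop in the severe head count) is
configurable; with only published marginal tables the joint before/after
counts are not recoverable, so no mode claims to reproduce any particular
published percentage exactly. Communities at ≥ 85% improvement are
labeled *best*, the rest *good*; the 85% default sits between the
published ranges of the two classes (87–89% versus 68–78%). A parameter
class is *representative* for a community when its prevalence reaches
0.70 (≥, inclusive), a value inside the gap the published per-community
tables imply (59% marked not representative, 84% marked representative).

The NC-threshold classifier predicts *good* iff NC ≤ cutoff. Both
orientations of the resulting 2×2 table are reported; they are
complementary (good-TPR = best-TNR and vice versa), which the tests
enforce. The contingency evaluation also accepts per-community head
counts directly, so published count tables can be re-scored without
patient-level data.

## Diagnostic statistics

ROC curves treat higher NC as evidence for OSA; test-positive means
score strictly above the cutoff, matching the "NC ≤ c vs NC > c" split
used throughout. The trapezoidal AUC over all distinct thresholds equals
the tie-corrected Mann–Whitney probability U/(n₊·n₋) — an exact identity
the suite checks to 1e−12. Confidence intervals use the Hanley–McNeil
standard error with normal quantiles, clipped to [0,1]; at AUC 0 or 1
the interval degenerates to a point. Youden's cutoff maximizes
sens + spec − 1 over candidate cutoffs (default: whole centimetres
spanning the observed range), ties broken toward the smaller cutoff.
Spearman and Mann–Whitney delegate to scipy.stats (average ranks,
t-approximation p for ρ; continuity-corrected normal p for U); two-sided
p-values throughout, 0.05 significance.

## Synthetic cohorts

The generators emulate the three study cohorts from their published
summary statistics:

* **Screening cohorts** — OSA-diagnosed males (n = 836; NC 44.91 ± 4.45
  cm, age 51.75 ± 12.47, BMI 33.13 ± 6.37, ESS 10.01 ± 5.07, AHI 41.68 ±
  24.07) and controls (n = 65; NC 40.67 ± 5.77, age 43.63 ± 18.66, BMI
  27.81 ± 6.37, ESS 6.73 ± 5.06, AHI 6.01 ± 2.42). All physiological
  marginals are normals truncated at zero (truncation mass is negligible
  at these coefficients of variation, so printed means/SDs are preserved);
  ESS is a rounded truncated normal clipped to [0, 24]. NC–AHI rank
  dependence is a Gaussian copula whose correlation is set analytically
  from the target Spearman ρ (r = 2 sin(πρ_s/6)), default ρ_s = 0.35.
  Hypertension prevalence is not published for these cohorts; defaults
  (0.6 OSA / 0.4 control) are plausible sleep-lab values and only affect
  one of six profile slots.
* **Titration cohort** — n = 145, 77% male, AHI-before drawn so that
  97.93% of patients are severe (the remainder moderate), via a strictly
  monotone piecewise inverse-CDF so the copula's rank dependence is
  preserved. The published summary is internally inconsistent here (a
  symmetric normal with the printed mean 52.28 ± 23.58 would put ~17% of
  mass below 30, and the printed severe-after share conflicts with the
  per-community after-tables); the generator prioritizes the severity-
  class structure over the printed AHI moments, since every downstream
  statistic consumes severity classes, not raw AHI. Post-treatment AHI is
  generated from the response model: a severe patient lands in the
  norm/mild band with probability 0.88 if thick-necked and 0.73
  otherwise (the midpoints of the published 87–89% and 68–78% class
  ranges), and in the mod/sev band otherwise. The within-band shapes
  (truncated normals) are stand-ins, not claims about the study data.
* **Planted-partition cohort** — each patient copies one of four
  archetype profiles (the published per-community majority classes) with
  every slot independently perturbed at flip probability 0.05 (booleans
  flip, the age group resamples among the other three); continuous
  measurements are then drawn from the titration marginals conditioned
  to the realized class side, so re-discretization recovers the planted
  profile exactly. Ground-truth labels are returned for recovery
  experiments.

All generators are bit-reproducible given (spec, seed).

What the synthetic cohorts do **not** emulate: the joint distribution of
all published variables beyond the stated marginals, the NC–AHI copula
and the response model; real measurement error; longitudinal adherence.
Passing tests therefore demonstrate that the pipeline recovers structure
it is guaranteed to contain at the published effect sizes — not that the
clinical findings replicate on new data.

## Known limits of planted-community recovery

Two of the four published archetype profiles differ in a single
parameter class (and another pair in two), so at threshold 4 their
blocks are linked by near-complete weight-5 bipartite edges. The
ground-truth 4-way partition then has *lower* modularity than the
partition that merges the two thick-neck blocks (measured 0.172 vs 0.212
on a seed-0 cohort), so any resolution-1 modularity maximizer — however
good — returns the merge; adjusted-Rand recovery of the planted 4-way
truth is structurally capped near 0.55. The acceptance suite keeps this
check at its face-value conditions and documents the failure; a
companion property test shows full recovery (ARI ≥ 0.9 in ≥ 90% of
seeds) once archetypes differ pairwise in ≥ 3 of 6 classes, which is the
generator's documented recoverability condition. On real data the
published four communities plausibly emerged because within-community
heterogeneity is richer than an archetype-plus-independent-flips model.

## Problem sizes and numerical choices

Tests run the planted-recovery experiments at n = 145 (20 seeds) and the
response-recovery experiment at 580 patients (community proportions
scaled ×4 from the published 55/32/29/29), a size chosen by a-priori
power analysis so that a 0.9-vs-0.85 improvement difference is
resolvable (binomial SD ≈ 0.017 at n ≈ 350). The oracle comparison uses
random graphs of 4–8 nodes, where Bell-number enumeration is immediate.
The screening AUC reproduction averages 50 replicate cohorts at the
published sizes (836/65). Layout runs 200 gradient iterations with
backtracking (halving on any energy increase, growth ×1.5 on success,
floor 1e−14); pairwise distances carry an 1e−12 jitter guard against
coincident points. Modularity comparisons use absolute tolerances of
1e−12; community ties break deterministically (sorted order, smallest
id).
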