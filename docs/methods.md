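# Methods

This note documents the models, defaults and design decisions behind
`ageplace`, and what the synthetic study conditions do and do not show
about real data.

## The synthetic scenario

The generator (`ageplace.synth`) emulates every raw source a national
ageing classification consumes, with known ground truth. Defaults
(`ScenarioConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_areas` | 2,000 | desk-scale stand-in for a national LSOA system; large enough for stable cluster geometry |
| `n_supergroups` / `groups_per_supergroup` | 5 / (3, 2, 2, 3, 3) | the two-tier 5/13 hierarchy typical of such products |
| `separation` | 2.5 | planted between-supergroup offset in within-cluster SD units; group offsets use half this |
| `n_practices` | 400 | one practice per ~5 areas, matching the national practice-to-LSOA ratio |
| `n_survey` / `survey_obs_lambda` | 16,000 / 7.0 | Poisson(7) respondents per area leaves ~10 % of areas with the ≥ 11 observations needed for training, mirroring the published training share of such surveys; the remainder of the 16,000 form an un-geocoded national tail |
| `seed` | 0 | root seed; each generator draws from an independent named substream |

**Planted geometry.** Each of the 65 direct catalogue variables gets a
per-supergroup offset `separation × z` and a per-group offset
`0.5 × separation × z'`, with `z, z'` fixed standard-normal draws, and
unit within-cluster noise, mapped onto plausible per-variable location
and scale. Demographic realism (age structure, education, affluence,
digital and prescribing tilts per supergroup) also scales linearly with
`separation`, so `separation = 0` removes *all* planted signal and
label recovery falls to chance; recovery is non-decreasing in the dial.

**Survey outcomes.** The four binary internet-use outcomes follow a
logistic model in the five constraint attributes plus a per-area offset
(supergroup digital tilt + N(0, 0.1) noise). The age gradient is
negative and dominant, so prevalence declines across age bands. The
latent per-area percentage — the quantity small-area estimation should
recover — integrates this model over the area's attribute distribution
(attributes independent within areas, exactly how respondents are
drawn), enumerated over all 756 attribute cells.

**Prescribing.** Latent annual log-rates combine a class base rate
(0.35 AChEI / 0.12 memantine items per person 50+ per year, plausible
for dementia medication), a supergroup tilt, a spatially smooth field
(Gaussian kernel, ~12-area correlation length) and small white noise.
The smooth field reflects that prescribing environments vary at the
scale of health systems rather than single areas — and is what makes
practice-level apportionment informative: allocation pools each
practice's ~5 catchment areas, so spatially white rates could not be
recovered by *any* apportionment scheme. Monthly practice items are
Poisson; registration counts are constant across the 60 months.

**What passing tests do not show.** The generator draws attributes
independently within areas (no cross-attribute interactions), plants
Gaussian, equally scaled cluster structure, uses a 1-D area ordering as
its spatial proxy, and keeps registration static. Real inputs have
survey non-response bias, attribute interactions, irregular geography
and practice churn; recovery statistics here certify the pipeline's
correctness, not its real-world accuracy.

## Prescribing apportionment

Shares are computed per (practice, year, month); a ledger month with no
registration snapshot borrows the practice's nearest *earlier* month
(registration extracts can lag prescribing extracts); practice-months
with items but no shares at all are returned in a report table, never
silently dropped. Allocations stay fractional until report time.
Allocation is linear, so summing monthly allocations over the five
years equals allocating period totals. Rates are not age-standardised;
areas with zero 50+ population get a flagged missing rate rather than
infinity.

## Small-area estimation

**IPF.** Starting from uniform weights summing to the area total, each
iteration rescales weights so one constraint variable's weighted
category totals match its targets, cycling through the five variables.
Convergence: maximum absolute marginal deviation relative to the area
total < 1e-8, capped at 1,000 iterations with a flag. Updates depend on
a respondent only through their constraint categories, so respondents
in the same attribute cell keep equal weights; the solver iterates over
distinct cells (≤ 756) and expands back to individuals — an exact
equivalence that makes whole-system runs cheap. Constraint categories
with positive targets but no survey support cannot receive weight;
their targets are redistributed proportionally across the variable's
supported categories and reported (or, on request, raised as a
structured error naming the empty cells).

**Extension model.** One XGBoost regressor per outcome (300 trees,
depth 3, learning rate 0.1, single-threaded, seeded), features = each
constraint category's share of the area total, sample weights = per-area
respondent counts, trained on areas with ≥ 11 geocoded respondents and
predicting *all* areas (model predictions are used everywhere, training
areas included, for consistency; callers can keep the raw
microsimulated values instead). Predictions are clipped to [0, 100].
Fewer than 10 training areas is an error. The feature choice is an
assumption: area-level constraint shares are the natural covariates
available for every area, but nothing forces a user to stop there.

## Preprocessing

Fixed order: screen → Box-Cox → range-scale. Skewness, quantiles and
the correlation matrix are reported; pairs with |r| ≥ 0.9 (default) and
constant columns are flagged for human review — the package never drops
a variable on its own, since that choice belongs to the analyst and
their stakeholders. Box-Cox uses the two-parameter form with
`shift = 1 − min(x)` when `min(x) ≤ 0`; λ maximises the profile
log-likelihood over [−3, 3]. The bound matters: on variables with large
location and small relative spread the unbounded MLE diverges and the
power transform underflows to a numerically constant column. A
brute-force likelihood grid (step 0.001) serves as an independent
oracle in the tests; estimates agree within 0.05 for every catalogue
variable. Range scaling maps each column exactly onto [0, 1]; the
fitted `TransformSpec` serialises to YAML so the identical transform
can be replayed on new data. Sensitivity analysis refits k-means
(fixed seed, fixed restarts) without each variable and reports deltas
of Silhouette, Calinski-Harabasz and Davies-Bouldin.

## Clustering

k-means with k-means++ initialisation, best of `n_init = 100` restarts
(10 for the exploratory clustergram), fixed seed. The clustergram
computes PC1 once on the column-centred scaled matrix (sign fixed by
the largest-|loading| coordinate); a node's position at each k is the
mean PC1 score of its members — the adopted reading of
"PC1-weighted centre"; the alternative (loading-weighted centroid
coordinates) is a one-line change in `pc1_scores` consumers but is not
the default. `suggest_k` automates the traditionally visual choice by
maximum mean Silhouette (ties to the smaller k) and flags best
Silhouette < 0.25 as weak structure (the Kaufman–Rousseeuw rule of
thumb); the full diagnostics table supports a human override, and the
CLI accepts explicit `--k-top`/`--k-sub`. The second tier re-clusters
each supergroup's rows on all 71 scaled variables (no per-supergroup
re-selection). Cluster codes at both tiers are assigned in descending
member count, so runs are comparable; note this means the *planted*
supergroup indices need not coincide with fitted codes — recovery tests
map fitted supergroups to planted ones by majority before choosing
per-supergroup subgroup counts.

## Profiles, summaries, ground truth

Pen portraits are computed on the standardised version of the matrix
that was clustered (the only internally consistent frame): supergroups
against the global mean (so size-weighted mean z per variable closes to
0), groups against their parent supergroup with columns re-standardised
on the parent subset (deviation in parent-SD units; the parent frame
needs an SD convention and this is the adopted one). Summary tables
report area counts, the supergroup's share of the total 50+ population,
the unweighted mean of area median ages (population weighting would be
an equally defensible alternative) and the mean Older Person Ratio
(pop 65+ / pop 18–64, NaN where the denominator is 0). Exports order
variables by descending z with lexical tie-breaks. Ground-truth scoring
treats an unmatched colour as an incorrect attempt; pooled accuracy is
therefore always bracketed by the stratum accuracies.

## Problem sizes

Module tests run on a 300-area scenario; end-to-end checks and the
acceptance script use the full 2,000-area defaults. The complete
default pipeline (generation through profiling) runs in well under a
minute on one CPU.

## Known limitations

- The 71-variable catalogue is a synthetic-representative stand-in
  (names and domain placement follow the field's pen-portrait
  vocabulary), not a published variable list.
- IPF supplies no interaction information beyond the survey seed; areas
  whose outcome levels deviate from their demographic profile are
  systematically smoothed toward it (visible in the held-out recovery
  being < 1).
- Apportioned prescribing rates are pooled over practice catchments;
  they inherit the spatial resolution of registration, not of the areas.
- The ground-truthing module scores responses; it does not render maps
  or manage panels.
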