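# ageplace

A tested re-implementation of the methodology behind small-area
geodemographic classifications of ageing populations: from raw source
tables (census-style cross-tabulations, survey microdata, GP prescribing
ledgers, secondary area indicators) to a two-tier k-means classification
with pen-portrait profiles and a ground-truthing score.

## Who this is for

Quantitative geographers, public-health analysts and biostatisticians
who want to build — or scrutinise — an area classification of older
people (aged 50+). National products of this kind assign each small area
(LSOA-like units of ~1,500 residents) to one of a handful of labelled
clusters describing the older population and its living environment, and
are used to target service planning. The full input data for such
products are restricted, so this package ships a synthetic-data
generator with *planted* cluster structure: every pipeline stage can be
run, tested and validated against known ground truth.

## The method

1. **Prescribing-rate apportionment.** GP prescribing ledgers give
   monthly item counts per practice, not per patient address. For each
   practice-month, items are split across areas in proportion to where
   the practice's registered patients live, then summed and divided by
   the 50+ population and the years covered:
   `rate_a = Σ items allocated to a / (pop50_a × n_years)`.
   Rates are deliberately not age-standardised — they describe the
   local treatment environment, not prevalence.
2. **Small-area estimation of digital engagement.** Iterative
   proportional fitting (IPF) reweights survey respondents so weighted
   category totals match each area's constraint marginals (age band,
   gender, qualification, social grade, economic activity). Weighted
   outcome means give per-area percentages for four internet-use
   outcomes; areas with ≥ 11 locally observed respondents provide
   training targets for sample-weighted gradient-boosted models
   (XGBoost) that predict all areas from constraint-share features.
3. **Preprocessing.** Descriptive screening and correlation flags, then
   per-variable Box-Cox normalisation (ML λ, bounded to [−3, 3], with a
   shift to positivity) and range scaling to [0, 1], plus a
   drop-one-variable cluster sensitivity analysis (Silhouette,
   Calinski-Harabasz, Davies-Bouldin deltas).
4. **Clustering.** A clustergram (per-k cluster centres projected on
   PC1, with member flows between consecutive k) supports the choice of
   k; k-means (best of 100 restarts) fits the top tier (*supergroups*),
   then re-clusters each supergroup into nested *groups* coded `s.j`.
5. **Profiling and validation.** Pen portraits are per-cluster mean
   z-scores of all input variables (0 = national average; groups are
   profiled against their parent supergroup), with summary tables
   (area counts, 50+ population share, mean median age, mean Older
   Person Ratio = pop 65+ / pop 18–64) and an accuracy score for the
   colour-matching ground-truthing exercise.

## Worked example

```python
from ageplace.config import ScenarioConfig
from ageplace.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(scenario=ScenarioConfig(seed=0), seed=0))
print(bundle.hierarchy.assignments["group"].nunique())
print(bundle.summary.round(2))
```

prints `13` (the second-tier group count of the default 5-supergroup
configuration) and

```
            n_areas  pct_pop_50plus  mean_median_age  mean_older_person_ratio
supergroup
1               518           28.89            41.73                     0.43
2               510           28.18            41.12                     0.40
3               476           22.10            38.94                     0.24
4               271           11.83            38.04                     0.20
5               225            9.00            36.81                     0.15
```

i.e. supergroup 1 holds 518 of the 2,000 areas and 28.9 % of the 50+
population, and its areas skew oldest (highest mean median age and
Older Person Ratio). The same run recovers the planted top-tier labels
with adjusted Rand index 1.000, recovers planted prescribing rates with
r ≈ 0.90 and latent digital-engagement percentages with held-out
r ≈ 0.83–0.87 (see `analysis/`, whose numbered scripts narrate each
stage and write their tables under `results/`).

The `ageplace` CLI exposes the same stages (`simulate`, `prescribe`,
`sae`, `preprocess`, `cluster`, `profile`, `groundtruth`, `run`).

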