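# pollenprofiles

Tools for studying **when in the grass pollen season allergy sufferers
experience their worst symptoms**, from two daily data streams: airborne
pollen concentrations (Hirst-type volumetric trap, grains/m³) and a
crowd-sourced symptom diary (eye/nose/lung/medication sub-scores per
user-day). It is aimed at aerobiologists and allergy epidemiologists who
want a tested, reproducible version of the standard season-profile
analysis rather than one-off scripts.

The pipeline:

1. **Season delimitation** — the main pollination period runs from the
   first day the cumulative annual pollen sum reaches 1% of the annual
   total to the first day it reaches 95%; the Annual Pollen Integral
   (APIn) is Σ c(d) over the closed season (pollen·day/m³).
2. **Sufferer filter** — keep users with ≥15 in-season diary days whose
   daily score s_u(d) has a positive Spearman correlation with same-day
   pollen c(d), one-sided p < 0.05.
3. **Imputation** — fill each user's missing season days with the median
   of the k = 3 nearest observed days under a range-normalised Manhattan
   (Gower-style) distance over (day of season, pollen concentration).
4. **Three season partitions** — APIn tertiles (cuts where the
   within-season cumulative pollen reaches APIn/3 and 2·APIn/3);
   phenology dates (cuts at the flowering onset of the main- and
   late-season grass taxa); per-user SLI tertiles (cuts where the user's
   cumulative symptom load reaches 1/3 and 2/3 of its total).
5. **Classification & reporting** — assign each user-year to the section
   of peak severity (argmax of mean daily score per section, earliest on
   ties), tabulate counts/percentages, draw cumulative SLI-vs-APIn
   profile curves with fast/slow-reactor flags, and summarise cross-year
   profile stability for users present in every year.

Because raw diaries of this kind cannot be shared, the package includes
a first-class synthetic generator (`pollenprofiles.synthetic`) producing
multi-peak pollen years and diary cohorts with hidden per-user section
labels, used throughout the tests to verify that the pipeline recovers
known truth.

## Worked example

```python
import pollenprofiles as pp

pollen = pp.gen_pollen_year(pp.DEFAULT_TAXA, year=2015)
season = pp.define_season(pollen, 2015)
partition = pp.apin_tertile_partition(pollen, season)

users = pp.make_users(100, pollen, partition, seed=2)
entries, truth = pp.gen_cohort(users, pollen, partition, seed=3)
series = pp.build_user_series(entries, season)
kept = pp.filter_users(series, pollen)
assignments = [pp.assign_section(s, partition) for s in kept]
table = pp.section_table(assignments, "apin")
print(season.start_date, season.end_date, season.duration_days, round(season.apin))
print(table.counts, table.percentages)
```

Running `python examples/delimit_season.py` prints:

```
season start 2015-05-08 (1% of annual total reached)
season end   2015-07-29 (95% reached)
duration     83 days, APIn 2763.1
section 1: 2015-05-08 .. 2015-06-06  (30 days)
section 2: 2015-06-07 .. 2015-06-21  (15 days)
section 3: 2015-06-22 .. 2015-07-29  (38 days)
```

i.e. an 83-day season whose middle third of pollen mass falls in a short
15-day core — the main pollination period. `examples/` holds one short
script per capability (simulation, season delimitation, filtering and
classification, imputation and profile curves, cross-year stability);
each prints the numbers it computes and a line on what they mean.
`docs/methods.md` documents the model, parameter defaults and
conventions (rounding, tie-breaks, degenerate inputs) in detail.

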