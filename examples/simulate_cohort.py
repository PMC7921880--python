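"""Generate a synthetic pollen year and diary cohort and write the three
pipeline CSVs (pollen, diary, phenology) to ./scratch_example/.

The printed numbers are the season the generator produced and the size of
the simulated diary: a multi-peak grass season of ~3 months and ~100
users entering scores on ~70% of season days.
"""

from pathlib import Path

import pollenprofiles as pp

out = Path("scratch_example")
out.mkdir(exist_ok=True)

pollen = pp.gen_pollen_year(pp.DEFAULT_TAXA, year=2015, seed=1)
season = pp.define_season(pollen, 2015)
partition = pp.apin_tertile_partition(pollen, season)
users = pp.make_users(100, pollen, partition, seed=2)
entries, truth = pp.gen_cohort(users, pollen, partition, seed=3)

pp.write_pollen_csv(pollen, out / "pollen.csv")
pp.write_diary_csv(entries, out / "diary.csv")
pp.write_phenology_csv(pp.default_phenology(2015), out / "phenology.csv")

n_obs = sum(len(v) for v in truth.observed_days.values())
print(f"season: {season.start_date} .. {season.end_date} "
      f"({season.duration_days} days, APIn {season.apin:.0f})")
print(f"cohort: {len(users)} users, {n_obs} diary entries "
      f"({n_obs / (len(users) * season.duration_days):.0%} of user-days)")
print(f"hidden labels: "
      f"{[sum(1 for s in truth.true_sections.values() if s == k) for k in (1, 2, 3)]}"
      " users peak in sections 1/2/3")
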