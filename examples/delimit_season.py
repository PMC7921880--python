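"""Delimit the main pollination period of a pollen year and split it into
cumulative-pollen tertiles.

Printed: the 1%/95% season boundaries, duration, Annual Pollen Integral
(sum of daily means over the season, pollen.day/m^3), and the two cut
dates at which one and two thirds of the APIn are reached.
"""

import pollenprofiles as pp

pollen = pp.gen_pollen_year(pp.DEFAULT_TAXA, year=2015)
season = pp.define_season(pollen, 2015)
print(f"season start {season.start_date} (1% of annual total reached)")
print(f"season end   {season.end_date} (95% reached)")
print(f"duration     {season.duration_days} days, APIn {season.apin:.1f}")

partition = pp.apin_tertile_partition(pollen, season)
for k, (lo, hi) in enumerate(partition.sections, start=1):
    print(f"section {k}: {lo} .. {hi}  "
          f"({pp.season_duration(lo, hi)} days)")
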