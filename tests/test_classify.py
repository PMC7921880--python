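import datetime as dt

import numpy as np
import pytest

import pollenprofiles as pp
from pollenprofiles.errors import (
    ConfigError,
    DegeneratePartitionError,
    InsufficientDataError,
    ValidationError,
)


def season_may_july(year=2015):
    return pp.SeasonDefinition(
        year=year,
        start_date=dt.date(year, 5, 1),
        end_date=dt.date(year, 7, 31),
        duration_days=92,
        apin=1000.0,
    )


def phen_period(taxon, start):
    return pp.PhenologyPeriod(
        taxon=taxon,
        flowering_start=start,
        full_flowering_start=start + dt.timedelta(days=7),
        full_flowering_end=start + dt.timedelta(days=21),
        flowering_end=start + dt.timedelta(days=28),
    )


def complete_series(season, score_fn, uid="u"):
    scores = {d: float(score_fn(d)) for d in season.days}
    return pp.ImputedSeries(
        user_id=uid, year=season.year, daily_scores=scores,
        imputed_flags={d: False for d in scores},
    )


class TestPhenologyPartition:
    def test_construction_from_group_onsets(self):
        season = season_may_july()
        periods = [
            phen_period("Poa pratensis", dt.date(2015, 5, 1)),
            phen_period("Dactylis glomerata", dt.date(2015, 5, 5)),
            phen_period("Arrhenatherum elatius", dt.date(2015, 6, 1)),
            phen_period("Festuca sp.", dt.date(2015, 6, 3)),
            phen_period("Lolium perenne", dt.date(2015, 6, 6)),
            phen_period("Phleum pratense", dt.date(2015, 7, 1)),
            phen_period("Cynodon dactylon", dt.date(2015, 7, 4)),
        ]
        part = pp.phenology_partition(periods, season)
        assert part.sections == (
            (dt.date(2015, 5, 1), dt.date(2015, 5, 31)),
            (dt.date(2015, 6, 1), dt.date(2015, 6, 30)),
            (dt.date(2015, 7, 1), dt.date(2015, 7, 31)),
        )

    def test_late_before_main_is_degenerate(self):
        season = season_may_july()
        periods = [
            phen_period("Poa pratensis", dt.date(2015, 5, 1)),
            phen_period("Dactylis glomerata", dt.date(2015, 5, 3)),
            phen_period("Arrhenatherum elatius", dt.date(2015, 6, 15)),
            phen_period("Festuca sp.", dt.date(2015, 6, 18)),
            phen_period("Lolium perenne", dt.date(2015, 6, 20)),
            phen_period("Phleum pratense", dt.date(2015, 6, 1)),
            phen_period("Cynodon dactylon", dt.date(2015, 6, 2)),
        ]
        with pytest.raises(DegeneratePartitionError):
            pp.phenology_partition(periods, season)

    def test_missing_group_is_config_error(self):
        season = season_may_july()
        periods = [phen_period("Poa pratensis", dt.date(2015, 5, 1))]
        with pytest.raises(ConfigError, match="matches no phenology record"):
            pp.phenology_partition(periods, season)

    def test_default_phenology_tiles_the_season(self, season_2015, phen_part):
        (a1, b1), (a2, b2), (a3, b3) = phen_part.sections
        assert a1 == season_2015.start_date
        assert b3 == season_2015.end_date
        assert b1 < a2 <= b2 < a3
        n_days = sum((b - a).days + 1 for a, b in phen_part.sections)
        assert n_days == season_2015.duration_days


class TestSliTertiles:
    def test_uniform_scores_cut_at_thirds(self):
        season = pp.SeasonDefinition(
            year=2015, start_date=dt.date(2015, 6, 1),
            end_date=dt.date(2015, 6, 30), duration_days=30, apin=1.0,
        )
        series = complete_series(season, lambda d: 1.0)
        part = pp.sli_tertile_sections(series, season)
        assert part.cut1 == dt.date(2015, 6, 10)
        assert part.cut2 == dt.date(2015, 6, 20)

    def test_mass_on_final_day_is_degenerate(self):
        season = pp.SeasonDefinition(
            year=2015, start_date=dt.date(2015, 6, 1),
            end_date=dt.date(2015, 6, 30), duration_days=30, apin=1.0,
        )
        series = complete_series(
            season, lambda d: 9.0 if d == season.end_date else 0.0
        )
        with pytest.raises(DegeneratePartitionError):
            pp.sli_tertile_sections(series, season)

    def test_all_zero_scores_rejected(self):
        season = season_may_july()
        series = complete_series(season, lambda d: 0.0)
        with pytest.raises(ValidationError, match="all-zero"):
            pp.sli_tertile_sections(series, season)

    def test_cuts_are_first_crossings_of_thirds(self):
        rng = np.random.default_rng(4)
        season = season_may_july()
        days = season.days
        for _ in range(50):
            scores = rng.integers(0, 13, size=len(days)).astype(float)
            if scores[: len(days) - 2].sum() == 0:
                continue
            series = pp.ImputedSeries(
                "u", 2015, dict(zip(days, scores)),
                {d: False for d in days},
            )
            try:
                part = pp.sli_tertile_sections(series, season)
            except DegeneratePartitionError:
                continue
            total = scores.sum()
            csum = dict(zip(days, np.cumsum(scores)))
            one = dt.timedelta(days=1)
            assert csum[part.cut1] >= total / 3
            if part.cut1 > season.start_date:
                assert csum[part.cut1 - one] < total / 3
            assert csum[part.cut2] >= 2 * total / 3
            assert csum[part.cut2 - one] < 2 * total / 3

    def test_score_mass_per_segment_within_one_day(self):
        """With strictly positive daily scores each tertile segment holds
        total/3 of the mass up to a single day's score."""
        rng = np.random.default_rng(8)
        season = season_may_july()
        days = season.days
        scores = rng.integers(1, 13, size=len(days)).astype(float)
        series = pp.ImputedSeries(
            "u", 2015, dict(zip(days, scores)), {d: False for d in days}
        )
        part = pp.sli_tertile_sections(series, season)
        total = scores.sum()
        max_day = scores.max()
        by_day = dict(zip(days, scores))
        for lo, hi in part.sections:
            mass = sum(v for d, v in by_day.items() if lo <= d <= hi)
            assert abs(mass - total / 3) <= max_day


class TestAssignSection:
    def test_support_in_one_section_wins(self, season_2015, apin_part):
        days = [apin_part.cut1 + dt.timedelta(days=3)]  # inside section 2
        series = pp.UserSeasonSeries("u", 2015, season_2015, {days[0]: 5.0})
        a = pp.assign_section(series, apin_part, statistic="sum")
        assert a.section == 2

    def test_constant_scores_tie_break_to_first_section(self):
        season = season_may_july()
        part = pp.SectionPartition(
            method="apin", season=season,
            cut1=dt.date(2015, 5, 31), cut2=dt.date(2015, 6, 30),
        )
        series = complete_series(season, lambda d: 2.0)
        a = pp.assign_section(series, part)
        assert a.section == 1
        assert a.per_section_summary[0] == a.per_section_summary[1]

    def test_empty_section_with_mean_instructs_to_impute(
        self, season_2015, apin_part
    ):
        series = pp.UserSeasonSeries(
            "u", 2015, season_2015, {season_2015.start_date: 3.0}
        )
        with pytest.raises(InsufficientDataError, match="impute"):
            pp.assign_section(series, apin_part, statistic="mean")

    def test_invariant_to_positive_rescaling(self, season_2015, apin_part):
        rng = np.random.default_rng(12)
        days = season_2015.days
        scores = {d: float(rng.integers(0, 13)) for d in days[::2]}
        base = pp.UserSeasonSeries("u", 2015, season_2015, scores)
        scaled = pp.UserSeasonSeries(
            "u", 2015, season_2015, {d: 7.0 * v for d, v in scores.items()}
        )
        for stat in ("mean", "sum", "peak"):
            assert (
                pp.assign_section(base, apin_part, stat).section
                == pp.assign_section(scaled, apin_part, stat).section
            )

    def test_noise_free_cohort_fully_recovered_by_calendar_methods(
        self, pollen_2015, season_2015, apin_part, phen_part
    ):
        """With no reporting noise and full adherence, APIn- and
        phenology-based classification recover every hidden label."""
        for part in (apin_part, phen_part):
            users = pp.make_users(
                30, pollen_2015, part, seed=21, noise_sd=0.0, adherence=1.0
            )
            entries, truth = pp.gen_cohort(users, pollen_2015, part, seed=22)
            series = pp.build_user_series(entries, season_2015)
            assert len(series) == 30
            for s in series:
                a = pp.assign_section(s, part)
                assert a.section == truth.true_sections[s.user_id]

    def test_sli_fastest_accumulation_semantics(self):
        """The SLI label is the tertile segment with the highest mean daily
        score, i.e. where symptom load accumulates fastest."""
        season = pp.SeasonDefinition(
            year=2015, start_date=dt.date(2015, 6, 1),
            end_date=dt.date(2015, 6, 30), duration_days=30, apin=1.0,
        )
        # 27 low days then a sharp three-day burst: the last tertile of the
        # load arrives in two days, the fastest accumulation of the season
        series = complete_series(
            season, lambda d: 9.0 if d >= dt.date(2015, 6, 28) else 1.0
        )
        part = pp.sli_tertile_sections(series, season)
        a = pp.assign_section(series, part)
        assert a.section == 3
        # mirrored: sharp burst at the start
        series2 = complete_series(
            season, lambda d: 9.0 if d <= dt.date(2015, 6, 3) else 1.0
        )
        part2 = pp.sli_tertile_sections(series2, season)
        assert pp.assign_section(series2, part2).section == 1


class TestAnova:
    def _series_from_groups(self, groups):
        season = pp.SeasonDefinition(
            year=2015, start_date=dt.date(2015, 6, 1),
            end_date=dt.date(2015, 6, 1)
            + dt.timedelta(days=sum(len(g) for g in groups) - 1),
            duration_days=sum(len(g) for g in groups),
            apin=1.0,
        )
        days = season.days
        n1, n2 = len(groups[0]), len(groups[1])
        part = pp.SectionPartition(
            method="apin", season=season,
            cut1=days[n1 - 1], cut2=days[n1 + n2 - 1],
        )
        flat = [v for g in groups for v in g]
        series = pp.ImputedSeries(
            "u", 2015, dict(zip(days, map(float, flat))),
            {d: False for d in days},
        )
        return series, part

    def test_identical_values_flagged_degenerate(self):
        series, part = self._series_from_groups([[2, 2, 2], [2, 2, 2], [2, 2, 2]])
        res = pp.anova_sections(series, part)
        assert res.degenerate
        assert np.isnan(res.f_statistic)

    def test_equal_group_means_give_f_zero(self):
        series, part = self._series_from_groups([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        res = pp.anova_sections(series, part)
        assert res.f_statistic == pytest.approx(0.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_textbook_mean_squares(self):
        rng = np.random.default_rng(13)
        groups = [list(rng.normal(m, 1.0, size=n)) for m, n in ((0, 8), (1, 12), (3, 7))]
        series, part = self._series_from_groups(groups)
        res = pp.anova_sections(series, part)
        # independent arithmetic: F = MSB / MSW
        all_vals = np.concatenate([np.array(g) for g in groups])
        grand = all_vals.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.array(g) - np.mean(g)) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / (len(all_vals) - 3))
        assert res.f_statistic == pytest.approx(f)
        from scipy.stats import f as fdist

        assert res.p_value == pytest.approx(fdist.sf(f, 2, len(all_vals) - 3))

    def test_small_section_rejected(self):
        series, part = self._series_from_groups([[1, 2], [1], [1, 2]])
        with pytest.raises(InsufficientDataError):
            pp.anova_sections(series, part)
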