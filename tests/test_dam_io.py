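"""DAM monitor file parsing/writing, binning and the survivor filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circadam import (
    FlySimParams,
    LightSchedule,
    MonitorData,
    bin_series,
    filter_survivors,
    parse_dam_text,
    simulate_population,
    write_dam_text,
)
from circadam.dam_io import N_CHANNELS, DamParseError


def make_lines(counts_rows, start="01 Jan 25\t08:00:00", statuses=None):
    """Construct DAMSystem3 lines from per-minute 32-count rows."""
    date, time = start.split("\t")
    hh, mm, ss = (int(v) for v in time.split(":"))
    lines = []
    for i, row in enumerate(counts_rows):
        status = 1 if statuses is None else statuses[i]
        minute = mm + i
        t = f"{hh + minute // 60:02d}:{minute % 60:02d}:{ss:02d}"
        fields = [str(i + 1), date, t, str(status)] + ["0"] * 6 + [str(v) for v in row]
        lines.append("\t".join(fields))
    return lines


class TestParse:
    def test_well_formed_counts_preserved(self):
        rows = [list(range(32)), [5] * 32, list(range(100, 132))]
        data = parse_dam_text(make_lines(rows))
        assert data.counts.shape == (32, 3)
        assert np.array_equal(data.counts.T, np.array(rows, dtype=float))
        assert data.timestamps[0] == pd.Timestamp("2025-01-01 08:00:00")

    def test_invalid_status_row_marks_minute_missing(self):
        rows = [[1] * 32, [0] * 32, [2] * 32]
        data = parse_dam_text(make_lines(rows, statuses=[1, 51, 1]))
        # hand parse: minute 1 missing for every channel, others preserved
        assert np.isnan(data.counts[:, 1]).all()
        assert (data.counts[:, 0] == 1).all()
        assert (data.counts[:, 2] == 2).all()
        assert data.status[1] == 51

    def test_timestamp_gap_filled_with_missing(self):
        lines = make_lines([[3] * 32])
        lines += make_lines([[4] * 32], start="01 Jan 25\t08:02:00")
        lines[1] = "2" + lines[1][1:]
        data = parse_dam_text(lines)
        assert data.n_minutes == 3
        assert np.isnan(data.counts[:, 1]).all()

    @pytest.mark.parametrize(
        "mutate, match",
        [
            (lambda ls: [ls[0] + "\textra"[:0], "bad line"], "line 2"),
            (lambda ls: [ls[0], ls[0]], "duplicate"),
            (lambda ls: [ls[1], ls[0]], "non-monotonic"),
        ],
    )
    def test_malformed_input_raises_naming_line(self, mutate, match):
        lines = make_lines([[0] * 32, [1] * 32])
        with pytest.raises(DamParseError, match=match):
            parse_dam_text(mutate(lines))

    def test_channel_map_attaches_genotypes(self):
        data = parse_dam_text(
            make_lines([[0] * 32]), channel_map={3: {"genotype": "per01", "sex": "f"}}
        )
        assert data.flies.loc["M01C03", "genotype"] == "per01"
        assert (data.flies.drop("M01C03")["genotype"] == "unknown").all()


class TestWrite:
    def test_single_fly_counts_in_channel_field(self, ld_dd_schedule):
        pop = simulate_population([FlySimParams()], ld_dd_schedule, 1, seed=0)
        pop.counts[0, :2] = [0, 5]
        lines = write_dam_text(pop)
        assert lines[0].split("\t")[10] == "0"
        assert lines[1].split("\t")[10] == "5"

    def test_empty_data_empty_output(self):
        data = parse_dam_text([])
        assert write_dam_text(data) == []

    def test_roundtrip_bit_exact(self, small_population):
        lines = write_dam_text(small_population)
        back = parse_dam_text(lines, schedule=small_population.schedule)
        assert write_dam_text(back) == lines
        assert np.array_equal(back.counts[:4], small_population.counts)

    def test_roundtrip_with_invalid_rows(self):
        rows = [[7] * 32, [0] * 32, [9] * 32]
        lines = make_lines(rows, statuses=[1, 51, 1])
        assert write_dam_text(parse_dam_text(lines)) == lines

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_random_monitor(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(3.0, size=(N_CHANNELS, 10)).astype(float)
        ts = pd.date_range("2025-02-19 08:00", periods=10, freq="min")
        data = MonitorData(counts, ts, parse_dam_text(make_lines([[0] * 32])).flies)
        back = parse_dam_text(write_dam_text(data))
        assert np.array_equal(back.counts, data.counts)
        assert write_dam_text(back) == write_dam_text(data)


class TestBinSeries:
    def test_constant_rate(self):
        assert np.array_equal(bin_series([2] * 120, 30), [60, 60, 60, 60])

    def test_trailing_partial_bin_dropped(self):
        assert np.array_equal(bin_series([1] * 61, 30), [30, 30])

    def test_missing_minute_poisons_bin(self):
        x = np.ones(60)
        x[40] = np.nan
        out = bin_series(x, 30)
        assert out[0] == 30 and np.isnan(out[1])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            bin_series([1, 2], 0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 45))
    def test_matches_brute_force_slice_sums(self, seed, width):
        x = np.random.default_rng(seed).poisson(2.0, 200).astype(float)
        out = bin_series(x, width)
        expected = [sum(x[i * width:(i + 1) * width]) for i in range(len(x) // width)]
        assert np.allclose(out, expected)
        # conservation over complete bins
        assert np.isclose(out.sum(), x[: len(out) * width].sum())


class TestFilterSurvivors:
    def _pop(self, death_days, schedule, n_days=11):
        specs = [
            FlySimParams(death_day=d if d >= 0 else None) for d in death_days
        ]
        return simulate_population(specs, schedule, n_days, seed=7)

    def test_terminal_zero_run_is_dead(self, ld_dd_schedule):
        pop = self._pop([-1], ld_dd_schedule)
        fid = pop.fly_ids[0]
        # silence the final 36 h of the 6-day DD window by hand
        start = 11 * 1440 - 36 * 60
        pop.counts[0, start:] = 0.0
        pop.counts[0, start - 1] = 3.0
        _, report = filter_survivors(pop, (5, 11))
        assert report.table.loc[fid, "status"] == "dead"
        assert report.table.loc[fid, "death_minute"] == start

    def test_active_in_final_hour_is_alive(self, ld_dd_schedule):
        pop = self._pop([-1], ld_dd_schedule)
        pop.counts[0, 5 * 1440:] = 0.0
        pop.counts[0, -30] = 1.0
        _, report = filter_survivors(pop, (5, 11))
        assert (report.table["status"] == "alive").all()

    def test_simulated_deaths_recovered(self, ld_dd_schedule):
        death_days = [-1] * 10 + [6, 7, 8] + [-1] * 19
        pop = self._pop(death_days, ld_dd_schedule)
        survivors, report = filter_survivors(pop, (5, 11))
        truth_dead = {pop.fly_ids[i] for i, d in enumerate(death_days) if d >= 0}
        called_dead = set(report.table.index[report.table["status"] == "dead"])
        assert called_dead == truth_dead
        assert survivors.n_flies == 29

    def test_idempotent_and_independent_verdicts(self, ld_dd_schedule):
        pop = self._pop([-1] * 5 + [6], ld_dd_schedule)
        survivors, r1 = filter_survivors(pop, (5, 11))
        again, r2 = filter_survivors(survivors, (5, 11))
        assert again.n_flies == survivors.n_flies
        alive1 = r1.table[r1.table["status"] == "alive"]["status"]
        assert (r2.table["status"] == alive1).all()

    def test_empty_window_rejected(self, ld_dd_schedule):
        pop = self._pop([-1], ld_dd_schedule)
        with pytest.raises(ValueError):
            filter_survivors(pop, (5, 5))
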