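import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import operantfp as ofp
from operantfp.behavior import (
    EventOffset,
    EventRecord,
    GuardedSwitch,
    IntervalRecord,
    PairedOnOff,
    SetOp,
    diff_spans,
    intersect_spans,
    merge_spans,
    union_spans,
)


def _session(events, intervals=()):
    return ofp.BehaviorSession(
        source="<memory>",
        events=[EventRecord(n, t) for n, t in events],
        intervals=[IntervalRecord(n, s, e) for n, s, e in intervals],
    )


# --------------------------------------------------------------------------
# Parsers
# --------------------------------------------------------------------------


class TestImetronicParser:
    def test_millisecond_timestamps_convert_to_seconds(self, tmp_path, cfg):
        f = tmp_path / "a.dat"
        f.write_text("1200000\t2\t1\t0\t1\n")
        sess = ofp.parse_imetronic(f, cfg)
        assert sess.events == [EventRecord("np1", 1200.0)]

    def test_unmatched_rows_counted_not_fatal(self, tmp_path, cfg):
        f = tmp_path / "a.dat"
        f.write_text("10\t9\t9\t0\t0\n20\t9\t8\t0\t0\n")
        with pytest.warns(UserWarning):
            sess = ofp.parse_imetronic(f, cfg)
        assert sess.events == []
        assert sess.unmatched_rows == 2

    def test_synthetic_fixture_round_trip(self, tmp_path, cfg):
        events = [("np1", 1.0 + i) for i in range(5)] + [("inj1", 10.5)]
        truth = ofp.GroundTruth(
            events=__import__("pandas").DataFrame(sorted(events, key=lambda x: x[1]), columns=["name", "time"]),
            intervals=__import__("pandas").DataFrame(columns=["name", "start", "end"]),
            session_end=20.0,
            seed=0,
        )
        f = tmp_path / "b.dat"
        ofp.write_imetronic(truth, f)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sess = ofp.parse_imetronic(f, cfg)
        assert [(e.name, e.time) for e in sess.events] == sorted(events, key=lambda x: (x[1], x[0]))


class TestGenericParser:
    def test_three_columns_two_rows(self, tmp_path, cfg):
        f = tmp_path / "t.dat"
        f.write_text("Dim1_on,Dim1_off,Dim2\n2.5,3.5,4.5\n7.5,8.5,9.5\n")
        sess = ofp.parse_generic_csv(f, cfg)
        assert len(sess.events) == 6
        assert sess.event_names() == ["Dim1_off", "Dim1_on", "Dim2"]
        assert list(sess.event_times("Dim1_on")) == [2.5, 7.5]

    def test_single_column_single_timestamp(self, tmp_path, cfg):
        f = tmp_path / "t.dat"
        f.write_text("lick\n12.0\n")
        sess = ofp.parse_generic_csv(f, cfg)
        assert [(e.name, e.time) for e in sess.events] == [("lick", 12.0)]

    def test_ragged_columns_no_padding_artifacts(self, tmp_path, cfg):
        f = tmp_path / "t.dat"
        f.write_text("a,b,c\n1,4,6\n2,,7\n3,,\n")
        sess = ofp.parse_generic_csv(f, cfg)
        assert len(sess.events) == 6
        assert list(sess.event_times("a")) == [1, 2, 3]
        assert list(sess.event_times("b")) == [4]
        assert list(sess.event_times("c")) == [6, 7]

    def test_duplicate_header_fatal(self, tmp_path, cfg):
        f = tmp_path / "t.dat"
        f.write_text("a,a\n1,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            ofp.parse_generic_csv(f, cfg)

    def test_non_numeric_cell_reports_row_and_column(self, tmp_path, cfg):
        f = tmp_path / "t.dat"
        f.write_text("a,b\n1,2\n3,oops\n")
        with pytest.raises(ValueError, match=r"row 3.*'b'"):
            ofp.parse_generic_csv(f, cfg)


# --------------------------------------------------------------------------
# Interval derivation
# --------------------------------------------------------------------------


class TestDeriveIntervals:
    def test_paired_on_off(self):
        sess = _session([("hled_on", 2400.0), ("hled_off", 3300.0)])
        out = ofp.derive_intervals(sess, [PairedOnOff("HLED_ON", "hled_on", "hled_off")])
        (iv,) = out.intervals_named("HLED_ON")
        assert (iv.start, iv.end) == (2400.0, 3300.0)

    def test_unclosed_onset_closes_at_session_end(self):
        sess = _session([("hled_on", 10.0), ("np1", 50.0)])
        out = ofp.derive_intervals(sess, [PairedOnOff("HLED_ON", "hled_on", "hled_off")])
        (iv,) = out.intervals_named("HLED_ON")
        assert (iv.start, iv.end) == (10.0, 50.0)

    def test_offset_before_onset_warns_and_is_ignored(self):
        sess = _session([("hled_off", 5.0), ("hled_on", 10.0), ("hled_off", 20.0)])
        with pytest.warns(UserWarning, match="before any onset"):
            out = ofp.derive_intervals(sess, [PairedOnOff("HLED_ON", "hled_on", "hled_off")])
        (iv,) = out.intervals_named("HLED_ON")
        assert (iv.start, iv.end) == (10.0, 20.0)

    def test_post_injection_timeout(self):
        sess = _session([("inj1", 100.0), ("np1", 200.0)])
        out = ofp.derive_intervals(sess, [EventOffset("TIMEOUT", "inj1", 40.0)])
        (iv,) = out.intervals_named("TIMEOUT")
        assert (iv.start, iv.end) == (100.0, 140.0)

    @pytest.mark.parametrize(
        "led2_off, expected",
        [(2400.0, "hled_on_from_led2"), (2390.0, "hled_on_from_dark")],
    )
    def test_guarded_switch_labels_by_prior_state(self, led2_off, expected):
        sess = _session([("led2_on", 2000.0), ("led2_off", led2_off), ("hled_on", 2400.0)])
        rules = [
            PairedOnOff("LED2_ON", "led2_on", "led2_off"),
            GuardedSwitch("hled_switch", "hled_on", "LED2_ON", "led2", "dark", 1.0),
        ]
        out = ofp.derive_intervals(sess, rules)
        derived = [e.name for e in out.events if e.name.startswith("hled_on_from")]
        assert derived == [expected]

    def test_set_ops_match_pointwise_boolean_oracle(self):
        rng = np.random.default_rng(7)
        spans_a = merge_spans([(s, s + d) for s, d in zip(rng.uniform(0, 90, 8), rng.uniform(1, 15, 8))])
        spans_b = merge_spans([(s, s + d) for s, d in zip(rng.uniform(0, 90, 8), rng.uniform(1, 15, 8))])

        def member(spans, t):
            return any(s <= t < e for s, e in spans)

        grid = np.arange(0.0, 110.0, 0.01)
        for got, want in [
            (union_spans(spans_a, spans_b), [member(spans_a, t) or member(spans_b, t) for t in grid]),
            (intersect_spans(spans_a, spans_b), [member(spans_a, t) and member(spans_b, t) for t in grid]),
            (diff_spans(spans_a, spans_b), [member(spans_a, t) and not member(spans_b, t) for t in grid]),
        ]:
            assert [member(got, t) for t in grid] == want

    def test_set_op_rule_over_named_intervals(self):
        sess = _session(
            [("led2_on", 0.0), ("led2_off", 10.0), ("inj1", 8.0)],
        )
        rules = [
            PairedOnOff("LED2_ON", "led2_on", "led2_off"),
            EventOffset("TIMEOUT", "inj1", 40.0),
            SetOp("AVAIL", "DIFF", ("LED2_ON", "TIMEOUT")),
            SetOp("EITHER", "OR", ("LED2_ON", "TIMEOUT")),
        ]
        out = ofp.derive_intervals(sess, rules)
        assert [(iv.start, iv.end) for iv in out.intervals_named("AVAIL")] == [(0.0, 8.0)]
        assert [(iv.start, iv.end) for iv in out.intervals_named("EITHER")] == [(0.0, 48.0)]

    def test_same_name_intervals_never_overlap(self):
        truth = ofp.simulate_behavior(ofp.SessionTemplate(seed=11, np1_rate_drug=0.05))
        cfg = ofp.load_config()
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as td:
            p = pathlib.Path(td) / "b.dat"
            ofp.write_imetronic(truth, p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sess = ofp.derive_intervals(ofp.parse_imetronic(p, cfg), cfg.behavior.intervals.values())
        for name in sess.interval_names():
            ivs = sorted(sess.intervals_named(name), key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_total_timeout_duration_is_40s_per_injection(self, cfg):
        import tempfile, pathlib

        truth = ofp.simulate_behavior(ofp.SessionTemplate(seed=5))
        with tempfile.TemporaryDirectory() as td:
            p = pathlib.Path(td) / "b.dat"
            ofp.write_imetronic(truth, p)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sess = ofp.derive_intervals(ofp.parse_imetronic(p, cfg), cfg.behavior.intervals.values())
        n_inj = len(truth.event_times("inj1"))
        assert n_inj > 0
        total = sum(iv.duration for iv in sess.intervals_named("TIMEOUT"))
        assert total == pytest.approx(40.0 * n_inj, abs=1e-9)


# --------------------------------------------------------------------------
# Event selection
# --------------------------------------------------------------------------


class TestSelectEvents:
    def test_all_without_interval_returns_parser_events(self):
        sess = _session([("np1", t) for t in (1.0, 2.0, 3.0)])
        assert list(ofp.select_events(sess, "np1")) == [1.0, 2.0, 3.0]

    def test_all_within_interval_filters(self):
        times = [1.0, 2.0, 11.0, 12.0, 21.0, 22.0, 31.0, 32.0, 41.0, 42.0]
        sess = _session(
            [("np1", t) for t in times],
            intervals=[("DRUG", 10.0, 15.0), ("DRUG", 40.0, 45.0)],
        )
        assert list(ofp.select_events(sess, "np1", within="DRUG")) == [11.0, 12.0, 41.0, 42.0]

    def test_first_in_interval_matches_brute_force(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0, 100, 40))
        ivs = [("DRUG", 10.0, 30.0), ("DRUG", 60.0, 80.0)]
        sess = _session([("np1", t) for t in times], intervals=ivs)
        got = list(ofp.select_events(sess, "np1", within="DRUG", selector="first_in_interval"))
        want = [min(t for t in times if s <= t < e) for _, s, e in ivs if any(s <= t < e for t in times)]
        assert got == sorted(want)
        assert len(got) == 2

    def test_ordinal_in_series_fixed_ratio(self):
        sess = _session([("np1", t) for t in (5.0, 6.0, 7.0, 8.0, 9.0)] + [("inj1", 11.0)])
        got = ofp.select_events(
            sess, "np1", selector="ordinal_in_series", k=1, series_size=5, reset_event="inj1"
        )
        assert list(got) == [5.0]

    def test_ordinal_k_beyond_series_size_fatal(self):
        sess = _session([("np1", 1.0)])
        with pytest.raises(ValueError):
            ofp.select_events(sess, "np1", selector="ordinal_in_series", k=6, series_size=5)

    def test_timeout_pokes_do_not_advance_series(self):
        events = [("np1", t) for t in (1.0, 2.0, 3.0, 4.0, 5.0)] + [("inj1", 7.0)]
        events += [("np1", 10.0), ("np1", 20.0)]  # inside the time-out
        events += [("np1", t) for t in (50.0, 51.0, 52.0, 53.0, 54.0)]
        sess = _session(events, intervals=[("TIMEOUT", 7.0, 47.0)])
        got = ofp.select_events(
            sess, "np1", selector="ordinal_in_series", k=1, series_size=5, reset_event="inj1"
        )
        assert list(got) == [1.0, 50.0]


# --------------------------------------------------------------------------
# Properties
# --------------------------------------------------------------------------


@given(
    st.lists(
        st.tuples(st.floats(0, 1000, allow_nan=False), st.floats(0.01, 50, allow_nan=False)),
        min_size=1,
        max_size=20,
    )
)
def test_merged_spans_are_sorted_and_disjoint(raw):
    spans = merge_spans([(s, s + d) for s, d in raw])
    assert all(e > s for s, e in spans)
    assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
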