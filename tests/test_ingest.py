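"""Ingest: parsing, deduplication, classification, network construction."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import driftnet as dn
from driftnet.ingest import drifter_flags

from conftest import reads_df

ANT = {"a1": "A", "a2": "A", "b1": "B"}


def make_log(lines):
    return io.StringIO("tag_id,antenna_id,timestamp\n" + "\n".join(lines))


class TestReadLog:
    def test_well_formed(self):
        log = dn.read_log(make_log(["t1,a1,0", "t1,a2,30", "t2,b1,5"]), ANT)
        assert len(log.reads) == 3
        assert log.n_skipped == 0
        assert log.reads["nest_id"].tolist() == ["A", "A", "B"]

    def test_unparseable_timestamp_skipped_and_reported(self):
        log = dn.read_log(make_log(["t1,a1,0", "t1,a1,oops", "t1,a1,90"]), ANT)
        assert len(log.reads) == 2
        assert log.n_skipped == 1
        assert log.skipped_lines == [3]

    def test_unknown_antenna_retained_but_flagged(self):
        log = dn.read_log(make_log(["t1,a1,0", "t1,zz,10"]), ANT)
        assert len(log.reads) == 2
        assert log.n_unresolved == 1
        assert (~log.reads["resolved"]).sum() == 1

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="antenna_id"):
            dn.read_log(io.StringIO("tag_id,timestamp\nt1,0\n"), ANT)

    def test_datetime_timestamps_accepted(self):
        log = dn.read_log(
            make_log(["t1,a1,2009-07-01 08:00:00", "t1,a1,2009-07-01 08:02:00"]), ANT
        )
        assert log.n_skipped == 0
        assert np.diff(log.reads["time"])[0] == pytest.approx(120.0)


class TestDeduplicate:
    def test_repeat_reads_within_window_merge(self):
        ev = dn.deduplicate(reads_df([("t", "A", 0.0), ("t", "A", 30.0), ("t", "A", 59.0)]))
        assert len(ev) == 1
        assert ev["time"].iloc[0] == 0.0  # event carries the first read's timestamp

    def test_window_boundary_splits(self):
        ev = dn.deduplicate(reads_df([("t", "A", 0.0), ("t", "A", 61.0)]))
        assert len(ev) == 2
        # gap measured to the retained event's start: exactly 60 s also splits
        ev = dn.deduplicate(reads_df([("t", "A", 0.0), ("t", "A", 60.0)]))
        assert len(ev) == 2

    def test_nest_change_always_splits(self):
        ev = dn.deduplicate(reads_df([("t", "A", 0.0), ("t", "B", 10.0)]))
        assert len(ev) == 2

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            dn.deduplicate(reads_df([("t", "A", 0.0)]), window=-1)

    @settings(max_examples=50, deadline=None)
    @given(
        times=st.lists(st.floats(0, 1000), min_size=1, max_size=30),
        nests=st.lists(st.sampled_from("AB"), min_size=30, max_size=30),
    )
    def test_idempotent_and_monotone_in_window(self, times, nests):
        rows = [("t", nests[i], t) for i, t in enumerate(sorted(times))]
        events = dn.deduplicate(reads_df(rows), window=60)
        again = dn.deduplicate(events.assign(resolved=True), window=60)
        pd.testing.assert_frame_equal(events, again)
        wider = dn.deduplicate(reads_df(rows), window=120)
        assert len(wider) <= len(events)


class TestClassify:
    def test_natal_vs_drift_labels(self):
        ev = reads_df([("w", "A", 0.0), ("w", "A", 100.0), ("w", "B", 200.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        assert lab["is_drift"].tolist() == [False, False, True]
        assert drifter_flags(lab)["w"]

    def test_home_only_wasp_is_not_a_drifter(self):
        ev = reads_df([("w", "A", 0.0), ("w", "A", 100.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        assert not lab["is_drift"].any()
        assert not drifter_flags(lab)["w"]

    def test_unknown_tag_flagged(self):
        ev = reads_df([("ghost", "A", 0.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        assert lab["unknown_origin"].iloc[0]


class TestBuildNetworks:
    CAL = dn.MonitoringCalendar(
        pd.DataFrame({"period_id": ["P1", "P2"], "start": [0.0, 1000.0], "end": [1000.0, 2000.0]})
    )

    def test_unique_wasps_vs_events(self):
        # one wasp from A visits B three times within one period
        ev = reads_df([("w", "B", 0.0), ("w", "B", 100.0), ("w", "B", 200.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        nets, pooled, _ = dn.build_networks(lab, self.CAL, nests=["A", "B"])
        assert nets[0].O[0, 1] == 1
        assert nets[0].W[0, 1] == 3

    def test_two_wasps_counted_separately(self):
        ev = reads_df([("w1", "B", 0.0), ("w1", "B", 100.0), ("w2", "B", 50.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w1": "A", "w2": "A"})
        _, pooled, _ = dn.build_networks(lab, self.CAL, nests=["A", "B"])
        assert pooled.O[0, 1] == 2
        assert pooled.W[0, 1] == 3

    def test_periods_partition_and_conserve(self):
        ev = reads_df([("w", "B", 500.0), ("w", "B", 1500.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        nets, pooled, n_outside = dn.build_networks(lab, self.CAL, nests=["A", "B"])
        assert n_outside == 0
        assert (nets[0].W + nets[1].W == pooled.W).all()

    def test_event_outside_periods_reported(self):
        ev = reads_df([("w", "B", 5000.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        _, pooled, n_outside = dn.build_networks(lab, self.CAL, nests=["A", "B"])
        assert n_outside == 1
        assert pooled.O.sum() == 0

    def test_no_drift_gives_zero_matrices(self):
        ev = reads_df([("w", "A", 0.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        nets, pooled, _ = dn.build_networks(lab, self.CAL, nests=["A", "B", "C"])
        assert pooled.O.sum() == 0 and pooled.R.sum() == 0
        assert pooled.n_nests == 3  # silent nests retained as isolated nodes

    def test_campaign_invariants(self, small_campaign):
        pooled = small_campaign["pooled"]
        labeled = small_campaign["labeled"]
        roster = small_campaign["sim"].roster
        # conservation: drift events in W + natal events = all classified events
        per_period = sum(net.W.sum() for net in small_campaign["networks"])
        assert per_period + (~labeled["is_drift"]).sum() == len(labeled)
        # O_ij bounded by the donor nest's wasp count
        homes = pd.Series(roster).value_counts()
        for i, nest in enumerate(pooled.nests):
            assert pooled.O[i].max() <= homes.get(nest, 0)
        assert (pooled.R == pooled.O.sum(axis=1)).all()


class TestSummarize:
    def test_all_natal(self):
        ev = reads_df([("w", "A", 0.0), ("w", "A", 100.0)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        s = dn.summarize(lab, {"w": "A"})
        assert s["drift_pct"] == 0.0
        assert s["return_fidelity"]["A"] == 1.0

    def test_empty(self):
        lab = dn.classify(reads_df([])[["tag_id", "nest_id", "time"]], {"w": "A"})
        s = dn.summarize(lab, {"w": "A"})
        assert s["n_records"] == 0 and s["drift_pct"] == 0.0

    def test_recovers_generated_drift_fraction(self):
        """Drift share of a 10k-event log stays inside the binomial 99% CI."""
        target = 0.2
        rng = np.random.default_rng(5)
        n = 10_000
        drift = rng.random(n) < target
        ev = reads_df([("w", "B" if d else "A", 200.0 * i) for i, d in enumerate(drift)])
        lab = dn.classify(ev[["tag_id", "nest_id", "time"]], {"w": "A"})
        s = dn.summarize(lab, {"w": "A", "x": "B"})
        assert s["drift_pct"] / 100 == pytest.approx(drift.mean())
        half = 2.576 * np.sqrt(target * (1 - target) / n)
        assert abs(s["drift_pct"] / 100 - target) < half


class TestDetectionRate:
    @pytest.mark.parametrize(
        "coverage,passes,expected",
        [(0.80, 2, 0.96), (1.0, 1, 1.0), (0.5, 3, 0.875)],
    )
    def test_values(self, coverage, passes, expected):
        assert dn.detection_rate(coverage, passes) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dn.detection_rate(1.2, 2)
        with pytest.raises(ValueError):
            dn.detection_rate(0.5, 0)
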