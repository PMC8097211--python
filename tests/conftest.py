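import io

import numpy as np
import pandas as pd
import pytest

import driftnet as dn


@pytest.fixture
def line3_X():
    """Three nests on a line at 0, 1, 2 metres."""
    return np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])


@pytest.fixture(scope="session")
def small_campaign():
    """A small but complete synthetic RFID campaign, run through ingest."""
    cfg = dn.GeneratorConfig(
        seed=11, n_buildings=2, nests_per_building=6, mean_group_size=10,
        n_periods=3, days_per_period=3, events_per_wasp_day=2,
    )
    frame = dn.generate_layout(cfg)
    sim = dn.generate_event_log(frame, cfg)
    log = dn.read_log(io.StringIO(sim.reads.to_csv(index=False)), sim.antenna_map)
    events = dn.deduplicate(log.reads)
    labeled = dn.classify(events, sim.roster)
    networks, pooled, n_outside = dn.build_networks(labeled, sim.calendar, nests=frame.nest_ids)
    return {
        "cfg": cfg, "frame": frame, "sim": sim, "log": log, "events": events,
        "labeled": labeled, "networks": networks, "pooled": pooled, "n_outside": n_outside,
    }


def reads_df(rows):
    """Helper: raw-read DataFrame from (tag, nest, time) tuples."""
    return pd.DataFrame(rows, columns=["tag_id", "nest_id", "time"]).assign(resolved=True)
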