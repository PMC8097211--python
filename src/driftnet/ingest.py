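"""RFID log ingestion: parsing, deduplication, drift classification, networks.

A raw RFID log is a delimited text file of (tag id, antenna id, timestamp)
records.  Antennae map many-to-one onto nests; repeat registrations of a tag
at one nest within a short window are a single visit event.  A wasp's natal
("home") nest is the nest on which it was tagged; any visit event at a
different nest is a *drift* from the home (donor) nest to the visited
(recipient) nest.  Per monitoring period these drifts aggregate into a
directed nest-by-nest network with two weights per dyad:

* ``O[i, j]`` — the number of distinct wasps with home ``i`` seen at ``j``;
* ``W[i, j]`` — the total number of drift events from ``i``-homed wasps at
  ``j``.

The out-strength ``R[i] = sum_j O[i, j]`` is the quantity the diffusive null
model of :mod:`driftnet.heterogeneity` conserves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReadLog",
    "MonitoringCalendar",
    "DriftNetwork",
    "read_log",
    "deduplicate",
    "classify",
    "build_networks",
    "summarize",
    "detection_rate",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ReadLog:
    """Parsed raw reads plus a parse report.

    ``reads`` has columns ``tag_id``, ``antenna_id``, ``nest_id``, ``time``
    (seconds), ``resolved`` (antenna found in the antenna->nest map), sorted
    by tag then time.  Malformed lines are skipped and counted, unresolved
    antennae are retained but flagged — neither is silently dropped.
    """

    reads: pd.DataFrame
    n_skipped: int = 0
    skipped_lines: list = field(default_factory=list)
    n_unresolved: int = 0


@dataclass
class MonitoringCalendar:
    """Named monitoring periods as half-open intervals [start, end) seconds."""

    periods: pd.DataFrame  # columns period_id, start, end

    def __post_init__(self):
        p = self.periods
        required = {"period_id", "start", "end"}
        if not required.issubset(p.columns):
            raise ValueError(f"calendar needs columns {sorted(required)}")
        if (p["end"] <= p["start"]).any():
            raise ValueError("calendar periods must have end > start")

    @property
    def period_ids(self) -> list:
        return list(self.periods["period_id"])

    def assign(self, times: np.ndarray) -> np.ndarray:
        """Period id per time; None for times outside every period.

        Boundary reads go to the earlier period (intervals are [start, end)).
        """
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, None, dtype=object)
        for row in self.periods.itertuples(index=False):
            mask = (times >= row.start) & (times < row.end)
            out[mask] = row.period_id
        return out

    @classmethod
    def from_csv(cls, path) -> "MonitoringCalendar":
        df = pd.read_csv(path)
        df["start"] = _to_seconds(df["start"])
        df["end"] = _to_seconds(df["end"])
        return cls(df)


@dataclass
class DriftNetwork:
    """Directed drift network for one monitoring period.

    ``O`` counts unique drifting wasps per ordered dyad, ``W`` counts drift
    events; diagonals are zero.  ``R`` (row sums of ``O``) is the per-nest
    drifter out-strength.
    """

    period_id: str
    nests: list
    O: np.ndarray
    W: np.ndarray

    def __post_init__(self):
        self.O = np.asarray(self.O)
        self.W = np.asarray(self.W)
        n = len(self.nests)
        if self.O.shape != (n, n) or self.W.shape != (n, n):
            raise ValueError("O and W must be N x N for N nests")
        if (self.O < 0).any() or (self.W < 0).any():
            raise ValueError("drift counts must be non-negative")
        if np.diag(self.O).any() or np.diag(self.W).any():
            raise ValueError("diagonal of O and W must be zero")
        if ((self.W < self.O) & (self.O > 0)).any():
            raise ValueError("W_ij must be >= O_ij wherever O_ij > 0")

    @property
    def R(self) -> np.ndarray:
        return self.O.sum(axis=1)

    @property
    def n_nests(self) -> int:
        return len(self.nests)

    def to_edge_list(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.O)
        return pd.DataFrame(
            {
                "donor": [self.nests[i] for i in src],
                "recipient": [self.nests[j] for j in dst],
                "unique_wasps": self.O[src, dst],
                "events": self.W[src, dst],
                "period": self.period_id,
            }
        )


# ---------------------------------------------------------------------------
# parsing


def _to_seconds(col: pd.Series) -> pd.Series:
    """Interpret a timestamp column as absolute seconds.

    Numeric values pass through; anything else is parsed as a datetime and
    converted to POSIX seconds.
    """
    num = pd.to_numeric(col, errors="coerce")
    if num.notna().all():
        return num.astype(float)
    dt = pd.to_datetime(col, errors="coerce", format="mixed")
    sec = dt.astype("int64", errors="ignore")
    out = num.copy().astype(float)
    mask = num.isna() & dt.notna()
    out[mask] = dt[mask].astype("int64") / 1e9
    return out


def read_log(
    path,
    antenna_map: dict,
    *,
    tag_col: str = "tag_id",
    antenna_col: str = "antenna_id",
    time_col: str = "timestamp",
    sep: str = ",",
) -> ReadLog:
    """Parse a delimited RFID read log.

    Parameters
    ----------
    path : path or file-like
        Delimited text with a header naming the tag, antenna and timestamp
        columns (names configurable).
    antenna_map : dict
        antenna_id -> nest_id (many antennae per nest).

    Raises
    ------
    ValueError
        If a required column is missing from the header.
    """
    df = pd.read_csv(path, sep=sep, dtype={tag_col: str, antenna_col: str}, skipinitialspace=True)
    for col in (tag_col, antenna_col, time_col):
        if col not in df.columns:
            raise ValueError(f"read log is missing required column {col!r}")

    times = _to_seconds(df[time_col])
    bad = ~np.isfinite(times.to_numpy(dtype=float, na_value=np.nan))
    skipped = [int(i) + 2 for i in np.nonzero(bad)[0]]  # 1-based + header line
    if skipped:
        logger.warning("skipped %d malformed line(s): %s", len(skipped), skipped)

    reads = pd.DataFrame(
        {
            "tag_id": df[tag_col].astype(str),
            "antenna_id": df[antenna_col].astype(str),
            "time": times,
        }
    )[~bad].copy()
    reads["nest_id"] = reads["antenna_id"].map(antenna_map)
    reads["resolved"] = reads["nest_id"].notna()
    n_unresolved = int((~reads["resolved"]).sum())
    if n_unresolved:
        logger.warning("%d read(s) from antennae absent from the antenna map", n_unresolved)
    reads = reads.sort_values(["tag_id", "time"], kind="stable").reset_index(drop=True)
    return ReadLog(reads=reads, n_skipped=len(skipped), skipped_lines=skipped, n_unresolved=n_unresolved)


def deduplicate(reads: pd.DataFrame, window: float = 60.0) -> pd.DataFrame:
    """Collapse repeat registrations into visit events.

    Within each tag, a read starts a new event when (a) its nest differs from
    the previous retained event's nest, or (b) it is at least ``window``
    seconds after the previous retained event's (first-read) timestamp.  The
    gap is measured to the retained event's start, not to the preceding raw
    read, so the rule is idempotent.  Unresolved reads (no nest) are dropped
    here; they were already counted by :func:`read_log`.

    Returns a DataFrame of events with columns ``tag_id``, ``nest_id``,
    ``time``.
    """
    if window < 0:
        raise ValueError("dedup window must be non-negative")
    if "resolved" in reads.columns:
        reads = reads[reads["resolved"]]
    reads = reads.sort_values(["tag_id", "time"], kind="stable")

    keep_rows = []
    for _, grp in reads.groupby("tag_id", sort=False):
        last_nest = None
        last_time = -np.inf
        for row in grp.itertuples():
            if row.nest_id != last_nest or (row.time - last_time) >= window:
                keep_rows.append(row.Index)
                last_nest = row.nest_id
                last_time = row.time
    events = reads.loc[keep_rows, ["tag_id", "nest_id", "time"]].reset_index(drop=True)
    return events


def classify(events: pd.DataFrame, roster: dict) -> pd.DataFrame:
    """Label events natal vs drift against the tagging roster.

    ``roster`` maps tag_id -> home_nest_id (the nest on which the wasp was
    tagged).  Events from tags absent from the roster are flagged
    ``unknown_origin`` and excluded from drift classification.  Adds columns
    ``home_nest``, ``is_drift``, ``unknown_origin``.
    """
    events = events.copy()
    events["home_nest"] = events["tag_id"].map(roster)
    events["unknown_origin"] = events["home_nest"].isna()
    n_unknown = int(events["unknown_origin"].sum())
    if n_unknown:
        logger.warning("%d event(s) from tags with no roster entry", n_unknown)
    events["is_drift"] = (~events["unknown_origin"]) & (events["nest_id"] != events["home_nest"])
    return events


def drifter_flags(labeled: pd.DataFrame) -> pd.Series:
    """Per-wasp drifter flag: True if the wasp has at least one drift event."""
    known = labeled[~labeled["unknown_origin"]]
    return known.groupby("tag_id")["is_drift"].any()


def build_networks(
    labeled: pd.DataFrame,
    calendar: MonitoringCalendar,
    nests: list | None = None,
) -> tuple[list[DriftNetwork], DriftNetwork, int]:
    """Per-period drift networks plus the pooled network.

    Nests with zero activity are retained as isolated nodes when a full nest
    list is supplied; otherwise the node set is the union of home and visited
    nests.  Returns ``(per_period, pooled, n_outside)`` where ``n_outside``
    counts events falling outside every calendar period (excluded, reported).
    """
    known = labeled[~labeled["unknown_origin"]].copy()
    if nests is None:
        nests = sorted(set(known["nest_id"]) | set(known["home_nest"]))
    index = {nest: i for i, nest in enumerate(nests)}
    n = len(nests)

    known["period_id"] = calendar.assign(known["time"].to_numpy())
    n_outside = int(known["period_id"].isna().sum())
    if n_outside:
        logger.warning("%d event(s) outside every monitoring period; excluded", n_outside)
    known = known[known["period_id"].notna()]

    networks = []
    for pid in calendar.period_ids:
        sub = known[(known["period_id"] == pid) & known["is_drift"]]
        O = np.zeros((n, n), dtype=int)
        W = np.zeros((n, n), dtype=int)
        if len(sub):
            pairs = sub.groupby(["home_nest", "nest_id"])
            for (i_nest, j_nest), grp in pairs:
                i, j = index[i_nest], index[j_nest]
                O[i, j] = grp["tag_id"].nunique()
                W[i, j] = len(grp)
        networks.append(DriftNetwork(period_id=pid, nests=list(nests), O=O, W=W))

    drifts = known[known["is_drift"]]
    O = np.zeros((n, n), dtype=int)
    W = np.zeros((n, n), dtype=int)
    if len(drifts):
        for (i_nest, j_nest), grp in drifts.groupby(["home_nest", "nest_id"]):
            i, j = index[i_nest], index[j_nest]
            O[i, j] = grp["tag_id"].nunique()
            W[i, j] = len(grp)
    pooled = DriftNetwork(period_id="pooled", nests=list(nests), O=O, W=W)
    return networks, pooled, n_outside


def summarize(labeled: pd.DataFrame, roster: dict) -> dict:
    """Descriptive drift summary.

    Returns totals, the drift percentage, the fraction of wasps that drifted,
    the fractions of nests acting as donors / recipients, per-nest return
    fidelity (fraction of a nest's own wasps' events that are natal) and its
    median across nests.
    """
    known = labeled[~labeled["unknown_origin"]]
    total = len(known)
    if total == 0:
        logger.warning("empty event set; summary is all zeros")
        return {
            "n_records": 0,
            "n_drift": 0,
            "drift_pct": 0.0,
            "pct_drifters": 0.0,
            "pct_donor_nests": 0.0,
            "pct_recipient_nests": 0.0,
            "return_fidelity": {},
            "median_return_fidelity": float("nan"),
        }
    n_drift = int(known["is_drift"].sum())
    flags = drifter_flags(labeled)

    nests = sorted(set(roster.values()))
    fidelity = {}
    for nest in nests:
        own = known[known["home_nest"] == nest]
        if len(own):
            fidelity[nest] = float((~own["is_drift"]).mean())
    donors = {r.home_nest for r in known[known["is_drift"]].itertuples()}
    recipients = {r.nest_id for r in known[known["is_drift"]].itertuples()}

    return {
        "n_records": total,
        "n_drift": n_drift,
        "drift_pct": 100.0 * n_drift / total,
        "pct_drifters": 100.0 * float(flags.mean()) if len(flags) else 0.0,
        "pct_donor_nests": 100.0 * len(donors) / len(nests) if nests else 0.0,
        "pct_recipient_nests": 100.0 * len(recipients) / len(nests) if nests else 0.0,
        "return_fidelity": fidelity,
        "median_return_fidelity": float(np.median(list(fidelity.values()))) if fidelity else float("nan"),
    }


def detection_rate(coverage: float, passes: int = 2) -> float:
    """Probability a wasp is detected at least once over ``passes`` passes.

    With a fraction ``coverage`` of the nest front inside the detection zone
    and independent passes (entry and exit give ``passes = 2``), the detection
    rate is ``1 - (1 - coverage) ** passes``; an 80% zone read on both entry
    and exit detects 96% of transits.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be a probability in [0, 1]")
    if passes < 1:
        raise ValueError("passes must be >= 1")
    return 1.0 - (1.0 - coverage) ** passes
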