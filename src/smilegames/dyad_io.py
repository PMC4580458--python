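"""Read, write and bin dyadic smile/gaze event data.

Raw observations are timestamped onset/offset events per actor and
behavior.  Analysis operates on fixed-width binary time series
(:class:`SmileSeries`) and on gaze-gated :class:`Episode` segments —
maximal runs of bins in which the infant is looking at the mother, so
that the partner's smiles are actually visible to the agent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTORS = ("infant", "mother", "adult", "robot")
BEHAVIORS = ("smile", "gaze_at_partner")

EVENT_COLUMNS = ["dyad_id", "session_id", "actor", "behavior", "onset_s", "offset_s"]


@dataclass(frozen=True)
class EventRecord:
    """One timestamped behavior event (e.g. a smile from onset to offset)."""

    dyad_id: str
    session_id: str
    actor: str
    behavior: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.actor not in ACTORS:
            raise ValueError(f"unknown actor {self.actor!r}; expected one of {ACTORS}")
        if self.behavior not in BEHAVIORS:
            raise ValueError(
                f"unknown behavior {self.behavior!r}; expected one of {BEHAVIORS}"
            )
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )


@dataclass
class SmileSeries:
    """Binned binary smile and gaze channels for one dyad session."""

    dyad_id: str
    session_id: str
    infant_smile: np.ndarray
    mother_smile: np.ndarray
    gaze: np.ndarray
    bin_width_s: float = 1.0

    def __post_init__(self) -> None:
        self.infant_smile = np.asarray(self.infant_smile, dtype=np.int8)
        self.mother_smile = np.asarray(self.mother_smile, dtype=np.int8)
        self.gaze = np.asarray(self.gaze, dtype=np.int8)
        n = len(self.infant_smile)
        if n < 1:
            raise ValueError("series must contain at least one bin")
        if len(self.mother_smile) != n or len(self.gaze) != n:
            raise ValueError("all channels must have equal length")
        for name in ("infant_smile", "mother_smile", "gaze"):
            v = getattr(self, name)
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.infant_smile)


@dataclass
class Episode:
    """A gaze-gated segment with channels relabeled by agent role.

    ``agent_smile`` is the channel of the partner whose goal is being
    analyzed; ``partner_smile`` is the plant being controlled.  Bins are
    0-based and half-open: the episode covers ``[start_bin, end_bin)`` of
    the source series.  Elapsed-time (tau) context resets at episode
    starts.
    """

    start_bin: int
    end_bin: int
    agent_smile: np.ndarray = field(repr=False)
    partner_smile: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.end_bin > self.start_bin:
            raise ValueError("end_bin must exceed start_bin")
        self.agent_smile = np.asarray(self.agent_smile, dtype=np.int8)
        self.partner_smile = np.asarray(self.partner_smile, dtype=np.int8)
        n = self.end_bin - self.start_bin
        if len(self.agent_smile) != n or len(self.partner_smile) != n:
            raise ValueError("episode channel length must equal end_bin - start_bin")

    def __len__(self) -> int:
        return self.end_bin - self.start_bin


def read_event_csv(path) -> list[EventRecord]:
    """Read an event table (dyad_id, session_id, actor, behavior, onset_s, offset_s).

    Rows are returned sorted by (dyad_id, session_id, onset_s).  Raises
    ``ValueError`` naming the offending line for malformed rows, invalid
    onset/offset pairs, or overlapping same-actor same-behavior events
    within a session.
    """
    df = pd.read_csv(path, dtype={"dyad_id": str, "session_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: list[EventRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            rec = EventRecord(
                dyad_id=str(row["dyad_id"]),
                session_id=str(row["session_id"]),
                actor=str(row["actor"]),
                behavior=str(row["behavior"]),
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        records.append(rec)
    records.sort(key=lambda r: (r.dyad_id, r.session_id, r.onset_s, r.offset_s))
    _check_no_overlap(records)
    return records


def _check_no_overlap(records: list[EventRecord]) -> None:
    last_end: dict[tuple, float] = {}
    for rec in records:
        key = (rec.dyad_id, rec.session_id, rec.actor, rec.behavior)
        if key in last_end and rec.onset_s < last_end[key]:
            raise ValueError(
                f"overlapping {rec.actor}/{rec.behavior} events in session "
                f"{rec.dyad_id}/{rec.session_id} at onset {rec.onset_s}"
            )
        last_end[key] = max(last_end.get(key, 0.0), rec.offset_s)


def write_event_csv(records: list[EventRecord], path) -> None:
    """Write events in the same column layout :func:`read_event_csv` expects."""
    df = pd.DataFrame(
        [
            {
                "dyad_id": r.dyad_id,
                "session_id": r.session_id,
                "actor": r.actor,
                "behavior": r.behavior,
                "onset_s": r.onset_s,
                "offset_s": r.offset_s,
            }
            for r in records
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False)


def bin_events(
    events: list[EventRecord],
    bin_width_s: float = 1.0,
    duration_s: float | None = None,
    coverage_threshold: float = 0.5,
) -> SmileSeries:
    """Bin one session's events into a binary :class:`SmileSeries`.

    A bin is 1 for a channel iff the behavior covers at least
    ``coverage_threshold`` of the bin interval ``[t*w, (t+1)*w)``.
    Events extending past ``duration_s`` are clipped with a warning.
    All events must belong to a single (dyad, session).
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    if not events:
        raise ValueError("cannot bin an empty event list")
    keys = {(e.dyad_id, e.session_id) for e in events}
    if len(keys) > 1:
        raise ValueError(f"events span multiple sessions: {sorted(keys)}")
    dyad_id, session_id = next(iter(keys))
    if duration_s is None:
        duration_s = max(e.offset_s for e in events)
    n = math.ceil(duration_s / bin_width_s)
    if n < 1:
        raise ValueError("duration_s must cover at least one bin")

    channels = {
        ("infant", "smile"): np.zeros(n),
        ("mother", "smile"): np.zeros(n),
        ("adult", "smile"): np.zeros(n),
        ("robot", "smile"): np.zeros(n),
        ("infant", "gaze_at_partner"): np.zeros(n),
    }
    for e in events:
        cov = channels.get((e.actor, e.behavior))
        if cov is None:
            continue
        onset, offset = e.onset_s, e.offset_s
        if offset > duration_s:
            logger.warning(
                "event %s/%s %s ends at %.2f s, clipped to duration %.2f s",
                e.actor,
                e.behavior,
                session_id,
                offset,
                duration_s,
            )
            offset = duration_s
        lo = int(onset // bin_width_s)
        hi = min(n - 1, int(np.nextafter(offset / bin_width_s, 0)))
        for t in range(lo, hi + 1):
            left = t * bin_width_s
            right = left + bin_width_s
            cov[t] += max(0.0, min(offset, right) - max(onset, left))

    def binarize(cov: np.ndarray) -> np.ndarray:
        return (cov / bin_width_s >= coverage_threshold).astype(np.int8)

    infant = binarize(channels[("infant", "smile")])
    # human-robot sessions store the human under "adult" and the machine
    # under "robot"; map them onto the agent/partner channel pair
    mother = binarize(
        channels[("mother", "smile")]
        + channels[("adult", "smile")]
        + channels[("robot", "smile")]
    )
    gaze = binarize(channels[("infant", "gaze_at_partner")])
    return SmileSeries(
        dyad_id=dyad_id,
        session_id=session_id,
        infant_smile=infant,
        mother_smile=mother,
        gaze=gaze,
        bin_width_s=bin_width_s,
    )


def extract_episodes(
    series: SmileSeries,
    agent: str = "infant",
    min_len_bins: int = 2,
    require_gaze: bool = True,
) -> list[Episode]:
    """Extract gaze-gated episodes, relabeling channels by agent role.

    Episodes are maximal runs of ``gaze == 1`` with length at least
    ``min_len_bins``.  ``agent="infant"`` puts the infant channel in
    ``agent_smile``; ``agent="mother"`` swaps the roles.  Setting
    ``require_gaze=False`` (defensible for the mother, who sees the
    infant's face throughout) returns the whole series as one episode.
    """
    if min_len_bins < 1:
        raise ValueError("min_len_bins must be >= 1")
    if agent not in ("infant", "mother"):
        raise ValueError(f"agent must be 'infant' or 'mother', got {agent!r}")
    if agent == "infant":
        agent_ch, partner_ch = series.infant_smile, series.mother_smile
    else:
        agent_ch, partner_ch = series.mother_smile, series.infant_smile

    if not require_gaze:
        if series.n_bins < min_len_bins:
            return []
        return [Episode(0, series.n_bins, agent_ch.copy(), partner_ch.copy())]

    gaze = series.gaze
    episodes: list[Episode] = []
    padded = np.concatenate([[0], gaze, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len_bins:
            episodes.append(Episode(int(s), int(e), agent_ch[s:e], partner_ch[s:e]))
    return episodes


def series_to_events(series: SmileSeries) -> list[EventRecord]:
    """Convert a binned series back to onset/offset events (runs of 1s)."""
    w = series.bin_width_s
    out: list[EventRecord] = []
    spec = [
        ("infant", "smile", series.infant_smile),
        ("mother", "smile", series.mother_smile),
        ("infant", "gaze_at_partner", series.gaze),
    ]
    for actor, behavior, channel in spec:
        padded = np.concatenate([[0], channel, [0]])
        diff = np.diff(padded)
        for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
            out.append(
                EventRecord(
                    dyad_id=series.dyad_id,
                    session_id=series.session_id,
                    actor=actor,
                    behavior=behavior,
                    onset_s=float(s) * w,
                    offset_s=float(e) * w,
                )
            )
    out.sort(key=lambda r: (r.dyad_id, r.session_id, r.onset_s, r.offset_s))
    return out


def write_series_csv(series: SmileSeries, path) -> None:
    """Write a binned series as CSV (bin, infant_smile, mother_smile, gaze)."""
    df = pd.DataFrame(
        {
            "bin": np.arange(series.n_bins),
            "infant_smile": series.infant_smile,
            "mother_smile": series.mother_smile,
            "gaze": series.gaze,
        }
    )
    df.to_csv(path, index=False)


def read_series_csv(
    path, dyad_id: str = "", session_id: str = "", bin_width_s: float = 1.0
) -> SmileSeries:
    """Read a binned series written by :func:`write_series_csv`."""
    df = pd.read_csv(path)
    for col in ("bin", "infant_smile", "mother_smile", "gaze"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.sort_values("bin")
    return SmileSeries(
        dyad_id=dyad_id,
        session_id=session_id,
        infant_smile=df["infant_smile"].to_numpy(),
        mother_smile=df["mother_smile"].to_numpy(),
        gaze=df["gaze"].to_numpy(),
        bin_width_s=bin_width_s,
    )
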