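"""Donor/acceptor trace processing: FRET efficiency, two-state idealization,
and binding-event extraction.

A trace is a uniformly sampled pair of donor and acceptor intensities for one
immobilized target molecule.  High FRET marks the bound state (donor on the
guide, acceptor on the target; proximity on seed pairing).  Idealization is a
deliberately simple hysteresis threshold — no HMM, no change-point — because
the downstream estimators only need dwell times and first-arrival times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FretTrace",
    "BindingEvent",
    "BindingEventSet",
    "compute_fret",
    "idealize_trace",
    "extract_events",
    "traces_to_frame",
    "events_to_frame",
    "first_arrivals_to_frame",
]


@dataclass
class FretTrace:
    """One molecule's donor/acceptor time trace on a uniform frame grid.

    ``efficiency`` is filled by :func:`compute_fret`; ``true_state`` is the
    simulator's per-frame ground truth (1 = bound) when available.
    """

    molecule_id: str
    time: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    efficiency: Optional[np.ndarray] = None
    true_state: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        n = self.time.size
        if self.donor.size != n or self.acceptor.size != n:
            raise ValueError("time, donor and acceptor must have equal length")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")

    @property
    def frame_interval(self) -> float:
        if self.time.size < 2:
            raise ValueError("trace too short to define a frame interval")
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class BindingEvent:
    """A contiguous bound interval on one molecule.

    ``left_censored``: the event was already in progress at the start of the
    observation window; ``right_censored``: the trace ended (or signal was
    lost) while still bound.  Censored dwells underestimate the true dwell.
    """

    molecule_id: str
    start_time: float
    end_time: float
    left_censored: bool = False
    right_censored: bool = False

    @property
    def dwell(self) -> float:
        return self.end_time - self.start_time

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("end_time must exceed start_time")


@dataclass
class BindingEventSet:
    """All binding events plus per-molecule first-arrival times.

    ``first_arrivals`` maps molecule id to the time from flow start to the
    start of that molecule's first binding event.  Molecules that never bound
    are counted in ``n_molecules_observed`` but have no first arrival — they
    are the censored tail of the arrival-time distribution.
    """

    events: list[BindingEvent]
    first_arrivals: dict[str, float]
    frame_interval: float
    n_molecules_observed: int

    def dwells(self, include_right_censored: bool = False) -> np.ndarray:
        """Dwell times in seconds; right-censored events excluded by default."""
        out = [
            e.dwell
            for e in self.events
            if not e.left_censored
            and (include_right_censored or not e.right_censored)
        ]
        return np.asarray(out, dtype=float)

    def dwell_observations(self) -> tuple[np.ndarray, np.ndarray]:
        """Dwells plus right-censor flags, for survival-aware fitting.

        Left-censored events are dropped (their start, hence dwell, is
        unknown); right-censored dwells are lower bounds and are flagged.
        """
        kept = [e for e in self.events if not e.left_censored]
        d = np.asarray([e.dwell for e in kept], dtype=float)
        c = np.asarray([e.right_censored for e in kept], dtype=bool)
        return d, c

    @property
    def n_events(self) -> int:
        return len(self.events)

    def merge(self, other: "BindingEventSet") -> "BindingEventSet":
        if not np.isclose(self.frame_interval, other.frame_interval):
            raise ValueError("cannot merge event sets with different frame intervals")
        fa = dict(self.first_arrivals)
        overlap = fa.keys() & other.first_arrivals.keys()
        if overlap:
            raise ValueError(f"duplicate molecule ids: {sorted(overlap)[:3]}")
        fa.update(other.first_arrivals)
        return BindingEventSet(
            events=self.events + other.events,
            first_arrivals=fa,
            frame_interval=self.frame_interval,
            n_molecules_observed=self.n_molecules_observed + other.n_molecules_observed,
        )


def compute_fret(
    trace: FretTrace,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
) -> FretTrace:
    """Fill in FRET efficiency as the background-corrected proximity ratio.

    E = max(0, A - bgA) / (max(0, D - bgD) + max(0, A - bgA)).  Frames where
    the corrected total is zero carry NaN (signal lost / both dyes dark).
    """
    if background_donor < 0 or background_acceptor < 0:
        raise ValueError("backgrounds must be non-negative")
    d = np.clip(trace.donor - background_donor, 0.0, None)
    a = np.clip(trace.acceptor - background_acceptor, 0.0, None)
    total = d + a
    eff = np.full(trace.n_frames, np.nan)
    ok = total > 0
    eff[ok] = a[ok] / total[ok]
    return replace(trace, efficiency=eff)


def _merge_short_runs(states: np.ndarray, min_frames: int) -> np.ndarray:
    """Absorb runs shorter than ``min_frames`` into the surrounding state.

    Runs are resolved shortest-first (ties: earliest first) so the result is
    deterministic; runs touching either trace end are kept, since their true
    extent is unknown.
    """
    s = states.copy()
    while True:
        # run-length encode
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [s.size]))
        lengths = ends - starts
        interior = (starts > 0) & (ends < s.size)
        short = interior & (lengths < min_frames)
        if not short.any():
            return s
        idx = np.flatnonzero(short)
        k = idx[np.lexsort((starts[idx], lengths[idx]))][0]
        s[starts[k] : ends[k]] = s[starts[k] - 1]


def idealize_trace(
    trace: FretTrace,
    threshold_high: float = 0.6,
    threshold_low: float = 0.4,
    min_frames: int = 2,
) -> np.ndarray:
    """Idealize a FRET trace into a per-frame 0/1 (unbound/bound) sequence.

    Hysteresis thresholding: enter the bound state when efficiency rises to
    ``threshold_high`` or above, leave it when efficiency falls below
    ``threshold_low``.  Afterwards any run shorter than ``min_frames`` frames
    (in either state) is merged into its surroundings, suppressing
    single-frame noise excursions.  NaN efficiencies keep the previous state.
    """
    if trace.efficiency is None:
        raise ValueError("trace has no efficiency; run compute_fret first")
    if threshold_low > threshold_high:
        raise ValueError("threshold_low must not exceed threshold_high")
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    if trace.n_frames < 2:
        raise ValueError("trace must have at least 2 frames")

    eff = trace.efficiency
    states = np.zeros(trace.n_frames, dtype=np.int8)
    state = 1 if eff[0] >= threshold_high else 0
    for i, e in enumerate(eff):
        if np.isnan(e):
            pass  # hold state through dropped frames
        elif state == 0 and e >= threshold_high:
            state = 1
        elif state == 1 and e < threshold_low:
            state = 0
        states[i] = state
    if min_frames > 1:
        states = _merge_short_runs(states, min_frames)
    return states


def extract_events(
    states: Sequence[int] | np.ndarray,
    time: Sequence[float] | np.ndarray,
    flow_start: float = 0.0,
    molecule_id: str = "mol",
) -> BindingEventSet:
    """Turn a per-frame state sequence into binding events and a first arrival.

    Each contiguous bound run becomes one event with dwell = run length x
    frame interval.  An event touching the last frame is right-censored; one
    touching the first frame is left-censored.  The first arrival is the start
    of the first event at or after ``flow_start``, measured from flow start.
    """
    states = np.asarray(states, dtype=int)
    time = np.asarray(time, dtype=float)
    if states.size != time.size:
        raise ValueError("states and time must have equal length")
    if states.size < 2:
        raise ValueError("need at least 2 frames")
    if not (time[0] <= flow_start <= time[-1]):
        raise ValueError(
            f"flow_start {flow_start} outside trace span [{time[0]}, {time[-1]}]"
        )
    dt = float(time[1] - time[0])

    padded = np.concatenate(([0], states, [0]))
    rises = np.flatnonzero(np.diff(padded) == 1)   # run start indices
    falls = np.flatnonzero(np.diff(padded) == -1)  # one past run end

    events: list[BindingEvent] = []
    for i0, i1 in zip(rises, falls):
        start = time[i0]
        end = time[i1 - 1] + dt  # dwell = run length * frame interval
        events.append(
            BindingEvent(
                molecule_id=molecule_id,
                start_time=start,
                end_time=end,
                left_censored=(i0 == 0),
                right_censored=(i1 == states.size),
            )
        )

    first_arrivals: dict[str, float] = {}
    for e in events:
        if not e.left_censored and e.start_time >= flow_start:
            first_arrivals[molecule_id] = e.start_time - flow_start
            break

    return BindingEventSet(
        events=events,
        first_arrivals=first_arrivals,
        frame_interval=dt,
        n_molecules_observed=1,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def traces_to_frame(traces: Sequence[FretTrace]) -> pd.DataFrame:
    """Long-format table: molecule_id, time_s, donor, acceptor[, true_state]."""
    parts = []
    for t in traces:
        d = {"molecule_id": t.molecule_id, "time_s": t.time,
             "donor": t.donor, "acceptor": t.acceptor}
        if t.true_state is not None:
            d["true_state"] = t.true_state
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[FretTrace]:
    out = []
    for mid, g in df.groupby("molecule_id", sort=True):
        out.append(
            FretTrace(
                molecule_id=str(mid),
                time=g["time_s"].to_numpy(),
                donor=g["donor"].to_numpy(),
                acceptor=g["acceptor"].to_numpy(),
                true_state=g["true_state"].to_numpy(dtype=int)
                if "true_state" in g
                else None,
            )
        )
    return out


def events_to_frame(event_set: BindingEventSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in event_set.events],
            "start_s": [e.start_time for e in event_set.events],
            "end_s": [e.end_time for e in event_set.events],
            "dwell_s": [e.dwell for e in event_set.events],
            "left_censored": [e.left_censored for e in event_set.events],
            "right_censored": [e.right_censored for e in event_set.events],
        }
    )


def first_arrivals_to_frame(event_set: BindingEventSet) -> pd.DataFrame:
    items = sorted(event_set.first_arrivals.items())
    return pd.DataFrame(
        {
            "molecule_id": [k for k, _ in items],
            "first_arrival_s": [v for _, v in items],
        }
    )
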