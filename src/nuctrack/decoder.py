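"""Decoding nuclear-translocation (NUC) events from classified transitions.

A NUC event is a nuclear translocation within the cell, recognised from the
sequence of (angle block, nucleus-position state) pairs by two frame-linkage
patterns over adjacent transitions:

* pattern A — leading-process extension then jump: a (HIGH, CC-ahead)
  transition followed by a (LOW, NC-ahead) transition;
* pattern B — jump then catch-up: a (LOW, NC-ahead) transition followed by a
  (LOW, CC-ahead) transition.

Matches that share a transition describe one biological translocation and are
merged into a single event keeping the earlier pattern label.  Each event's
NUC distance is the displacement of the nucleus *within the cell frame* —
|Δ(NC − CC)| between the start of its first and the end of its last spanned
transition — and events whose noise-corrected distance is zero are discarded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import CentroidTrack
from .kinetics import (
    DEFAULT_TAU_UM,
    AngleBlock,
    PositionState,
    TransitionRecord,
    block_frequencies,
    nc_cc_distance_series,
    noise_correct,
    track_velocity,
    transitions,
)

__all__ = [
    "EventPattern",
    "Signature",
    "NucEvent",
    "TrackSummary",
    "detect_signatures",
    "decode_state_sequence",
    "decode_events",
    "nuc_footprint",
    "summarize_track",
    "summarize_tracks",
    "velocity_footprint_correlation",
]


class EventPattern(enum.Enum):
    A_LP_THEN_JUMP = "A_lp_then_jump"
    B_JUMP_THEN_CATCHUP = "B_jump_then_catchup"


@dataclass(frozen=True, slots=True)
class Signature:
    """A maximal run of >= 2 consecutive transitions in one LOW/HIGH block."""

    block: AngleBlock
    start_transition: int
    end_transition: int

    @property
    def length(self) -> int:
        return self.end_transition - self.start_transition + 1


@dataclass(frozen=True, slots=True)
class NucEvent:
    pattern: EventPattern
    start_transition: int
    end_transition: int
    nuc_distance_um: float

    @property
    def span(self) -> int:
        return self.end_transition - self.start_transition + 1


@dataclass(frozen=True, slots=True)
class TrackSummary:
    track_id: str
    condition: str
    velocity_um_min: float
    accumulated_um: float
    n_transitions: int
    block_freqs: dict
    undef_count: int
    n_events: int
    footprint_um: float
    mean_abs_nc_cc_um: float


def detect_signatures(records: list[TransitionRecord]) -> list[Signature]:
    """Maximal runs of >= 2 same-block transitions, LOW and HIGH blocks only.

    MID/UNDEF transitions and gap-flagged transitions break runs.
    """
    sigs: list[Signature] = []
    run_block: AngleBlock | None = None
    run_start = 0
    for i, r in enumerate(records + [None]):  # sentinel flushes the last run
        block = None
        if r is not None and not r.gap_flag and r.block in (
            AngleBlock.LOW,
            AngleBlock.HIGH,
        ):
            block = r.block
        if block is not run_block:
            if run_block is not None and i - run_start >= 2:
                sigs.append(Signature(run_block, run_start, i - 1))
            run_block = block
            run_start = i
    return sigs


_A_FIRST = (AngleBlock.HIGH, PositionState.CC_AHEAD)
_A_SECOND = (AngleBlock.LOW, PositionState.NC_AHEAD)
_B_FIRST = (AngleBlock.LOW, PositionState.NC_AHEAD)
_B_SECOND = (AngleBlock.LOW, PositionState.CC_AHEAD)


def decode_state_sequence(
    blocks,
    states,
    gap_flags=None,
) -> list[tuple[int, int, EventPattern]]:
    """Pattern-match the (block, position-state) sequence into merged spans.

    Returns ``(start, end, pattern)`` tuples over transition indices; spans
    never overlap and each keeps the pattern of its earliest raw match.
    """
    n = len(blocks)
    if gap_flags is None:
        gap_flags = [False] * n
    matches: list[tuple[int, int, EventPattern]] = []
    for i in range(n - 1):
        if gap_flags[i] or gap_flags[i + 1]:
            continue
        first = (blocks[i], states[i])
        second = (blocks[i + 1], states[i + 1])
        if first == _A_FIRST and second == _A_SECOND:
            matches.append((i, i + 1, EventPattern.A_LP_THEN_JUMP))
        elif first == _B_FIRST and second == _B_SECOND:
            matches.append((i, i + 1, EventPattern.B_JUMP_THEN_CATCHUP))
    merged: list[tuple[int, int, EventPattern]] = []
    for start, end, pat in matches:
        if merged and start <= merged[-1][1]:
            ps, pe, pp = merged[-1]
            merged[-1] = (ps, max(pe, end), pp)
        else:
            merged.append((start, end, pat))
    return merged


def decode_events(
    records: list[TransitionRecord], tau: float = DEFAULT_TAU_UM
) -> list[NucEvent]:
    """Decode merged NUC events and measure their in-cell-frame distances."""
    spans = decode_state_sequence(
        [r.block for r in records],
        [r.pos_state for r in records],
        [r.gap_flag for r in records],
    )
    events: list[NucEvent] = []
    for start, end, pat in spans:
        dx = records[end].rel_to_um[0] - records[start].rel_from_um[0]
        dy = records[end].rel_to_um[1] - records[start].rel_from_um[1]
        dist = noise_correct(math.hypot(dx, dy), tau)
        if dist == 0.0:
            continue
        events.append(NucEvent(pat, start, end, dist))
    return events


def nuc_footprint(
    events: list[NucEvent],
    n_transitions: int,
    weighting: str = "duration",
) -> float:
    """Weighted mean NUC distance (um) of a track's events; 0 with no events.

    ``duration`` weights each event by its spanned transition count (the
    default); ``uniform`` weights all events equally.
    """
    if n_transitions < 0:
        raise ValueError("n_transitions must be >= 0")
    if not events:
        return 0.0
    if weighting == "duration":
        weights = [e.span for e in events]
    elif weighting == "uniform":
        weights = [1] * len(events)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total_w = sum(weights)
    return sum(e.nuc_distance_um * w for e, w in zip(events, weights)) / total_w


def summarize_track(
    track: CentroidTrack,
    tau: float = DEFAULT_TAU_UM,
    *,
    velocity_reference: str = "NC",
    footprint_weighting: str = "duration",
) -> TrackSummary:
    """Full per-track summary: kinetics plus decoded events."""
    recs = transitions(track, tau)
    events = decode_events(recs, tau)
    freqs, undef = block_frequencies(recs)
    vel, acc = track_velocity(track, velocity_reference)
    return TrackSummary(
        track_id=track.track_id,
        condition=track.condition,
        velocity_um_min=vel,
        accumulated_um=acc,
        n_transitions=len(recs),
        block_freqs=freqs,
        undef_count=undef,
        n_events=len(events),
        footprint_um=nuc_footprint(events, len(recs), footprint_weighting),
        mean_abs_nc_cc_um=float(nc_cc_distance_series(track).mean()),
    )


def summarize_tracks(ts, tau: float = DEFAULT_TAU_UM, **kwargs) -> list[TrackSummary]:
    return [summarize_track(t, tau, **kwargs) for t in ts]


def summaries_to_frame(summaries: list[TrackSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "track_id": s.track_id,
                "condition": s.condition,
                "velocity_um_min": s.velocity_um_min,
                "accumulated_um": s.accumulated_um,
                "n_transitions": s.n_transitions,
                "freq_low": s.block_freqs.get(AngleBlock.LOW, float("nan")),
                "freq_mid": s.block_freqs.get(AngleBlock.MID, float("nan")),
                "freq_high": s.block_freqs.get(AngleBlock.HIGH, float("nan")),
                "undef_count": s.undef_count,
                "n_events": s.n_events,
                "footprint_um": s.footprint_um,
                "mean_abs_nc_cc_um": s.mean_abs_nc_cc_um,
            }
        )
    return pd.DataFrame(rows)


def events_to_frame(track_id: str, events: list[NucEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": track_id,
            "pattern": [e.pattern.value for e in events],
            "start_transition": [e.start_transition for e in events],
            "end_transition": [e.end_transition for e in events],
            "nuc_distance_um": [e.nuc_distance_um for e in events],
        }
    )


def velocity_footprint_correlation(
    summaries: list[TrackSummary],
) -> tuple[float, float, int]:
    """Pearson correlation of per-track velocity vs NUC footprint.

    Diagnoses nucleokinetic migration: cells that translocate their nuclei in
    larger strokes also cover more ground, so velocity tracks the footprint;
    mesenchymal cohorts show no such coupling.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 tracks for a correlation")
    v = [s.velocity_um_min for s in summaries]
    f = [s.footprint_um for s in summaries]
    if len(set(v)) == 1 or len(set(f)) == 1:
        raise ValueError(
            "degenerate input: zero variance in velocity or footprint"
        )
    r, p = stats.pearsonr(v, f)
    return float(r), float(p), len(summaries)
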