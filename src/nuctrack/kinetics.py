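"""Per-transition geometry of paired cell/nucleus centroid tracks.

For consecutive stored frames *n* and *n+1* of a track, the nuclear centroid
(NC) at time *n* is linked to the cellular centroid (CC) at time *n+1*.  The
angle at vertex NC(n+1) between the vector back to NC(n) and the vector to
CC(n+1) — the NNC/NCC angle — separates two migration geometries:

* high angles (140–180 deg): the cell centroid leads while the nucleus trails,
  the geometry of leading-process extension or mesenchymal towing;
* low angles (0–40 deg): the nucleus advances toward or past the cell
  centroid, the geometry of anterior nuclear translocation or contraction.

Alongside the angle, each transition carries the signed along-axis position of
the nucleus relative to the cell centroid (positive = nucleus ahead of CC
along the instantaneous CC motion direction), noise-corrected with a
displacement floor ``tau`` (default 0.12 um, the pooled median per-frame
nuclear displacement of sessile cells — cells whose median speed is below
0.05 um/min).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CentroidTrack, Phase, Point2D, TrackSet

__all__ = [
    "DEFAULT_TAU_UM",
    "LOW_BLOCK_MAX_DEG",
    "HIGH_BLOCK_MIN_DEG",
    "SESSILE_SPEED_UM_MIN",
    "AngleBlock",
    "PositionState",
    "TransitionRecord",
    "nnc_ncc_angle",
    "classify_block",
    "signed_nc_cc",
    "noise_correct",
    "transitions",
    "transitions_to_frame",
    "track_velocity",
    "is_sessile",
    "estimate_noise_threshold",
    "block_frequencies",
    "nc_cc_distance_series",
    "compare_phase_displacements",
]

#: noise floor for nuclear displacement, um (sessile-cell calibration)
DEFAULT_TAU_UM = 0.12
#: upper bound of the low angle block, degrees (inclusive)
LOW_BLOCK_MAX_DEG = 40.0
#: lower bound of the high angle block, degrees (inclusive)
HIGH_BLOCK_MIN_DEG = 140.0
#: median-speed threshold below which a track counts as sessile, um/min
SESSILE_SPEED_UM_MIN = 0.05

_EPS_UM = 1e-9


class AngleBlock(enum.Enum):
    LOW = "low"
    MID = "mid"
    HIGH = "high"
    UNDEF = "undef"


class PositionState(enum.Enum):
    NC_AHEAD = "nc_ahead"
    CC_AHEAD = "cc_ahead"
    NEUTRAL = "neutral"


@dataclass(frozen=True, slots=True)
class TransitionRecord:
    """Derived geometry for one consecutive stored frame pair."""

    from_frame: int
    to_frame: int
    angle_deg: float | None
    block: AngleBlock
    raw_nc_cc_um: float | None
    signed_nc_cc_um: float | None
    pos_state: PositionState
    cc_step_um: float
    nc_step_um: float
    dt_min: float
    gap_flag: bool = False
    phase: Phase = Phase.UNKNOWN
    # nucleus position relative to the cell centroid at the two endpoints,
    # needed to measure translocation distance in the cell frame
    rel_from_um: tuple[float, float] = (0.0, 0.0)
    rel_to_um: tuple[float, float] = (0.0, 0.0)


def nnc_ncc_angle(nc_n: Point2D, nc_n1: Point2D, cc_n1: Point2D) -> float | None:
    """Angle (deg) at vertex ``nc_n1`` between ``nc_n - nc_n1`` and ``cc_n1 - nc_n1``.

    Returns ``None`` when either arm is shorter than 1 nm (direction undefined).
    """
    ux, uy = nc_n[0] - nc_n1[0], nc_n[1] - nc_n1[1]
    vx, vy = cc_n1[0] - nc_n1[0], cc_n1[1] - nc_n1[1]
    nu = math.hypot(ux, uy)
    nv = math.hypot(vx, vy)
    if nu < _EPS_UM or nv < _EPS_UM:
        return None
    c = (ux * vx + uy * vy) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def classify_block(
    angle: float | None,
    low_max: float = LOW_BLOCK_MAX_DEG,
    high_min: float = HIGH_BLOCK_MIN_DEG,
) -> AngleBlock:
    """Coarse angle category: [0, low_max] LOW, [high_min, 180] HIGH, else MID."""
    if angle is None:
        return AngleBlock.UNDEF
    if not 0.0 <= angle <= 180.0:
        raise ValueError(f"angle {angle} outside [0, 180]")
    if angle <= low_max:
        return AngleBlock.LOW
    if angle >= high_min:
        return AngleBlock.HIGH
    return AngleBlock.MID


def signed_nc_cc(cc_n: Point2D, cc_n1: Point2D, nc_n1: Point2D) -> float | None:
    """Signed along-axis nucleus position relative to the cell centroid (um).

    Scalar projection of ``nc_n1 - cc_n1`` onto the unit vector of the CC step
    ``cc_n1 - cc_n``.  Positive: nucleus ahead of the cell centroid along the
    motion direction.  ``None`` when the cell centroid did not move.
    """
    dx, dy = cc_n1[0] - cc_n[0], cc_n1[1] - cc_n[1]
    norm = math.hypot(dx, dy)
    if norm < _EPS_UM:
        return None
    rx, ry = nc_n1[0] - cc_n1[0], nc_n1[1] - cc_n1[1]
    return (rx * dx + ry * dy) / norm


def noise_correct(value: float | None, tau: float = DEFAULT_TAU_UM) -> float | None:
    """Zero displacements below the noise floor ``tau``; pass others unchanged."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if value is None:
        return None
    return 0.0 if abs(value) < tau else value


def _pos_state(signed: float | None, tau: float) -> PositionState:
    if signed is None:
        return PositionState.NEUTRAL
    if signed > tau:
        return PositionState.NC_AHEAD
    if signed < -tau:
        return PositionState.CC_AHEAD
    return PositionState.NEUTRAL


def transitions(
    track: CentroidTrack,
    tau: float = DEFAULT_TAU_UM,
    *,
    low_max: float = LOW_BLOCK_MAX_DEG,
    high_min: float = HIGH_BLOCK_MIN_DEG,
) -> list[TransitionRecord]:
    """One :class:`TransitionRecord` per consecutive stored frame pair.

    A transition whose frame-index gap exceeds 1 is computed but gap-flagged;
    downstream signature/event decoding skips flagged transitions because the
    linkage patterns are defined on truly consecutive frames.
    """
    recs: list[TransitionRecord] = []
    fi = track.frame_index
    cc, nc = track.cc, track.nc
    for i in range(track.n_frames - 1):
        p_cc_n = Point2D(*cc[i])
        p_cc_n1 = Point2D(*cc[i + 1])
        p_nc_n = Point2D(*nc[i])
        p_nc_n1 = Point2D(*nc[i + 1])
        angle = nnc_ncc_angle(p_nc_n, p_nc_n1, p_cc_n1)
        raw = signed_nc_cc(p_cc_n, p_cc_n1, p_nc_n1)
        corrected = noise_correct(raw, tau)
        gap = int(fi[i + 1] - fi[i])
        recs.append(
            TransitionRecord(
                from_frame=int(fi[i]),
                to_frame=int(fi[i + 1]),
                angle_deg=angle,
                block=classify_block(angle, low_max, high_min),
                raw_nc_cc_um=raw,
                signed_nc_cc_um=corrected,
                pos_state=_pos_state(corrected, tau),
                cc_step_um=float(np.hypot(*(cc[i + 1] - cc[i]))),
                nc_step_um=float(np.hypot(*(nc[i + 1] - nc[i]))),
                dt_min=gap * track.frame_interval_min,
                gap_flag=gap > 1,
                phase=track.phase[i],
                rel_from_um=(float(nc[i, 0] - cc[i, 0]), float(nc[i, 1] - cc[i, 1])),
                rel_to_um=(
                    float(nc[i + 1, 0] - cc[i + 1, 0]),
                    float(nc[i + 1, 1] - cc[i + 1, 1]),
                ),
            )
        )
    return recs


def transitions_to_frame(track_id: str, recs: list[TransitionRecord]) -> pd.DataFrame:
    """Tabulate transitions for TSV export."""
    return pd.DataFrame(
        {
            "track_id": track_id,
            "from_frame": [r.from_frame for r in recs],
            "to_frame": [r.to_frame for r in recs],
            "angle_deg": [r.angle_deg for r in recs],
            "block": [r.block.value for r in recs],
            "raw_nc_cc_um": [r.raw_nc_cc_um for r in recs],
            "signed_nc_cc_um": [r.signed_nc_cc_um for r in recs],
            "pos_state": [r.pos_state.value for r in recs],
            "cc_step_um": [r.cc_step_um for r in recs],
            "nc_step_um": [r.nc_step_um for r in recs],
            "dt_min": [r.dt_min for r in recs],
            "gap_flag": [r.gap_flag for r in recs],
        }
    )


def accumulated_distance(track: CentroidTrack, reference: str = "NC") -> float:
    """Total path length (um) of the chosen centroid over stored frames."""
    xy = track.nc if reference.upper() == "NC" else track.cc
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def track_velocity(track: CentroidTrack, reference: str = "NC") -> tuple[float, float]:
    """(velocity um/min, accumulated distance um) for CC or NC path length.

    Velocity is accumulated path length divided by total elapsed minutes
    (true frame-index span times the frame interval).
    """
    dist = accumulated_distance(track, reference)
    total_min = (track.frame_index[-1] - track.frame_index[0]) * track.frame_interval_min
    return dist / total_min, dist


def is_sessile(
    track: CentroidTrack, speed_threshold: float = SESSILE_SPEED_UM_MIN
) -> bool:
    """True when the median per-transition NC speed is below the threshold.

    Sessile cells provide the substrate for noise calibration: their nuclei
    are not migrating, so their per-frame displacements measure tracking and
    segmentation jitter.
    """
    steps = np.hypot(*np.diff(track.nc, axis=0).T)
    dts = np.diff(track.frame_index) * track.frame_interval_min
    return float(np.median(steps / dts)) < speed_threshold


def estimate_noise_threshold(
    sessile: TrackSet,
    *,
    strict: bool = False,
    speed_threshold: float = SESSILE_SPEED_UM_MIN,
) -> float:
    """Median per-transition NC displacement (um) pooled over sessile tracks.

    The pooled median over genuinely sessile cells is the displacement noise
    floor ``tau`` used everywhere else.  Non-sessile members are a warning by
    default (``strict=True`` raises).
    """
    if len(sessile) == 0:
        raise ValueError("cannot estimate a noise threshold from an empty TrackSet")
    offenders = [t.track_id for t in sessile if not is_sessile(t, speed_threshold)]
    if offenders:
        msg = f"{len(offenders)} track(s) exceed the sessile speed threshold: " \
              f"{offenders[:5]}"
        if strict:
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    pooled = np.concatenate(
        [np.hypot(*np.diff(t.nc, axis=0).T) for t in sessile.tracks]
    )
    return float(np.median(pooled))


def block_frequencies(
    records: list[TransitionRecord],
) -> tuple[dict[AngleBlock, float], int]:
    """Relative block frequencies over defined-angle transitions.

    Returns ``(freqs, undef_count)``; freqs sum to 1 whenever any transition
    has a defined angle, and is empty otherwise.
    """
    counts = {AngleBlock.LOW: 0, AngleBlock.MID: 0, AngleBlock.HIGH: 0}
    undef = 0
    for r in records:
        if r.block is AngleBlock.UNDEF:
            undef += 1
        else:
            counts[r.block] += 1
    total = sum(counts.values())
    if total == 0:
        return {}, undef
    return {b: c / total for b, c in counts.items()}, undef


def nc_cc_distance_series(track: CentroidTrack) -> np.ndarray:
    """Per stored frame |NC - CC| in um, order preserved."""
    return np.hypot(*(track.nc - track.cc).T)


def compare_phase_displacements(
    ts: TrackSet, *, method: str = "asymp"
) -> dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test of NC step lengths, G1 vs S/G2.

    Transitions inherit the phase of their *from* frame; per-transition NC
    displacement distances are pooled across tracks.  Returns the KS D
    statistic, its p-value and the two group sizes.
    """
    g1: list[float] = []
    sg2: list[float] = []
    for t in ts:
        steps = np.hypot(*np.diff(t.nc, axis=0).T)
        for i, s in enumerate(steps):
            ph = t.phase[i]
            if ph is Phase.G1:
                g1.append(float(s))
            elif ph is Phase.S_G2:
                sg2.append(float(s))
    for name, grp in (("G1", g1), ("S_G2", sg2)):
        if len(grp) < 2:
            raise ValueError(f"phase group {name} has < 2 transitions")
    res = stats.ks_2samp(g1, sg2, method=method)
    return {
        "D": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_G1": len(g1),
        "n_SG2": len(sg2),
    }
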