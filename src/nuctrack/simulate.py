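"""Seeded generators: CC/NC track cohorts and paired DE tables.

Three migration modes are emulated, with ground-truth event labels written at
generation time (never by post-hoc decoding, so recovery tests are
non-circular):

``NUC`` — two-stroke nucleokinetic migration.  Each cycle of ``cycle_frames``
frames, the cell centroid advances ``step_um`` per frame along a persistent
heading while the nucleus drags slowly behind (leading-process extension,
high-angle geometry); on the last frame of the cycle the nucleus translocates
forward in a single stroke, landing ``jump_um`` ahead of the cell centroid
(anterior translocation, low-angle geometry).  One truth event is recorded
per translocation.

``MES`` — smooth mesenchymal migration.  Both centroids advance together,
the nucleus towed ``lag_um`` behind the heading.  With probability
``pause_prob`` per frame the cell pauses briefly, leaving only jitter — the
intermittent rests of real mesenchymal cells.  No truth events.

``SESSILE`` — stationary cells.  Both centroids jitter about fixed anchors;
used to calibrate the displacement noise floor.

``jitter_sd_um`` is calibrated as the per-axis standard deviation of the
*per-frame displacement* noise (the quantity the noise-floor estimator sees):
positions receive independent per-axis Gaussian noise of SD
``jitter_sd_um / sqrt(2)``, so frame-to-frame displacement noise has per-axis
SD ``jitter_sd_um`` and its magnitude has median ``jitter_sd_um *
sqrt(2 ln 2)``.

Reproducibility: one global seed expands to per-track substreams via
``numpy.random.default_rng([seed, track_index])``, so cohorts are identical
regardless of generation order.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CentroidTrack, TrackSet

__all__ = [
    "Mode",
    "SimParams",
    "LabeledTrackSet",
    "simulate",
    "jitter_for_noise_median",
    "simulate_de_pair",
]


class Mode(enum.Enum):
    NUC = "nuc"
    MES = "mes"
    SESSILE = "sessile"


def jitter_for_noise_median(median_um: float) -> float:
    """Per-axis displacement-noise SD whose step-magnitude median is ``median_um``.

    The step magnitude is Rayleigh with scale sigma, whose median is
    sigma * sqrt(2 ln 2); inverting gives the sigma to feed ``jitter_sd_um``.
    """
    return median_um / math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the package's standard study conditions."""

    mode: Mode = Mode.NUC
    n_tracks: int = 100
    n_frames: int = 200
    frame_interval_min: float = 5.0
    step_um: float = 1.0  # mean CC advance per motile frame
    jump_um: float = 1.5  # how far past CC the nucleus lands per translocation
    lag_um: float = 2.0  # nucleus offset behind CC, MES mode
    jitter_sd_um: float = 0.08  # per-axis SD of per-frame displacement noise
    persistence: float = 0.9  # directional correlation of the heading
    cycle_frames: int = 8  # extension + translocation period, NUC mode
    nc_drag: float = 0.5  # NC advance per extension frame, fraction of step
    pause_prob: float = 0.1  # per-frame pause probability, MES mode
    track_scale_spread: float = 0.4  # per-track uniform spread of step/jump
    seed: int = 42

    def validate(self) -> None:
        problems = []
        if self.n_tracks < 1:
            problems.append("n_tracks must be >= 1")
        if self.n_frames < 2:
            problems.append("n_frames must be >= 2")
        if self.frame_interval_min <= 0:
            problems.append("frame_interval_min must be > 0")
        for name in ("step_um", "jump_um", "lag_um", "jitter_sd_um"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            problems.append("persistence must be in [0, 1]")
        if self.cycle_frames < 2:
            problems.append("cycle_frames must be >= 2")
        if not 0.0 <= self.pause_prob < 1.0:
            problems.append("pause_prob must be in [0, 1)")
        if not 0.0 <= self.track_scale_spread < 1.0:
            problems.append("track_scale_spread must be in [0, 1)")
        if problems:
            raise ValueError("invalid SimParams: " + "; ".join(problems))
        if self.mode is Mode.NUC and self.jump_um <= 2 * self.jitter_sd_um:
            warnings.warn(
                "NUC mode with jump_um <= 2 * jitter_sd_um: translocations "
                "may not be identifiable above noise",
                stacklevel=2,
            )

    @classmethod
    def for_mode(cls, mode: Mode | str, **overrides) -> "SimParams":
        """Mode presets: NUC at 5-min, MES and SESSILE at 15-min intervals."""
        mode = Mode(mode) if not isinstance(mode, Mode) else mode
        interval = {Mode.NUC: 5.0, Mode.MES: 15.0, Mode.SESSILE: 15.0}[mode]
        base = cls(mode=mode, frame_interval_min=interval)
        return replace(base, **overrides) if overrides else base


@dataclass
class LabeledTrackSet:
    tracks: TrackSet
    truth_events: dict[str, list[tuple[int, int]]]
    params: SimParams = field(default=None)


def _heading_turns(rng, n: int, persistence: float) -> np.ndarray:
    """Cumulative headings (rad): wrapped-Gaussian turns scaled by 1 - persistence."""
    turn_sd = (1.0 - persistence) * math.pi / 2.0
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    turns = rng.normal(0.0, turn_sd, size=n)
    return theta0 + np.concatenate([[0.0], np.cumsum(turns[1:])])


def _simulate_track(params: SimParams, idx: int) -> tuple[CentroidTrack, list[tuple[int, int]]]:
    rng = np.random.default_rng([params.seed, idx])
    n = params.n_frames
    sp = params.track_scale_spread
    scale = rng.uniform(1.0 - sp, 1.0 + sp) if sp > 0 else 1.0
    step = params.step_um * scale
    jump = params.jump_um * scale
    pos_sd = params.jitter_sd_um / math.sqrt(2.0)
    cc = np.zeros((n, 2))
    nc = np.zeros((n, 2))
    truth: list[tuple[int, int]] = []
    theta = _heading_turns(rng, n, params.persistence)
    h = np.column_stack([np.cos(theta), np.sin(theta)])

    if params.mode is Mode.SESSILE:
        cc_anchor = rng.uniform(-50.0, 50.0, size=2)
        nc_anchor = cc_anchor + rng.uniform(-1.0, 1.0, size=2)
        cc[:] = cc_anchor
        nc[:] = nc_anchor
    elif params.mode is Mode.MES:
        start = rng.uniform(-50.0, 50.0, size=2)
        cc[0] = start
        nc[0] = start - params.lag_um * h[0]
        paused = rng.random(n) < params.pause_prob
        for t in range(1, n):
            if paused[t]:
                cc[t] = cc[t - 1]
            else:
                cc[t] = cc[t - 1] + step * h[t]
            nc[t] = cc[t] - params.lag_um * h[t]
    else:  # NUC: two-stroke cycles
        start = rng.uniform(-50.0, 50.0, size=2)
        cc[0] = start
        nc[0] = start  # nucleus starts at the cell centroid
        for t in range(1, n):
            cc[t] = cc[t - 1] + step * h[t]
            if t % params.cycle_frames == 0:
                # translocation stroke: nucleus lands ahead of the new CC
                nc[t] = cc[t] + jump * h[t]
                truth.append((t - 1, t - 1))
            else:
                # extension stroke: nucleus drags slowly along the heading
                nc[t] = nc[t - 1] + params.nc_drag * step * h[t]

    if params.jitter_sd_um > 0:
        cc = cc + rng.normal(0.0, pos_sd, size=cc.shape)
        nc = nc + rng.normal(0.0, pos_sd, size=nc.shape)

    track = CentroidTrack(
        track_id=f"{params.mode.value}_{idx:04d}",
        frame_index=np.arange(n),
        cc=cc,
        nc=nc,
        frame_interval_min=params.frame_interval_min,
        condition=params.mode.value,
    )
    return track, truth


def simulate(params: SimParams) -> LabeledTrackSet:
    """Generate a cohort; deterministic given ``params.seed``."""
    params.validate()
    tracks = []
    truth: dict[str, list[tuple[int, int]]] = {}
    for i in range(params.n_tracks):
        t, ev = _simulate_track(params, i)
        tracks.append(t)
        truth[t.track_id] = ev
    ts = TrackSet(
        tracks=tracks,
        metadata={"generator": "nuctrack.simulate", "mode": params.mode.value,
                  "seed": params.seed},
    )
    return LabeledTrackSet(tracks=ts, truth_events=truth, params=params)


def truth_events_to_frame(lts: LabeledTrackSet) -> pd.DataFrame:
    rows = [
        {"track_id": tid, "start_transition": s, "end_transition": e}
        for tid, evs in lts.truth_events.items()
        for s, e in evs
    ]
    return pd.DataFrame(rows, columns=["track_id", "start_transition", "end_transition"])


def evaluate_event_recovery(lts: LabeledTrackSet, tau: float = 0.12) -> dict:
    """Recall/precision of decoded events against the generator's truth labels.

    A truth translocation is recovered when some decoded event's span covers
    its transition; a decoded event is correct when its span covers some truth
    transition.  Also reports the decoded event rate per transition.
    """
    from .decoder import decode_events
    from .kinetics import transitions as compute_transitions

    tp = fn = 0
    n_decoded = matched_decoded = n_transitions = 0
    for t in lts.tracks:
        recs = compute_transitions(t, tau)
        events = decode_events(recs, tau)
        n_transitions += len(recs)
        n_decoded += len(events)
        truth = lts.truth_events[t.track_id]
        for s, _ in truth:
            if any(ev.start_transition <= s <= ev.end_transition for ev in events):
                tp += 1
            else:
                fn += 1
        for ev in events:
            if any(
                ev.start_transition <= s <= ev.end_transition for s, _ in truth
            ):
                matched_decoded += 1
    n_truth = tp + fn
    return {
        "recall": tp / n_truth if n_truth else float("nan"),
        "precision": matched_decoded / n_decoded if n_decoded else float("nan"),
        "n_truth": n_truth,
        "n_decoded": n_decoded,
        "event_rate": n_decoded / n_transitions if n_transitions else 0.0,
    }


def simulate_de_pair(
    n_genes: int,
    frac_mis_up: float = 0.1,
    frac_mis_down: float = 0.1,
    frac_concordant: float = 0.2,
    effect_size: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired DE tables with a known mis-expression category structure.

    Classified genes carry |logFC| = ``effect_size`` with their category's
    sign pattern and p-values in (0, 0.05]; the remainder gets p-values in
    (0.05, 1].  Concordant genes split evenly between up/up and down/down.
    Returns (perturbation table, clinical table, truth category per gene).
    """
    from .misexpression import Category

    fracs = (frac_mis_up, frac_mis_down, frac_concordant)
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("category fractions must be >= 0 and sum to <= 1")
    rng = np.random.default_rng(seed)
    n_up = round(n_genes * frac_mis_up)
    n_down = round(n_genes * frac_mis_down)
    n_conc = round(n_genes * frac_concordant)
    n_conc_up = n_conc // 2
    n_conc_down = n_conc - n_conc_up
    n_null = n_genes - n_up - n_down - n_conc

    genes = np.array([f"g{i:06d}" for i in range(n_genes)])
    rng.shuffle(genes)
    e = effect_size
    signs = (
        [(+1, -1)] * n_up
        + [(-1, +1)] * n_down
        + [(+1, +1)] * n_conc_up
        + [(-1, -1)] * n_conc_down
    )
    cats = (
        [Category.MIS_UP] * n_up
        + [Category.MIS_DOWN] * n_down
        + [Category.CONCORDANT_UP] * n_conc_up
        + [Category.CONCORDANT_DOWN] * n_conc_down
        + [Category.UNCLASSIFIED] * n_null
    )
    lfc_kd = np.concatenate(
        [np.array([s[0] for s in signs]) * e, rng.normal(0.0, e / 3.0, n_null)]
    )
    lfc_cl = np.concatenate(
        [np.array([s[1] for s in signs]) * e, rng.normal(0.0, e / 3.0, n_null)]
    )
    # significant genes: p in (0, 0.05]; null genes: p in (0.05, 1]
    n_sig = n_genes - n_null
    p_kd = np.concatenate(
        [0.05 * (1.0 - rng.random(n_sig)), 0.05 + 0.95 * (1.0 - rng.random(n_null))]
    )
    p_cl = np.concatenate(
        [0.05 * (1.0 - rng.random(n_sig)), 0.05 + 0.95 * (1.0 - rng.random(n_null))]
    )
    kd = pd.DataFrame({"gene_id": genes, "logFC": lfc_kd, "p_value": p_kd})
    cl = pd.DataFrame({"gene_id": genes, "logFC": lfc_cl, "p_value": p_cl})
    truth = pd.Series(cats, index=genes, name="truth_category")
    return kd, cl, truth
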