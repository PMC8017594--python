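"""Reading, validating, pairing and writing centroid track tables.

A *track* is one cell followed over time with two points recorded per frame:
the cellular centroid (CC) and the nuclear centroid (NC), both in micrometres.
Two on-disk dialects are supported:

``native_tsv``
    One tab-separated file with columns ``track_id, frame, cc_x_um, cc_y_um,
    nc_x_um, nc_y_um, phase, condition``.  This is the package's own format
    and round-trips exactly through :func:`write_tracks` / :func:`read_tracks`.

``imagej_pair``
    Two ImageJ Manual-Tracking-style exports (one for the cell body, one for
    the nucleus), each with a track column (``track_id`` or ``Track n°``),
    a frame column (``frame`` or ``Slice n°``) and ``x``/``y`` coordinates.
    Coordinates may be in pixels; pass ``pixel_size_um`` to convert.  The two
    files are inner-joined on (track, frame): frames present in only one file
    are dropped and counted.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "Point2D",
    "TrackFrame",
    "CentroidTrack",
    "TrackSet",
    "TrackFormatError",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
]


class TrackFormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class TrackValidationError(ValueError):
    """Structurally valid file whose content violates a track invariant."""


class Phase(enum.Enum):
    """FUCCI-style cell-cycle annotation attached to a frame."""

    G1 = "g1"
    S_G2 = "s_g2"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value: "Phase | str | None") -> "Phase":
        if isinstance(value, Phase):
            return value
        if value is None:
            return cls.UNKNOWN
        return cls(str(value).strip().lower())


class Point2D(NamedTuple):
    """A planar position in micrometres."""

    x: float
    y: float


class TrackFrame(NamedTuple):
    """One stored timepoint: frame index, both centroids, phase label."""

    frame_index: int
    cc: Point2D
    nc: Point2D
    phase: Phase


@dataclass
class CentroidTrack:
    """Time-ordered paired CC/NC positions for one cell.

    Coordinates are kept as ``(n, 2)`` float arrays; ``frame_index`` holds the
    original (possibly gapped) frame numbers.  Time of frame *k* is
    ``k * frame_interval_min`` minutes; transitions between stored frames use
    the true index gap, so dropped frames never corrupt velocities.
    """

    track_id: str
    frame_index: np.ndarray  # (n,) int
    cc: np.ndarray  # (n, 2) float, um
    nc: np.ndarray  # (n, 2) float, um
    frame_interval_min: float
    phase: np.ndarray | None = None  # (n,) of Phase
    condition: str = ""

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.cc = np.asarray(self.cc, dtype=float)
        self.nc = np.asarray(self.nc, dtype=float)
        if self.phase is None:
            self.phase = np.full(len(self.frame_index), Phase.UNKNOWN, dtype=object)
        else:
            self.phase = np.asarray(
                [Phase.coerce(p) for p in self.phase], dtype=object
            )
        self.validate()

    def validate(self) -> None:
        n = len(self.frame_index)
        if n < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: needs >= 2 frames, has {n}"
            )
        if self.cc.shape != (n, 2) or self.nc.shape != (n, 2):
            raise TrackValidationError(
                f"track {self.track_id!r}: coordinate arrays must be ({n}, 2)"
            )
        if not (np.isfinite(self.cc).all() and np.isfinite(self.nc).all()):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite coordinates"
            )
        if np.any(np.diff(self.frame_index) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: frame_index not strictly increasing"
            )
        if np.any(self.frame_index < 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: negative frame index"
            )
        if not self.frame_interval_min > 0:
            raise TrackValidationError(
                f"track {self.track_id!r}: frame_interval_min must be > 0"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def frames(self) -> Iterator[TrackFrame]:
        """Iterate frames as :class:`TrackFrame` tuples."""
        for i in range(self.n_frames):
            yield TrackFrame(
                int(self.frame_index[i]),
                Point2D(*self.cc[i]),
                Point2D(*self.nc[i]),
                self.phase[i],
            )


@dataclass
class TrackSet:
    """An ordered collection of tracks with unique ids plus free metadata."""

    tracks: list[CentroidTrack]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate track ids: {dupes}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[CentroidTrack]:
        return iter(self.tracks)

    def __getitem__(self, track_id: str) -> CentroidTrack:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)


NATIVE_COLUMNS = [
    "track_id",
    "frame",
    "cc_x_um",
    "cc_y_um",
    "nc_x_um",
    "nc_y_um",
    "phase",
    "condition",
]

# accepted spellings of the ImageJ Manual Tracking export headers
_IJ_TRACK_COLS = ("track_id", "track n°", "track no", "track")
_IJ_FRAME_COLS = ("frame", "slice n°", "slice no", "slice")
_IJ_X_COLS = ("x", "x (um)", "x_um")
_IJ_Y_COLS = ("y", "y (um)", "y_um")


def _find_column(df: pd.DataFrame, candidates: tuple[str, ...], path) -> str:
    lower = {c.strip().lower(): c for c in df.columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise TrackFormatError(
        f"{path}: none of the expected columns {candidates} found "
        f"(got {list(df.columns)})"
    )


def read_tracks(
    path,
    dialect: str = "native_tsv",
    *,
    nucleus_path=None,
    pixel_size_um: float = 1.0,
    frame_interval_min: float | None = None,
) -> TrackSet:
    """Read a :class:`TrackSet` from disk.

    Parameters
    ----------
    path
        The native TSV, or (for ``imagej_pair``) the *cell*-centroid file.
    dialect
        ``"native_tsv"`` or ``"imagej_pair"``.
    nucleus_path
        Required for ``imagej_pair``: the nucleus-centroid file.
    pixel_size_um
        Multiplied onto imagej_pair coordinates (native files are already um).
    frame_interval_min
        Frame interval in minutes.  Required for ``imagej_pair``; for
        ``native_tsv`` it defaults to the value stored in metadata or 1.0.
    """
    if dialect == "native_tsv":
        return _read_native(path, frame_interval_min)
    if dialect == "imagej_pair":
        if nucleus_path is None:
            raise ValueError("imagej_pair dialect requires nucleus_path")
        if frame_interval_min is None:
            raise ValueError("imagej_pair dialect requires frame_interval_min")
        return _read_imagej_pair(path, nucleus_path, pixel_size_um, frame_interval_min)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_native(path, frame_interval_min: float | None) -> TrackSet:
    df = pd.read_csv(path, sep="\t", dtype={"track_id": str, "condition": str})
    missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s) {missing}")
    interval = frame_interval_min
    if interval is None:
        interval = float(df.attrs.get("frame_interval_min", 1.0)) if df.attrs else 1.0
    tracks = []
    dropped = 0
    # preserve file order of first appearance
    for tid in df["track_id"].drop_duplicates():
        sub = df[df["track_id"] == tid].sort_values("frame")
        if sub["frame"].duplicated().any():
            raise TrackValidationError(
                f"{path}: track {tid!r} has duplicate frame indices"
            )
        if len(sub) < 2:
            dropped += 1
            continue
        cond = sub["condition"].iloc[0]
        tracks.append(
            CentroidTrack(
                track_id=str(tid),
                frame_index=sub["frame"].to_numpy(),
                cc=sub[["cc_x_um", "cc_y_um"]].to_numpy(),
                nc=sub[["nc_x_um", "nc_y_um"]].to_numpy(),
                frame_interval_min=interval,
                phase=sub["phase"].tolist(),
                condition="" if pd.isna(cond) else str(cond),
            )
        )
    meta = {"source": str(path), "dropped_short_tracks": dropped}
    if dropped:
        warnings.warn(f"{dropped} track(s) with < 2 frames excluded", stacklevel=2)
    return TrackSet(tracks=tracks, metadata=meta)


def _read_point_file(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt", ".xls")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    out = pd.DataFrame(
        {
            "track_id": df[_find_column(df, _IJ_TRACK_COLS, path)].astype(str),
            "frame": df[_find_column(df, _IJ_FRAME_COLS, path)].astype(int),
            "x": df[_find_column(df, _IJ_X_COLS, path)].astype(float),
            "y": df[_find_column(df, _IJ_Y_COLS, path)].astype(float),
        }
    )
    return out


def _read_imagej_pair(
    cell_path, nucleus_path, pixel_size_um: float, frame_interval_min: float
) -> TrackSet:
    cell = _read_point_file(cell_path)
    nuc = _read_point_file(nucleus_path)
    merged = cell.merge(
        nuc, on=["track_id", "frame"], how="inner", suffixes=("_cc", "_nc")
    )
    n_dropped = (len(cell) - len(merged)) + (len(nuc) - len(merged))
    tracks = []
    excluded = 0
    for tid in merged["track_id"].drop_duplicates():
        sub = merged[merged["track_id"] == tid].sort_values("frame")
        sub = sub.drop_duplicates(subset="frame", keep="first")
        if len(sub) < 2:
            excluded += 1
            continue
        tracks.append(
            CentroidTrack(
                track_id=str(tid),
                frame_index=sub["frame"].to_numpy(),
                cc=sub[["x_cc", "y_cc"]].to_numpy() * pixel_size_um,
                nc=sub[["x_nc", "y_nc"]].to_numpy() * pixel_size_um,
                frame_interval_min=frame_interval_min,
            )
        )
    if n_dropped or excluded:
        warnings.warn(
            f"imagej_pair join: {n_dropped} unmatched frame row(s) dropped, "
            f"{excluded} track(s) with < 2 joined frames excluded",
            stacklevel=3,
        )
    return TrackSet(
        tracks=tracks,
        metadata={
            "source": f"{cell_path}+{nucleus_path}",
            "unmatched_rows_dropped": int(n_dropped),
            "dropped_short_tracks": excluded,
            "pixel_size_um": pixel_size_um,
        },
    )


def tracks_to_frame(ts: TrackSet) -> pd.DataFrame:
    """Flatten a TrackSet into one native-format DataFrame."""
    chunks = []
    for t in ts:
        chunks.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frame_index,
                    "cc_x_um": t.cc[:, 0],
                    "cc_y_um": t.cc[:, 1],
                    "nc_x_um": t.nc[:, 0],
                    "nc_y_um": t.nc[:, 1],
                    "phase": [p.value for p in t.phase],
                    "condition": t.condition,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(columns=NATIVE_COLUMNS)
    return pd.concat(chunks, ignore_index=True)[NATIVE_COLUMNS]


def write_tracks(ts: TrackSet, path) -> None:
    """Write the native TSV; coordinates keep >= 6 significant digits."""
    df = tracks_to_frame(ts)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g", lineterminator="\n")
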