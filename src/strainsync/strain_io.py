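"""Read, write and validate per-point longitudinal-strain exports.

Speckle-tracking packages export one Lagrangian longitudinal strain trace
per tracked point.  In the parasternal long-axis (PLAX) view the left
ventricle is divided into six segments (anterior/posterior x
base/mid/apex) with eight tracked points each, so a complete layer
(endocardial or epicardial) carries 48 point traces.

This module defines the in-memory containers (:class:`FrameGrid`,
:class:`PointTrace`, :class:`StrainStudy`, :class:`CycleWindow`) and the
``strainsync-v1`` CSV dialect used to persist them:

    frame,time_ms,layer,segment,point,strain_pct[,pos_x_mm,pos_y_mm]

one row per (frame, trace), with an optional YAML sidecar
(``<file stem>.yaml``) carrying the nominal frame rate, cardiac-cycle
windows and free-form metadata.  Strain is stored as signed percent with
systolic shortening negative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, IntegrityError

__all__ = [
    "Segment",
    "Layer",
    "SEGMENTS",
    "FrameGrid",
    "PointTrace",
    "CycleWindow",
    "StrainStudy",
    "LayerReport",
    "POINTS_PER_SEGMENT",
    "POINTS_PER_LAYER",
    "read_export",
    "write_export",
    "validate_layer",
    "sidecar_path",
]


class Segment(str, enum.Enum):
    """The six PLAX long-axis segments, anterior base to posterior base."""

    ANT_BASE = "ant_base"
    ANT_MID = "ant_mid"
    ANT_APEX = "ant_apex"
    POST_APEX = "post_apex"
    POST_MID = "post_mid"
    POST_BASE = "post_base"


class Layer(str, enum.Enum):
    ENDO = "endo"
    EPI = "epi"


#: Canonical segment order (anatomical, around the PLAX trace).
SEGMENTS: tuple[Segment, ...] = (
    Segment.ANT_BASE,
    Segment.ANT_MID,
    Segment.ANT_APEX,
    Segment.POST_APEX,
    Segment.POST_MID,
    Segment.POST_BASE,
)

POINTS_PER_SEGMENT = 8
POINTS_PER_LAYER = POINTS_PER_SEGMENT * len(SEGMENTS)  # 48

_REQUIRED_COLUMNS = ("frame", "time_ms", "layer", "segment", "point", "strain_pct")
_POSITION_COLUMNS = ("pos_x_mm", "pos_y_mm")


@dataclass(frozen=True)
class FrameGrid:
    """The temporal axis of an acquisition.

    Parameters
    ----------
    frame_times : array of float
        Frame times in milliseconds, strictly increasing, length >= 2.
    frame_rate : float
        Nominal frame rate in Hz.  The median inter-frame interval must
        agree with ``1000 / frame_rate`` to within 20%.
    """

    frame_times: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        times = np.asarray(self.frame_times, dtype=float)
        object.__setattr__(self, "frame_times", times)
        if times.ndim != 1 or times.size < 2:
            raise IntegrityError("frame_times must be 1-D with at least 2 frames")
        if not np.all(np.isfinite(times)):
            raise IntegrityError("frame_times must be finite")
        if np.any(np.diff(times) <= 0):
            raise IntegrityError("frame_times must be strictly increasing")
        if not self.frame_rate > 0:
            raise IntegrityError("frame_rate must be positive")
        nominal = 1000.0 / self.frame_rate
        median_dt = float(np.median(np.diff(times)))
        if abs(median_dt - nominal) > 0.2 * nominal:
            raise IntegrityError(
                f"median inter-frame interval {median_dt:.3f} ms is inconsistent "
                f"with nominal frame rate {self.frame_rate:g} Hz ({nominal:.3f} ms)"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    @property
    def frame_interval_ms(self) -> float:
        """Median inter-frame interval in ms."""
        return float(np.median(np.diff(self.frame_times)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameGrid):
            return NotImplemented
        return (
            np.allclose(self.frame_times, other.frame_times)
            and abs(self.frame_rate - other.frame_rate) < 1e-9
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass
class PointTrace:
    """One tracked point's strain time series.

    ``strain`` is percent longitudinal strain per frame (negative =
    shortening); ``position``, if present, is an ``(n_frames, 2)`` array
    of traced (x, y) coordinates in mm.
    """

    segment: Segment
    layer: Layer
    point_index: int
    strain: np.ndarray
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.segment = Segment(self.segment)
        self.layer = Layer(self.layer)
        self.point_index = int(self.point_index)
        if not 0 <= self.point_index < POINTS_PER_SEGMENT:
            raise IntegrityError(
                f"point_index must be 0-{POINTS_PER_SEGMENT - 1}, "
                f"got {self.point_index}"
            )
        self.strain = np.asarray(self.strain, dtype=float)
        if self.strain.ndim != 1:
            raise IntegrityError("strain must be a 1-D array")
        if not np.all(np.isfinite(self.strain)):
            raise IntegrityError(f"non-finite strain in trace {self.key}")
        if np.any(np.abs(self.strain) >= 100.0):
            raise IntegrityError(f"|strain| must be < 100% in trace {self.key}")
        if self.position is not None:
            pos = np.asarray(self.position, dtype=float)
            if pos.shape != (self.strain.size, 2):
                raise IntegrityError(
                    f"position must have shape (n_frames, 2) in trace {self.key}"
                )
            self.position = pos

    @property
    def key(self) -> tuple[Segment, Layer, int]:
        return (self.segment, self.layer, self.point_index)


@dataclass(frozen=True)
class CycleWindow:
    """A half-open frame window ``[start_frame, end_frame)`` covering one
    cardiac cycle."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_frame", int(self.start_frame))
        object.__setattr__(self, "end_frame", int(self.end_frame))
        if self.start_frame < 0 or self.end_frame <= self.start_frame:
            raise IntegrityError(
                f"invalid cycle window [{self.start_frame}, {self.end_frame})"
            )
        if self.n_frames < 4:
            raise IntegrityError("cycle window must span at least 4 frames")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    def slice(self) -> slice:
        return slice(self.start_frame, self.end_frame)


@dataclass
class StrainStudy:
    """A full acquisition: temporal grid, point traces, cycle windows and
    free-form metadata (animal id, timepoint, view, ...)."""

    grid: FrameGrid
    traces: list[PointTrace]
    cycles: list[CycleWindow] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = list(self.traces)
        self.cycles = list(self.cycles)
        seen: set[tuple[Segment, Layer, int]] = set()
        for tr in self.traces:
            if tr.strain.size != self.grid.n_frames:
                raise IntegrityError(
                    f"trace {tr.key} has {tr.strain.size} frames, "
                    f"grid has {self.grid.n_frames}"
                )
            if tr.key in seen:
                raise IntegrityError(f"duplicate trace {tr.key}")
            seen.add(tr.key)
        prev_end = 0
        for w in self.cycles:
            if w.start_frame < prev_end:
                raise IntegrityError("cycle windows must be ordered, non-overlapping")
            if w.end_frame > self.grid.n_frames:
                raise IntegrityError("cycle window exceeds the frame grid")
            prev_end = w.end_frame

    @property
    def n_frames(self) -> int:
        return self.grid.n_frames

    def layer_traces(self, layer: Layer | str) -> list[PointTrace]:
        layer = Layer(layer)
        return [t for t in self.traces if t.layer is layer]

    def get_trace(
        self, layer: Layer | str, segment: Segment | str, point_index: int
    ) -> PointTrace:
        key = (Segment(segment), Layer(layer), int(point_index))
        for t in self.traces:
            if t.key == key:
                return t
        raise KeyError(key)

    def has_positions(self, layer: Layer | str | None = None) -> bool:
        traces = self.traces if layer is None else self.layer_traces(layer)
        return bool(traces) and all(t.position is not None for t in traces)

    def sorted_layer_traces(self, layer: Layer | str) -> list[PointTrace]:
        """Layer traces in canonical order (segment order, then point)."""
        order = {s: i for i, s in enumerate(SEGMENTS)}
        return sorted(
            self.layer_traces(layer), key=lambda t: (order[t.segment], t.point_index)
        )


@dataclass(frozen=True)
class LayerReport:
    """Completeness report for one layer of a study."""

    layer: Layer
    present: tuple[tuple[Segment, int], ...]
    missing: tuple[tuple[Segment, int], ...]

    @property
    def n_present(self) -> int:
        return len(self.present)

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    @property
    def complete(self) -> bool:
        return self.n_missing == 0


def validate_layer(study: StrainStudy, layer: Layer | str) -> LayerReport:
    """Report which of the 48 (segment, point) slots of ``layer`` are filled."""
    layer = Layer(layer)
    have = {(t.segment, t.point_index) for t in study.layer_traces(layer)}
    expected = [(s, p) for s in SEGMENTS for p in range(POINTS_PER_SEGMENT)]
    present = tuple(sp for sp in expected if sp in have)
    missing = tuple(sp for sp in expected if sp not in have)
    return LayerReport(layer=layer, present=present, missing=missing)


def sidecar_path(path: str | Path) -> Path:
    """The YAML sidecar companion of a CSV export (``stem.yaml``)."""
    path = Path(path)
    return path.with_suffix(".yaml")


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_export(
    study: StrainStudy, path: str | Path, *, write_sidecar: bool = True
) -> Path:
    """Write a study to a ``strainsync-v1`` CSV file.

    Floats are written with 9 significant digits so a read-back study
    matches the original to well beyond 6 significant digits.  Position
    columns are emitted only when every trace carries positions.  The
    YAML sidecar records the nominal frame rate, cycle windows and
    metadata; without it the frame rate is re-inferred on read.
    """
    path = Path(path)
    if not study.traces:
        raise IntegrityError("refusing to write a study with no traces")
    with_pos = all(t.position is not None for t in study.traces)
    header = list(_REQUIRED_COLUMNS) + (list(_POSITION_COLUMNS) if with_pos else [])
    times = study.grid.frame_times
    order = {s: i for i, s in enumerate(SEGMENTS)}
    traces = sorted(
        study.traces,
        key=lambda t: (t.layer.value, order[t.segment], t.point_index),
    )
    lines = [",".join(header)]
    for tr in traces:
        base = f"{tr.layer.value},{tr.segment.value},{tr.point_index}"
        for i in range(study.n_frames):
            row = f"{i},{_fmt(times[i])},{base},{_fmt(tr.strain[i])}"
            if with_pos:
                row += f",{_fmt(tr.position[i, 0])},{_fmt(tr.position[i, 1])}"
            lines.append(row)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if write_sidecar:
        doc = {
            "frame_rate": float(study.grid.frame_rate),
            "cycles": [[w.start_frame, w.end_frame] for w in study.cycles],
            "meta": dict(study.meta),
        }
        sidecar_path(path).write_text(yaml.safe_dump(doc), encoding="utf-8")
    return path


def read_export(path: str | Path) -> StrainStudy:
    """Parse a ``strainsync-v1`` CSV export into a :class:`StrainStudy`.

    Raises
    ------
    FormatError
        If a required column is absent.
    IntegrityError
        On duplicate (segment, layer, point) rows, ragged frame counts,
        or inconsistent frame times across traces.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    with_pos = all(c in df.columns for c in _POSITION_COLUMNS)

    try:
        df["layer"] = df["layer"].map(Layer)
        df["segment"] = df["segment"].map(Segment)
    except ValueError as exc:
        raise FormatError(f"unknown layer/segment label in {path}: {exc}") from exc
    if df["layer"].isna().any() or df["segment"].isna().any():
        raise FormatError(f"unknown layer/segment label in {path}")

    # Frame grid: frame numbers must be 0..n-1 with one consistent time each.
    frame_time = df.drop_duplicates("frame").sort_values("frame")
    frames = frame_time["frame"].to_numpy()
    n_frames = int(frames.max()) + 1 if len(frames) else 0
    if len(frames) != n_frames or not np.array_equal(frames, np.arange(n_frames)):
        raise IntegrityError(f"frame numbers in {path} are not contiguous from 0")
    times = frame_time["time_ms"].to_numpy(dtype=float)
    check = df.groupby("frame")["time_ms"].nunique()
    if (check > 1).any():
        raise IntegrityError(f"inconsistent time_ms for the same frame in {path}")

    frame_rate = None
    cycles: list[CycleWindow] = []
    meta: dict = {}
    sc = sidecar_path(path)
    if sc.exists() and sc != path:
        doc = yaml.safe_load(sc.read_text(encoding="utf-8")) or {}
        frame_rate = doc.get("frame_rate")
        cycles = [CycleWindow(a, b) for a, b in doc.get("cycles", [])]
        meta = dict(doc.get("meta", {}))
    if frame_rate is None:
        frame_rate = 1000.0 / float(np.median(np.diff(times)))
    grid = FrameGrid(frame_times=times, frame_rate=float(frame_rate))

    traces: list[PointTrace] = []
    seen: set[tuple] = set()
    for (layer, segment, point), g in df.groupby(
        ["layer", "segment", "point"], sort=False
    ):
        key = (segment, layer, int(point))
        if key in seen:  # pragma: no cover - groupby already merges keys
            raise IntegrityError(f"duplicate trace {key} in {path}")
        seen.add(key)
        if len(g) != n_frames or g["frame"].nunique() != n_frames:
            if g["frame"].duplicated().any():
                raise IntegrityError(f"duplicate rows for trace {key} in {path}")
            raise IntegrityError(
                f"trace {key} has {g['frame'].nunique()} frames, expected {n_frames}"
            )
        g = g.sort_values("frame")
        position = None
        if with_pos:
            position = g[list(_POSITION_COLUMNS)].to_numpy(dtype=float)
        traces.append(
            PointTrace(
                segment=segment,
                layer=layer,
                point_index=int(point),
                strain=g["strain_pct"].to_numpy(dtype=float),
                position=position,
            )
        )
    return StrainStudy(grid=grid, traces=traces, cycles=cycles, meta=meta)
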