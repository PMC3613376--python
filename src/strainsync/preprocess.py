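"""Build segment-level and global strain curves, detect cardiac cycles,
and resample cycles onto a common grid.

Segment curves are frame-wise arithmetic means of a segment's 8 point
traces; the global curve averages all 48 points of a layer.  Because no
ECG channel exists in a strain export, cycle windows are anchored at
local maxima of the global curve: in speckle-tracking output strain is
zero by construction at each cycle's end-diastolic reference frame, so
the near-zero local maxima mark cycle starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import CompletenessError, CycleDetectionError, UsageError
from .strain_io import (
    SEGMENTS,
    CycleWindow,
    FrameGrid,
    Layer,
    PointTrace,
    Segment,
    StrainStudy,
    validate_layer,
)

__all__ = [
    "SegmentCurve",
    "GlobalCurve",
    "segment_curves",
    "global_curve",
    "detect_cycles",
    "select_cycles",
    "resample_cycle",
]


@dataclass(frozen=True)
class SegmentCurve:
    """Frame-wise mean strain of one segment's 8 points."""

    segment: Segment
    layer: Layer
    strain: np.ndarray


@dataclass(frozen=True)
class GlobalCurve:
    """Frame-wise mean strain over all 48 points of a layer."""

    layer: Layer
    strain: np.ndarray


def _require_complete(study: StrainStudy, layer: Layer | str) -> Layer:
    layer = Layer(layer)
    report = validate_layer(study, layer)
    if not report.complete:
        raise CompletenessError(
            f"layer {layer.value!r} incomplete: {report.n_missing} of 48 "
            f"(segment, point) slots missing, e.g. {report.missing[:3]}"
        )
    return layer


def segment_curves(study: StrainStudy, layer: Layer | str) -> list[SegmentCurve]:
    """The 6 segment curves of a complete layer, in canonical segment order."""
    layer = _require_complete(study, layer)
    traces = study.sorted_layer_traces(layer)
    curves = []
    for seg in SEGMENTS:
        block = np.stack([t.strain for t in traces if t.segment is seg])
        curves.append(SegmentCurve(segment=seg, layer=layer, strain=block.mean(axis=0)))
    return curves


def global_curve(study: StrainStudy, layer: Layer | str) -> GlobalCurve:
    """Frame-wise mean over all 48 point traces of a complete layer."""
    layer = _require_complete(study, layer)
    block = np.stack([t.strain for t in study.layer_traces(layer)])
    return GlobalCurve(layer=layer, strain=block.mean(axis=0))


def detect_cycles(
    curve: GlobalCurve,
    grid: FrameGrid,
    min_cycles: int = 3,
    *,
    min_period_ms: float = 40.0,
    prominence_fraction: float = 0.2,
) -> list[CycleWindow]:
    """Detect consecutive cardiac-cycle windows from a global strain curve.

    Windows run between successive end-diastolic reference frames, found
    as local maxima of the curve (including the endpoints when they are
    local maxima) with prominence at least ``prominence_fraction`` of the
    curve's range and separated by at least ``min_period_ms`` (default
    40 ms, i.e. heart rates up to 1500 bpm are admissible).  Peak ties
    resolve to the earliest frame.

    Returns all detected windows in order; warns if fewer than
    ``min_cycles`` were found.  Raises :class:`CycleDetectionError` when
    no full cycle is detectable (e.g. a flat curve).
    """
    y = np.asarray(curve.strain, dtype=float)
    if y.size != grid.n_frames:
        raise UsageError("curve length does not match the frame grid")
    span = float(np.ptp(y))
    if span <= 0:
        raise CycleDetectionError("flat curve: no cardiac cycles detectable")
    distance = max(2, int(round(min_period_ms / 1000.0 * grid.frame_rate)))
    # Pad with -inf so end-diastolic frames at the record boundaries are
    # themselves detectable as local maxima.
    padded = np.concatenate(([-np.inf], y, [-np.inf]))
    peaks, _ = find_peaks(
        padded, prominence=prominence_fraction * span, distance=distance
    )
    peaks = peaks - 1
    windows = [
        CycleWindow(int(a), int(b))
        for a, b in zip(peaks[:-1], peaks[1:])
        if b - a >= 4
    ]
    if not windows:
        raise CycleDetectionError("fewer than 1 full cardiac cycle detected")
    if len(windows) < min_cycles:
        warnings.warn(
            f"detected {len(windows)} cycles, fewer than the requested "
            f"{min_cycles}",
            stacklevel=2,
        )
    return windows


def select_cycles(windows: list[CycleWindow], n: int) -> list[CycleWindow]:
    """Deterministic selection policy: the first ``n`` consecutive windows."""
    if n < 1:
        raise UsageError("must select at least one cycle")
    return list(windows[: min(n, len(windows))])


def resample_cycle(study: StrainStudy, window: CycleWindow, n_out: int) -> StrainStudy:
    """Linearly interpolate every trace onto ``n_out`` equally spaced times
    spanning ``window``.

    The output study's grid covers exactly the window's duration and
    carries a single cycle window spanning all ``n_out`` frames.  Linear
    interpolation is exact on affine traces and is the identity when
    ``n_out`` equals the window's own frame count.
    """
    if n_out < 4:
        raise UsageError("n_out must be at least 4")
    if window.end_frame > study.n_frames:
        raise UsageError("cycle window lies outside the frame grid")
    t_old = study.grid.frame_times[window.slice()]
    t_new = np.linspace(t_old[0], t_old[-1], n_out)
    frame_rate = 1000.0 * (n_out - 1) / (t_new[-1] - t_new[0])
    grid = FrameGrid(frame_times=t_new, frame_rate=frame_rate)
    traces = []
    for tr in study.traces:
        strain = np.interp(t_new, t_old, tr.strain[window.slice()])
        position = None
        if tr.position is not None:
            pos = tr.position[window.slice()]
            position = np.column_stack(
                [np.interp(t_new, t_old, pos[:, k]) for k in range(2)]
            )
        traces.append(
            PointTrace(
                segment=tr.segment,
                layer=tr.layer,
                point_index=tr.point_index,
                strain=strain,
                position=position,
            )
        )
    return StrainStudy(
        grid=grid,
        traces=traces,
        cycles=[CycleWindow(0, n_out)],
        meta={**study.meta, "resampled_from_window": [window.start_frame, window.end_frame]},
    )
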