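"""Peak strain, time-to-peak and regional summaries.

Peak longitudinal strain is the signed minimum of a curve (the most
negative value — maximal shortening); "reduced strain" therefore means a
smaller magnitude.  Time-to-peak (TTP) is measured in ms from the start
of the cardiac-cycle window.  Regional contrasts pool the basal segments
(anterior + posterior base, 16 points) against the apical segments
(anterior + posterior apex, 16 points); mid segments are excluded from
the regional contrast.

Metrics are computed per cycle and then averaged across the selected
cycles (typically three consecutive cycles).

Also included: the simplified Bernoulli transform, 4·v², converting a
continuous-wave Doppler peak velocity (m/s) into a stenosis pressure
gradient (mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError, UsageError
from .preprocess import global_curve, segment_curves
from .strain_io import (
    SEGMENTS,
    CycleWindow,
    Layer,
    Segment,
    StrainStudy,
)

__all__ = [
    "PeakResult",
    "RegionalSummary",
    "BASAL_SEGMENTS",
    "APICAL_SEGMENTS",
    "peak_of_curve",
    "segment_peaks",
    "regional_summary",
    "bernoulli_gradient",
    "summary_report",
]

#: Segments pooled into the basal region for regional contrasts.
BASAL_SEGMENTS: tuple[Segment, ...] = (Segment.ANT_BASE, Segment.POST_BASE)
#: Segments pooled into the apical region.
APICAL_SEGMENTS: tuple[Segment, ...] = (Segment.ANT_APEX, Segment.POST_APEX)


@dataclass(frozen=True)
class PeakResult:
    """Peak (most negative) strain of a curve within one cycle.

    ``time_to_peak_ms`` is the offset from the cycle start; ties between
    equal minima resolve to the earliest frame.
    """

    peak_strain: float
    time_to_peak_ms: float
    frame_index: int


@dataclass(frozen=True)
class RegionalSummary:
    """Cycle-averaged global, basal and apical peaks plus per-segment peaks."""

    layer: Layer
    n_cycles_averaged: int
    global_peak: float
    basal_peak: float
    apical_peak: float
    per_segment: dict[Segment, PeakResult]


def peak_of_curve(strain: np.ndarray, times_ms: np.ndarray) -> PeakResult:
    """Signed minimum of ``strain`` and its time offset from the window start.

    ``times_ms`` are the frame times of the window (same length as
    ``strain``).  An all-NaN curve raises :class:`DataError`.
    """
    strain = np.asarray(strain, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if strain.size == 0:
        raise UsageError("empty curve")
    if strain.shape != times_ms.shape:
        raise UsageError("strain and times must have equal length")
    if np.all(np.isnan(strain)):
        raise DataError("all-NaN strain curve")
    idx = int(np.nanargmin(strain))
    return PeakResult(
        peak_strain=float(strain[idx]),
        time_to_peak_ms=float(times_ms[idx] - times_ms[0]),
        frame_index=idx,
    )


def segment_peaks(
    study: StrainStudy, layer: Layer | str, cycle: CycleWindow
) -> list[PeakResult]:
    """Per-segment peak results within one cycle, in canonical segment order."""
    times = study.grid.frame_times[cycle.slice()]
    return [
        peak_of_curve(c.strain[cycle.slice()], times)
        for c in segment_curves(study, layer)
    ]


def _region_curve(
    study: StrainStudy, layer: Layer, segments: tuple[Segment, ...]
) -> np.ndarray:
    # Point-level definition: mean over the region's 16 point traces.
    block = np.stack(
        [t.strain for t in study.layer_traces(layer) if t.segment in segments]
    )
    return block.mean(axis=0)


def regional_summary(
    study: StrainStudy, layer: Layer | str, cycles: list[CycleWindow]
) -> RegionalSummary:
    """Cycle-averaged peak strain globally, per region and per segment.

    For each cycle the peak of the global curve, of the basal and apical
    region curves (frame-wise mean of the region's 16 points), and of
    each segment curve is extracted; peaks and TTPs are then averaged
    arithmetically across cycles.
    """
    layer = Layer(layer)
    if not cycles:
        raise UsageError("at least one cycle window is required")
    g = global_curve(study, layer).strain
    basal = _region_curve(study, layer, BASAL_SEGMENTS)
    apical = _region_curve(study, layer, APICAL_SEGMENTS)

    g_peaks, b_peaks, a_peaks = [], [], []
    seg_acc: dict[Segment, list[PeakResult]] = {s: [] for s in SEGMENTS}
    for w in cycles:
        times = study.grid.frame_times[w.slice()]
        g_peaks.append(peak_of_curve(g[w.slice()], times).peak_strain)
        b_peaks.append(peak_of_curve(basal[w.slice()], times).peak_strain)
        a_peaks.append(peak_of_curve(apical[w.slice()], times).peak_strain)
        for seg, pk in zip(SEGMENTS, segment_peaks(study, layer, w)):
            seg_acc[seg].append(pk)

    per_segment = {
        seg: PeakResult(
            peak_strain=float(np.mean([p.peak_strain for p in pks])),
            time_to_peak_ms=float(np.mean([p.time_to_peak_ms for p in pks])),
            frame_index=int(round(np.mean([p.frame_index for p in pks]))),
        )
        for seg, pks in seg_acc.items()
    }
    return RegionalSummary(
        layer=layer,
        n_cycles_averaged=len(cycles),
        global_peak=float(np.mean(g_peaks)),
        basal_peak=float(np.mean(b_peaks)),
        apical_peak=float(np.mean(a_peaks)),
        per_segment=per_segment,
    )


def bernoulli_gradient(peak_velocity: float) -> float:
    """Simplified Bernoulli pressure gradient, 4·v² (mmHg from m/s)."""
    if peak_velocity < 0:
        raise DomainError("peak velocity must be non-negative")
    return 4.0 * float(peak_velocity) ** 2


def summary_report(summary: RegionalSummary) -> dict:
    """JSON-ready report for a :class:`RegionalSummary`."""
    return {
        "layer": summary.layer.value,
        "n_cycles": summary.n_cycles_averaged,
        "global_peak_pct": summary.global_peak,
        "basal_peak_pct": summary.basal_peak,
        "apical_peak_pct": summary.apical_peak,
        "per_segment": {
            seg.value: {
                "peak_pct": pk.peak_strain,
                "ttp_ms": pk.time_to_peak_ms,
            }
            for seg, pk in summary.per_segment.items()
        },
    }
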