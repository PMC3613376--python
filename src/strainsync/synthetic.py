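"""Synthetic murine strain-study generator.

Emulates the per-point longitudinal strain traces a speckle-tracking
package exports for a mouse parasternal long-axis acquisition: ~230
frames/s, heart rates of 600–700 bpm, three cardiac cycles, 48 tracked
points per layer (endo + epi).  Every source of heterogeneity the
dyssynchrony measures respond to is a controllable parameter:

* regional amplitude (per-segment peak strain magnitude),
* timing dispersion (per-point Gaussian phase jitter, plus optional
  deterministic per-segment phase offsets),
* waveform morphology (a fraction of points receives an added
  early-systolic positive-strain excursion, mimicking the clusters of
  positive strain seen under pressure overload),
* additive white measurement noise.

The waveform template is a C¹ raised-cosine trough: strain is 0 at the
cycle-start (end-diastolic) reference frame, descends smoothly to
−amplitude at the systolic peak fraction, and returns to 0 by cycle end.
Endo and epi traces of the same point share one latent phase; the epi
amplitude is scaled down by a transmural gradient (endo magnitude >
epi), standard physiology.

Point positions are laid out on a schematic PLAX half-ellipse (synthetic
geometry for map rendering; not a tracing of any real ventricle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import UsageError
from .strain_io import (
    POINTS_PER_SEGMENT,
    SEGMENTS,
    CycleWindow,
    FrameGrid,
    Layer,
    PointTrace,
    Segment,
    StrainStudy,
)

__all__ = [
    "ScenarioConfig",
    "waveform",
    "positive_excursion",
    "simulate_study",
    "scenario_preset",
    "PRESET_NAMES",
]


def _uniform_amplitudes(
    base: float, mid: float, apex: float
) -> dict[Segment, float]:
    return {
        Segment.ANT_BASE: base,
        Segment.POST_BASE: base,
        Segment.ANT_MID: mid,
        Segment.POST_MID: mid,
        Segment.ANT_APEX: apex,
        Segment.POST_APEX: apex,
    }


@dataclass
class ScenarioConfig:
    """Parameters of one simulated acquisition.

    Defaults reflect a healthy adult mouse imaged in long axis: 650 bpm,
    230 frames/s, three cycles, peak strain magnitudes increasing from
    base (15%) to apex (20%) — the apical predominance seen in normal
    murine longitudinal strain — small timing jitter and modest
    measurement noise.
    """

    heart_rate: float = 650.0  # bpm
    frame_rate: float = 230.0  # Hz
    n_cycles: int = 3
    #: Peak strain magnitude (%) per segment; traces reach −amplitude.
    amplitude_map: dict[Segment, float] = field(
        default_factory=lambda: _uniform_amplitudes(15.0, 17.5, 20.0)
    )
    #: SD (ms) of the per-point Gaussian timing offset.
    phase_jitter_sd: float = 1.5
    #: Deterministic extra timing offset (ms) per segment, on top of jitter.
    segment_phase_offsets: dict[Segment, float] = field(default_factory=dict)
    #: Fraction of eligible points given a positive-strain excursion.
    morphology_positive_fraction: float = 0.0
    #: Peak height (%) of the added early-systolic positive excursion.
    positive_excursion_amplitude: float = 4.0
    #: Segments whose points are eligible for positive excursions
    #: (None = all six).
    positive_segments: tuple[Segment, ...] | None = None
    #: SD (%) of additive white per-frame noise.
    noise_sd: float = 0.5
    #: Transmural amplitude gradient: epi amplitude = endo × this factor.
    epi_amplitude_scale: float = 0.8
    #: Fraction of the cycle at which the systolic trough occurs.
    systolic_peak_fraction: float = 0.45
    include_positions: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 300.0 <= self.heart_rate <= 900.0:
            raise UsageError("heart_rate must lie in [300, 900] bpm")
        if not 50.0 <= self.frame_rate <= 1000.0:
            raise UsageError("frame_rate must lie in [50, 1000] Hz")
        if self.n_cycles < 1:
            raise UsageError("n_cycles must be >= 1")
        if set(self.amplitude_map) != set(SEGMENTS):
            raise UsageError("amplitude_map must cover all 6 segments")
        if any(a < 0 for a in self.amplitude_map.values()):
            raise UsageError("amplitudes must be >= 0")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be >= 0")
        if not 0.0 <= self.morphology_positive_fraction <= 1.0:
            raise UsageError("morphology_positive_fraction must lie in [0, 1]")
        if not 0.0 < self.systolic_peak_fraction < 1.0:
            raise UsageError("systolic_peak_fraction must lie in (0, 1)")

    @property
    def period_ms(self) -> float:
        return 60000.0 / self.heart_rate


def waveform(
    t_norm: np.ndarray | float, amplitude: float, peak_fraction: float = 0.45
) -> np.ndarray | float:
    """One-cycle longitudinal-strain template (%) at normalized time.

    Zero at ``t_norm = 0`` and ``1``, a single smooth trough of depth
    −``amplitude`` at ``t_norm = peak_fraction``; C¹ (two raised-cosine
    half-arcs meeting with zero slope at the trough).
    """
    t = np.asarray(t_norm, dtype=float)
    down = 0.5 * (1.0 - np.cos(np.pi * t / peak_fraction))
    up = 0.5 * (1.0 - np.cos(np.pi * (1.0 - t) / (1.0 - peak_fraction)))
    shape = np.where(t <= peak_fraction, down, up)
    out = -amplitude * shape
    return out if out.ndim else float(out)


def positive_excursion(
    t_norm: np.ndarray | float,
    amplitude: float,
    center: float = 0.12,
    width: float = 0.24,
) -> np.ndarray | float:
    """Early-systolic positive-strain bump (%): a raised cosine of the
    given peak height centered at ``center`` with full width ``width``,
    zero elsewhere."""
    t = np.asarray(t_norm, dtype=float)
    u = (t - center) / width
    bump = np.where(np.abs(u) < 0.5, amplitude * 0.5 * (1.0 + np.cos(2 * np.pi * u)), 0.0)
    return bump if bump.ndim else float(bump)


def _plax_positions(n_frames: int, strain_block: np.ndarray) -> np.ndarray:
    """Schematic PLAX geometry for the 48 points of one layer.

    Points sit on a half-ellipse (base at top, apex at bottom, raster
    y-down); each point moves radially toward the centroid in proportion
    to its instantaneous strain.  Returns (48, n_frames, 2) in mm.
    """
    phi = np.pi * (np.arange(48) + 0.5) / 48.0
    a, b = 2.8, 4.5  # semi-axes mm: short (x), long (y)
    x0 = -a * np.cos(phi)
    y0 = b * np.sin(phi)
    radial = 1.0 + strain_block / 300.0  # mild contraction motion
    pos = np.empty((48, n_frames, 2))
    pos[:, :, 0] = x0[:, None] * radial
    pos[:, :, 1] = y0[:, None] * radial
    return pos


def simulate_study(config: ScenarioConfig) -> StrainStudy:
    """Generate a deterministic :class:`StrainStudy` from a scenario.

    96 traces (48 endo + 48 epi).  Each point draws one latent timing
    offset shared by its endo and epi trace; amplitude comes from the
    point's segment (epi scaled by the transmural gradient); a seeded
    random subset of eligible points receives the positive excursion;
    white noise is added independently per trace and frame.  The true
    cycle windows are attached to the study.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    period = config.period_ms
    n_frames = int(round(config.n_cycles * period / 1000.0 * config.frame_rate)) + 1
    times = np.arange(n_frames) * 1000.0 / config.frame_rate
    grid = FrameGrid(frame_times=times, frame_rate=config.frame_rate)

    eligible = (
        set(config.positive_segments)
        if config.positive_segments is not None
        else set(SEGMENTS)
    )
    # Latent per-point draws, in canonical order so output is seed-stable.
    offsets: dict[tuple[Segment, int], float] = {}
    has_bump: dict[tuple[Segment, int], bool] = {}
    for seg in SEGMENTS:
        seg_shift = float(config.segment_phase_offsets.get(seg, 0.0))
        for p in range(POINTS_PER_SEGMENT):
            offsets[(seg, p)] = seg_shift + rng.normal(0.0, config.phase_jitter_sd)
            has_bump[(seg, p)] = (
                seg in eligible
                and rng.random() < config.morphology_positive_fraction
            )

    layer_scale = {Layer.ENDO: 1.0, Layer.EPI: config.epi_amplitude_scale}
    traces: list[PointTrace] = []
    blocks: dict[Layer, list[np.ndarray]] = {Layer.ENDO: [], Layer.EPI: []}
    for layer in (Layer.ENDO, Layer.EPI):
        for seg in SEGMENTS:
            amp = config.amplitude_map[seg] * layer_scale[layer]
            for p in range(POINTS_PER_SEGMENT):
                t_norm = np.mod(times - offsets[(seg, p)], period) / period
                strain = waveform(t_norm, amp, config.systolic_peak_fraction)
                if has_bump[(seg, p)]:
                    strain = strain + positive_excursion(
                        t_norm, config.positive_excursion_amplitude
                    )
                if config.noise_sd > 0:
                    strain = strain + rng.normal(0.0, config.noise_sd, n_frames)
                blocks[layer].append(np.asarray(strain))
                traces.append(
                    PointTrace(segment=seg, layer=layer, point_index=p, strain=strain)
                )

    if config.include_positions:
        scale = {Layer.ENDO: 1.0, Layer.EPI: 1.25}
        i = 0
        for layer in (Layer.ENDO, Layer.EPI):
            pos = _plax_positions(n_frames, np.stack(blocks[layer])) * scale[layer]
            for k in range(48):
                traces[i].position = pos[k]
                i += 1

    frames_per_cycle = period / 1000.0 * config.frame_rate
    cycles = []
    for k in range(config.n_cycles):
        a = int(round(k * frames_per_cycle))
        b = min(int(round((k + 1) * frames_per_cycle)), n_frames)
        cycles.append(CycleWindow(a, b))

    return StrainStudy(
        grid=grid,
        traces=traces,
        cycles=cycles,
        meta={
            "source": "strainsync.synthetic",
            "seed": config.seed,
            "heart_rate_bpm": config.heart_rate,
        },
    )


#: Named scenario presets mirroring the arms of a pressure-overload study.
PRESET_NAMES = ("sham", "aac", "deaac", "mi_like")


def scenario_preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Preset scenario configurations.

    ``sham``
        Healthy control: apical > basal strain magnitude, small timing
        jitter, no positive excursions.
    ``aac``
        Ascending aortic constriction (pressure overload): reduced basal
        amplitudes, large timing jitter, positive-strain excursions
        concentrated in the basal and mid segments.
    ``deaac``
        Constriction released: sham-like amplitudes, mild residual jitter.
    ``mi_like``
        Infarct-like: one contiguous region (anterior mid + apex) with
        near-zero amplitude and positive (dyskinetic) excursions.

    Preset numbers are tool defaults chosen to reproduce the qualitative
    regional/timing patterns of each condition, not measurements of any
    particular animal.
    """
    base = ScenarioConfig(seed=seed)
    if name == "sham":
        return base
    if name == "aac":
        return replace(
            base,
            amplitude_map=_uniform_amplitudes(9.0, 14.0, 19.0),
            phase_jitter_sd=6.0,
            morphology_positive_fraction=0.5,
            positive_excursion_amplitude=5.0,
            positive_segments=(
                Segment.ANT_BASE,
                Segment.POST_BASE,
                Segment.ANT_MID,
                Segment.POST_MID,
            ),
        )
    if name == "deaac":
        return replace(
            base,
            amplitude_map=_uniform_amplitudes(14.0, 17.0, 19.5),
            phase_jitter_sd=2.5,
        )
    if name == "mi_like":
        amps = _uniform_amplitudes(15.0, 17.5, 20.0)
        amps[Segment.ANT_MID] = 1.0
        amps[Segment.ANT_APEX] = 1.0
        return replace(
            base,
            amplitude_map=amps,
            phase_jitter_sd=3.0,
            morphology_positive_fraction=0.8,
            positive_excursion_amplitude=5.0,
            positive_segments=(Segment.ANT_MID, Segment.ANT_APEX),
        )
    raise UsageError(f"unknown scenario preset {name!r}; choose from {PRESET_NAMES}")
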