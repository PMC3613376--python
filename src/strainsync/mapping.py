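"""Topographical strain maps.

Each frame's tracked points are drawn at their traced (x, y) positions,
color-coded by instantaneous longitudinal strain through a diverging
blue–white–red scale (blue = negative strain / shortening, red =
positive strain / lengthening), endocardial and epicardial chains
distinguished by marker size.  Frames can be assembled into a cine loop
(MP4 when an encoder is available, animated PNG otherwise, with a
per-frame PNG directory as the last resort).

Rendering conventions, fixed so outputs are reproducible pixel for
pixel: raster y-axis increases downward; positions in mm are mapped by a
fixed isotropic scale with a constant margin; out-of-range strain clamps
to the scale endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colors as mcolors
from matplotlib.figure import Figure

from .errors import CapabilityError, UsageError
from .strain_io import Layer, StrainStudy

__all__ = ["ColorScale", "FrameMap", "render_frame", "render_cine"]


@dataclass(frozen=True)
class ColorScale:
    """Diverging strain color scale: ``min_strain`` maps to saturated
    blue, ``max_strain`` to saturated red, ``midpoint`` to neutral white.
    Default symmetric about 0 at ±30%."""

    min_strain: float = -30.0
    max_strain: float = 30.0
    midpoint: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_strain < self.midpoint < self.max_strain:
            raise UsageError("require min_strain < midpoint < max_strain")

    def to_color(self, strain: float | np.ndarray) -> np.ndarray:
        """RGBA color(s) for strain value(s); clamps outside the range."""
        norm = mcolors.TwoSlopeNorm(
            vmin=self.min_strain, vcenter=self.midpoint, vmax=self.max_strain
        )
        cmap = plt.get_cmap("bwr")
        vals = norm(np.clip(np.asarray(strain, dtype=float), self.min_strain, self.max_strain))
        return cmap(vals)


@dataclass(frozen=True)
class FrameMap:
    """Render plan for one frame: (x, y, layer, RGBA color) per point."""

    frame_index: int
    points: tuple[tuple[float, float, Layer, tuple[float, float, float, float]], ...]


_MARKER_SIZE = {Layer.ENDO: 30.0, Layer.EPI: 70.0}


def _positioned_traces(study: StrainStudy):
    traces = [t for t in study.traces if t.position is not None]
    if not traces:
        raise CapabilityError(
            "no trace carries positions; simulate with include_positions=True "
            "or supply pos_x_mm/pos_y_mm columns in the export"
        )
    return traces


def _bounds(traces) -> tuple[float, float, float, float]:
    pos = np.concatenate([t.position for t in traces])
    margin = 1.0  # mm
    return (
        float(pos[:, 0].min() - margin),
        float(pos[:, 0].max() + margin),
        float(pos[:, 1].min() - margin),
        float(pos[:, 1].max() + margin),
    )


def frame_map(study: StrainStudy, frame: int, scale: ColorScale) -> FrameMap:
    """Compute the per-point render plan for one frame."""
    if not 0 <= frame < study.n_frames:
        raise UsageError(f"frame {frame} outside grid of {study.n_frames} frames")
    traces = _positioned_traces(study)
    pts = []
    for tr in traces:
        x, y = tr.position[frame]
        rgba = tuple(float(c) for c in scale.to_color(tr.strain[frame]))
        pts.append((float(x), float(y), tr.layer, rgba))
    return FrameMap(frame_index=frame, points=tuple(pts))


def _draw(fig: Figure, fmap: FrameMap, scale: ColorScale, bounds) -> None:
    ax = fig.add_axes((0.02, 0.05, 0.78, 0.9))
    # Epi first (larger markers behind), then endo.
    for layer in (Layer.EPI, Layer.ENDO):
        pts = [p for p in fmap.points if p[2] is layer]
        if pts:
            xs, ys, _, cols = zip(*pts)
            ax.scatter(
                xs, ys, s=_MARKER_SIZE[layer], c=list(cols),
                edgecolors="0.4", linewidths=0.4,
            )
    ax.set_xlim(bounds[0], bounds[1])
    ax.set_ylim(bounds[3], bounds[2])  # raster convention: y down
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"frame {fmap.frame_index}", fontsize=9)
    cax = fig.add_axes((0.84, 0.15, 0.04, 0.7))
    norm = mcolors.TwoSlopeNorm(
        vmin=scale.min_strain, vcenter=scale.midpoint, vmax=scale.max_strain
    )
    fig.colorbar(
        plt.cm.ScalarMappable(norm=norm, cmap="bwr"),
        cax=cax, label="strain (%)",
    )


def _figure() -> Figure:
    from matplotlib.backends.backend_agg import FigureCanvasAgg

    fig = Figure(figsize=(4.0, 3.2), dpi=120)
    FigureCanvasAgg(fig)
    return fig


def render_frame(
    study: StrainStudy,
    frame: int,
    scale: ColorScale | None = None,
    path: str | Path | None = None,
) -> FrameMap:
    """Render one frame's topographic strain map.

    Returns the :class:`FrameMap` render plan; when ``path`` is given,
    also writes a PNG there.  Requires traces with positions.
    """
    scale = scale or ColorScale()
    fmap = frame_map(study, frame, scale)
    if path is not None:
        fig = _figure()
        _draw(fig, fmap, scale, _bounds(_positioned_traces(study)))
        fig.savefig(path, format="png", metadata={"Software": None})
    return fmap


def _frame_array(study: StrainStudy, frame: int, scale: ColorScale, bounds) -> np.ndarray:
    fig = _figure()
    _draw(fig, frame_map(study, frame, scale), scale, bounds)
    fig.canvas.draw()
    return np.asarray(fig.canvas.buffer_rgba()).copy()


def render_cine(
    study: StrainStudy,
    path: str | Path,
    scale: ColorScale | None = None,
    fps_out: float = 30.0,
) -> Path:
    """Assemble every frame's map into a cine loop.

    Writes MP4 when ``path`` ends in ``.mp4`` and an ffmpeg encoder is
    available; otherwise (or for a ``.png`` path) an animated PNG.  If
    neither encoder works, falls back to a directory of per-frame PNGs
    with a warning.  Returns the path actually written.
    """
    scale = scale or ColorScale()
    path = Path(path)
    bounds = _bounds(_positioned_traces(study))
    frames = [
        _frame_array(study, i, scale, bounds) for i in range(study.n_frames)
    ]
    if path.suffix.lower() == ".mp4":
        try:
            import imageio.v3 as iio

            iio.imwrite(path, [f[:, :, :3] for f in frames], fps=fps_out, plugin="FFMPEG")
            return path
        except Exception:
            warnings.warn(
                "MP4 encoder unavailable; writing animated PNG instead",
                stacklevel=2,
            )
            path = path.with_suffix(".png")
    if path.suffix.lower() == ".png":
        try:
            from PIL import Image

            imgs = [Image.fromarray(f) for f in frames]
            imgs[0].save(
                path,
                save_all=True,
                append_images=imgs[1:],
                duration=int(round(1000.0 / fps_out)),
                loop=0,
            )
            return path
        except Exception:
            warnings.warn(
                "animated-PNG write failed; writing per-frame PNGs",
                stacklevel=2,
            )
    outdir = path.with_suffix("")
    outdir.mkdir(parents=True, exist_ok=True)
    from PIL import Image

    for i, f in enumerate(frames):
        Image.fromarray(f).save(outdir / f"frame_{i:04d}.png")
    return outdir
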