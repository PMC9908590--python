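"""Annotator behavior traces: viewport dwell intervals and attention heatmaps.

During annotation the client records timestamped events — field-of-view (FOV)
center changes, magnification changes, pencil switches, voice start/stop,
undo/delete and label edits.  Dwell follows last-event-holds semantics: a
FOV or magnification event opens an interval that lasts until the next FOV or
magnification event (or the final event of the trace); other event types do
not move the viewport and so do not close intervals.  Dwell maps reveal where
the annotator looked longest, which correlates with lesion difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyTraceError, EventTypeError

EVENT_TYPES = frozenset(
    {
        "fov_center_change",
        "magnification",
        "pencil_switch",
        "voice_start",
        "voice_stop",
        "undo",
        "delete",
        "label_create",
        "label_modify",
    }
)

#: events that move or rescale the viewport and hence close a dwell interval
_VIEW_EVENTS = frozenset({"fov_center_change", "magnification"})

DEFAULT_SCREEN_PX = (1920, 1080)
DEFAULT_IDLE_CAP_S = 120.0


@dataclass
class Event:
    t_ms: int
    type: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise EventTypeError(f"unknown event type {self.type!r}", type=self.type)


@dataclass
class Trace:
    wsi_id: str
    annotator_id: str
    screen_px: tuple[int, int] = DEFAULT_SCREEN_PX
    events: list[Event] = field(default_factory=list)


@dataclass(frozen=True)
class ViewportInterval:
    """One dwell interval: a level-0 rectangle held for ``dwell_s`` seconds."""

    x0: float
    y0: float
    x1: float
    y1: float
    dwell_s: float
    center: tuple[float, float]
    magnification: float


@dataclass
class HeatmapGrid:
    cell_px: int
    cells: np.ndarray  # [rows (y), cols (x)] of dwell-seconds
    total_dwell_s: float

    def normalized(self) -> np.ndarray:
        m = float(self.cells.max())
        return self.cells / m if m > 0 else np.zeros_like(self.cells)


def viewport_intervals(
    trace: Trace,
    slide_size: tuple[int, int] | None = None,
    idle_cap_s: float = DEFAULT_IDLE_CAP_S,
) -> list[ViewportInterval]:
    """Reconstruct dwell rectangles from a trace.

    The viewport rectangle is ``screen_px / magnification`` level-0 pixels,
    centered on the current FOV center and clipped to ``slide_size`` when
    given.  Intervals longer than ``idle_cap_s`` are truncated (idle
    sessions would otherwise dominate the heat).
    """
    center: tuple[float, float] | None = None
    magnification = 1.0
    open_t: int | None = None
    out: list[ViewportInterval] = []
    if not trace.events:
        raise EmptyTraceError("trace has no events", wsi=trace.wsi_id)
    end_t = trace.events[-1].t_ms

    def emit(until_ms: int) -> None:
        if center is None or open_t is None or until_ms <= open_t:
            return
        dwell = min((until_ms - open_t) / 1000.0, idle_cap_s)
        w = trace.screen_px[0] / magnification
        h = trace.screen_px[1] / magnification
        cx, cy = center
        x0, y0, x1, y1 = cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2
        if slide_size is not None:
            x0, y0 = max(x0, 0.0), max(y0, 0.0)
            x1, y1 = min(x1, float(slide_size[0])), min(y1, float(slide_size[1]))
        if x1 > x0 and y1 > y0:
            out.append(ViewportInterval(x0, y0, x1, y1, dwell, (cx, cy), magnification))

    for ev in trace.events:
        if ev.type not in _VIEW_EVENTS:
            continue
        emit(ev.t_ms)
        if ev.type == "fov_center_change":
            center = (float(ev.payload["x"]), float(ev.payload["y"]))
        else:
            magnification = float(ev.payload["factor"])
        open_t = ev.t_ms if center is not None else None
    emit(end_t)
    if center is None:
        raise EmptyTraceError("trace has no fov_center_change events", wsi=trace.wsi_id)
    return out


def attention_heatmap(
    trace: Trace,
    cell_px: int = 256,
    slide_size: tuple[int, int] | None = None,
    idle_cap_s: float = DEFAULT_IDLE_CAP_S,
) -> HeatmapGrid:
    """Accumulate dwell seconds on a grid of ``cell_px`` level-0 pixels.

    Each interval deposits its full dwell into every cell its rectangle
    intersects, so the grid total equals
    ``sum(dwell_i * covered_cell_count_i)`` — conservation checked by tests.
    """
    intervals = viewport_intervals(trace, slide_size=slide_size, idle_cap_s=idle_cap_s)
    if slide_size is not None:
        ncols = int(np.ceil(slide_size[0] / cell_px))
        nrows = int(np.ceil(slide_size[1] / cell_px))
    else:
        xmax = max(iv.x1 for iv in intervals)
        ymax = max(iv.y1 for iv in intervals)
        ncols = max(1, int(np.ceil(xmax / cell_px)))
        nrows = max(1, int(np.ceil(ymax / cell_px)))
    cells = np.zeros((nrows, ncols), dtype=float)
    total = 0.0
    for iv in intervals:
        c0 = max(0, int(np.floor(iv.x0 / cell_px)))
        c1 = min(ncols, int(np.ceil(iv.x1 / cell_px)))
        r0 = max(0, int(np.floor(iv.y0 / cell_px)))
        r1 = min(nrows, int(np.ceil(iv.y1 / cell_px)))
        if c1 > c0 and r1 > r0:
            cells[r0:r1, c0:c1] += iv.dwell_s
        total += iv.dwell_s
    return HeatmapGrid(cell_px=cell_px, cells=cells, total_dwell_s=total)


def dwell_by_region(
    trace: Trace,
    regions,
    slide_size: tuple[int, int] | None = None,
    idle_cap_s: float = DEFAULT_IDLE_CAP_S,
) -> dict[str, float]:
    """Attribute each interval's dwell to the region containing its center.

    A center inside several (overlapping) regions is attributed to the first
    containing region in document order, so the attributed total never
    exceeds the trace total.  Centers outside all regions are dropped.
    """
    from shapely.geometry import Point, Polygon

    polys = [(r.id, Polygon(r.polygon)) for r in regions]
    out: dict[str, float] = {}
    for iv in viewport_intervals(trace, slide_size=slide_size, idle_cap_s=idle_cap_s):
        pt = Point(iv.center)
        for rid, poly in polys:
            if poly.covers(pt):
                out[rid] = out.get(rid, 0.0) + iv.dwell_s
                break
    return out


def render_heatmap_png(grid: HeatmapGrid, path, colormap: str = "magma") -> Path:
    """Render the grid to a PNG, one image pixel per cell, deterministic."""
    import matplotlib
    from PIL import Image

    norm = grid.normalized()
    rgba = (matplotlib.colormaps[colormap](norm) * 255).astype(np.uint8)
    img = Image.fromarray(rgba[:, :, :3], mode="RGB")
    path = Path(path)
    img.save(path, format="PNG")
    return path


def write_heatmap_csv(grid: HeatmapGrid, path) -> Path:
    path = Path(path)
    np.savetxt(path, grid.cells, delimiter=",", fmt="%.6f")
    return path
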