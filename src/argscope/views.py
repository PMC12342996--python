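"""Assemble a browse store and a viewport into render-ready view payloads.

Five views: summary counts, edges (horizontal genome-interval segments at
parent or child time), mutations (position × time points weighted by
inheritor count), nodes (genomic span envelopes of ancestral nodes), and a
filter/sort/page table viewer.  Each browsable view carries linked
histograms computed from exactly the in-viewport subset, so the marginal
summaries always describe what is on screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .preprocess import BrowseStore
from .raster import (
    CountGrid,
    Viewport,
    default_log_delta,
    histogram1d,
    rasterize_points,
    rasterize_segments,
)

#: Above this many in-viewport items a view returns a raster instead of the
#: raw item list.
DENSITY_THRESHOLD = 50_000

DEFAULT_HIST_BINS = 20


@dataclass
class ViewData:
    view_name: str
    viewport: Viewport
    raster: CountGrid | None
    items: np.ndarray | None  # raw (below density threshold)
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    n_items: int
    y_scale: str = "linear"
    delta: float = 1.0
    annotations: list | None = None


def summary_view(store: BrowseStore) -> dict:
    out = dict(store.counts)
    out["sequence_length"] = store.sequence_length
    return out


def _finish(name, viewport, items, kind, histograms, width, height, delta,
            threshold):
    n = len(items)
    raster = None
    raw = items
    if n > threshold:
        raw = None
    if kind == "segments":
        raster = rasterize_segments(items, viewport, width, height, delta)
    else:
        raster = rasterize_points(items[:, :2] if n else items, viewport,
                                  width, height, delta)
    return ViewData(
        view_name=name,
        viewport=viewport,
        raster=raster,
        items=raw,
        histograms=histograms,
        n_items=n,
        y_scale=viewport.y_scale,
        delta=delta,
    )


def _hist(values, n_bins=DEFAULT_HIST_BINS):
    """Histogram covering the full value range, so the total equals the
    number of items (the linked-histogram contract)."""
    values = np.asarray(values, np.float64)
    if len(values) == 0:
        return np.zeros(n_bins, np.int64), np.linspace(0, 1, n_bins + 1)
    lo, hi = float(values.min()), float(values.max())
    if not lo < hi:
        lo, hi = lo - 0.5, hi + 0.5
    return histogram1d(values, n_bins, lo, hi)


def _store_delta(store: BrowseStore) -> float:
    return default_log_delta(store["nodes/time"])


def edges_view(
    store: BrowseStore,
    viewport: Viewport,
    y_mode: Literal["parent", "child"] = "child",
    width: int = 400,
    height: int = 300,
    threshold: int = DENSITY_THRESHOLD,
) -> ViewData:
    """Edges as horizontal segments (left, right, time of parent or child).

    Segments are clipped to the viewport; an edge is in view when its
    genome interval overlaps [x0, x1) and its y-time lies within [y0, y1].
    Histograms: branch_length, span (clipped), y-time.
    """
    left = store["edges/left"]
    right = store["edges/right"]
    node = store["edges/parent"] if y_mode == "parent" else \
        store["edges/child"]
    y = store["nodes/time"][node] if len(node) else np.empty(0)
    keep = (left < viewport.x1) & (right > viewport.x0) & \
        (y >= viewport.y0) & (y <= viewport.y1)
    cl = np.maximum(left[keep], viewport.x0)
    cr = np.minimum(right[keep], viewport.x1)
    segments = np.column_stack([cl, cr, y[keep]]) if np.any(keep) else \
        np.empty((0, 3))
    delta = _store_delta(store)
    histograms = {
        "branch_length": _hist(store["edges/branch_length"][keep]),
        "span": _hist(cr - cl),
        "time": _hist(y[keep]),
    }
    return _finish("edges", viewport, segments, "segments", histograms,
                   width, height, delta, threshold)


def mutations_view(
    store: BrowseStore,
    viewport: Viewport,
    width: int = 400,
    height: int = 300,
    threshold: int = DENSITY_THRESHOLD,
) -> ViewData:
    """Mutations as (position, plotted time) points; inheritor_count rides
    along as a per-point weight for tooltips.  Histograms: time,
    inheritor_count."""
    x = store["mutations/position"]
    y = store["mutations/time_plotted"]
    w = store["mutations/inheritor_count"]
    keep = (x >= viewport.x0) & (x < viewport.x1) & \
        (y >= viewport.y0) & (y <= viewport.y1)
    pts = np.column_stack([x[keep], y[keep], w[keep].astype(np.float64)]) \
        if np.any(keep) else np.empty((0, 3))
    histograms = {
        "time": _hist(y[keep]),
        "inheritor_count": _hist(w[keep]),
    }
    return _finish("mutations", viewport, pts, "points", histograms,
                   width, height, _store_delta(store), threshold)


def nodes_view(
    store: BrowseStore,
    viewport: Viewport,
    width: int = 400,
    height: int = 300,
    threshold: int = DENSITY_THRESHOLD,
) -> ViewData:
    """Ancestral (non-sample) nodes as horizontal span-envelope segments at
    the node's time.  Histograms: span (clipped), time."""
    flags = store["nodes/flags"]
    is_sample = (flags & 1) != 0
    sl = store["nodes/span_left"]
    sr = store["nodes/span_right"]
    t = store["nodes/time"]
    ok = (~is_sample) & (store["nodes/span"] > 0) & np.isfinite(sl)
    keep = ok & (sl < viewport.x1) & (sr > viewport.x0) & \
        (t >= viewport.y0) & (t <= viewport.y1)
    cl = np.clip(np.maximum(sl[keep], viewport.x0), 0, store.sequence_length)
    cr = np.clip(np.minimum(sr[keep], viewport.x1), 0, store.sequence_length)
    segments = np.column_stack([cl, cr, t[keep]]) if np.any(keep) else \
        np.empty((0, 3))
    histograms = {
        "span": _hist(cr - cl),
        "time": _hist(t[keep]),
    }
    return _finish("nodes", viewport, segments, "segments", histograms,
                   width, height, _store_delta(store), threshold)


# -- table viewer -------------------------------------------------------------

_FILTER_OPS = {
    "==": lambda s, v: s == v,
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
    "contains": lambda s, v: s.astype(str).str.contains(str(v), regex=False),
}


def store_dataframe(store: BrowseStore, table_name: str) -> pd.DataFrame:
    """Raw + feature columns of one table as a DataFrame indexed by row id."""
    prefix = table_name + "/"
    cols = {}
    for key in list(store.arrays) + list(store.strings):
        if key.startswith(prefix):
            cols[key[len(prefix):]] = store[key]
    if not cols:
        raise KeyError(f"unknown table {table_name!r}")
    df = pd.DataFrame(cols)
    df.insert(0, "id", np.arange(len(df)))
    return df


def table_query(
    store: BrowseStore,
    table_name: str,
    filters: list[tuple[str, str, object]] | None = None,
    sort: list[tuple[str, str]] | None = None,
    offset: int = 0,
    limit: int | None = None,
) -> pd.DataFrame:
    """Filter (ANDed), sort (stable, final tie-break on row id), then page.

    Raises KeyError / ValueError naming an unknown column or operator.
    """
    df = store_dataframe(store, table_name)
    for column, op, value in filters or []:
        if column not in df.columns:
            raise KeyError(f"unknown column {column!r} in {table_name}")
        if op not in _FILTER_OPS:
            raise ValueError(f"unknown filter op {op!r}")
        df = df[_FILTER_OPS[op](df[column], value)]
    if sort:
        columns, ascending = [], []
        for column, direction in sort:
            if column not in df.columns:
                raise KeyError(f"unknown sort column {column!r}")
            if direction not in ("asc", "desc"):
                raise ValueError(f"unknown sort direction {direction!r}")
            columns.append(column)
            ascending.append(direction == "asc")
        columns.append("id")
        ascending.append(True)
        df = df.sort_values(columns, ascending=ascending, kind="stable")
    start = max(0, int(offset))
    stop = None if limit is None else start + int(limit)
    return df.iloc[start:stop].reset_index(drop=True)


# -- static export ------------------------------------------------------------


def _colormap_image(grid: CountGrid):
    """Map counts through a perceptually uniform colormap to RGB bytes.

    Deterministic: depends only on the counts.  Row 0 (recent time) is
    drawn at the bottom.
    """
    import matplotlib

    counts = grid.counts[::-1].astype(np.float64)
    top = counts.max()
    norm = np.log1p(counts) / np.log1p(top) if top > 0 else counts
    rgba = matplotlib.colormaps["viridis"](norm)
    rgba[counts == 0] = [1.0, 1.0, 1.0, 1.0]
    return (rgba[..., :3] * 255).astype(np.uint8)


def render_png_bytes(view: ViewData, scale: int = 1) -> bytes:
    """Rasterize a view's grid to PNG bytes (byte-deterministic)."""
    import io

    from PIL import Image

    rgb = _colormap_image(view.raster)
    img = Image.fromarray(rgb, "RGB")
    if scale > 1:
        img = img.resize((img.width * scale, img.height * scale),
                         Image.NEAREST)
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def render_static(view: ViewData, path, format: str = "png") -> None:
    """Write a deterministic snapshot of a view: ``png`` (the count grid
    through a colormap) or ``html`` (grid image inlined plus histogram
    tables)."""
    import base64

    if format == "png":
        with open(path, "wb") as fh:
            fh.write(render_png_bytes(view))
    elif format == "html":
        png = base64.b64encode(render_png_bytes(view)).decode()
        rows = []
        for name, (counts, edges) in view.histograms.items():
            rows.append(
                f"<h3>{name}</h3><pre>{list(map(int, counts))}</pre>"
            )
        html = (
            "<!DOCTYPE html><html><body>"
            f"<h2>{view.view_name} view</h2>"
            f'<img src="data:image/png;base64,{png}"/>'
            + "".join(rows)
            + "</body></html>"
        )
        with open(path, "w") as fh:
            fh.write(html)
    else:
        raise ValueError(f"unsupported format {format!r}")


def full_viewport(store: BrowseStore, y_scale: str = "linear") -> Viewport:
    """The whole genome × the full node-time range of the store."""
    t = store["nodes/time"]
    y1 = float(t.max()) if len(t) else 1.0
    if y1 <= 0:
        y1 = 1.0
    return Viewport(0.0, store.sequence_length, 0.0, y1, y_scale)


def column_coverage(store: BrowseStore, n_columns: int = 300,
                    y_mode: str = "parent") -> np.ndarray:
    """Per-column edge-segment coverage over the full viewport (the signal
    behind the sweep wedge: fewer segments cross the centre)."""
    vp = full_viewport(store)
    view = edges_view(store, vp, y_mode=y_mode, width=n_columns, height=1)
    return view.raster.counts.sum(axis=0)


def wedge_statistics(store: BrowseStore, n_columns: int = 300) -> dict:
    """Mean per-column coverage of the central third vs the flanking
    thirds of the genome."""
    cov = column_coverage(store, n_columns)
    third = n_columns // 3
    center = float(cov[third:2 * third].mean())
    flanks = float(np.concatenate([cov[:third], cov[2 * third:]]).mean())
    return {"center_mean": center, "flank_mean": flanks}
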