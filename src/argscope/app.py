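"""Command-line interface and web service.

Two commands mirror the two-stage workflow: ``preprocess`` turns an ARG
file into a browse store, ``serve`` exposes the store over HTTP so the ARG
can stay in place on the machine that holds it while a browser elsewhere
pans and zooms.  Every HTTP payload is a thin shim over the views module:
the server holds the store in memory, re-rasterizes on each viewport
request, and never writes to the store file.

Annotation files (BED / GFF3 / CSV) supply genomic intervals to overlay on
the genome axis.  The model has a single linear coordinate system, so
sequence names are ignored unless a ``contig`` filter is given.
"""

from __future__ import annotations

import hashlib
import json
import sys
import threading
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from urllib.parse import parse_qs, urlparse

import click
import numpy as np

from . import preprocess, ts_model, views
from .raster import Viewport


class AnnotationError(ValueError):
    def __init__(self, message, path=None, line=None):
        loc = f" [{path}:{line}]" if path is not None else ""
        super().__init__(message + loc)
        self.line = line


@dataclass
class AnnotationTrack:
    """Labelled genomic intervals, 0-based half-open, one linear axis."""

    intervals: list[tuple[float, float, str, str]]  # (start, end, label, strand)
    source_format: str

    def query(self, x0: float, x1: float) -> list[tuple]:
        """Intervals overlapping [x0, x1)."""
        return [iv for iv in self.intervals if iv[0] < x1 and iv[1] > x0]

    def clipped(self, sequence_length: float) -> "AnnotationTrack":
        out = []
        for start, end, label, strand in self.intervals:
            s, e = max(0.0, start), min(sequence_length, end)
            if s < e:
                out.append((s, e, label, strand))
        return AnnotationTrack(out, self.source_format)


def parse_annotations(path, format: str, contig: str | None = None
                      ) -> AnnotationTrack:
    """Read an annotation file into a track.

    BED is taken verbatim (already 0-based half-open); GFF3 is converted
    from 1-based closed (start-1, end); CSV must have ``start,end,label``
    columns and is declared 0-based half-open.
    """
    path = Path(path)
    intervals: list[tuple[float, float, str, str]] = []

    def add(start, end, label, strand, lineno):
        if not end > start:
            raise AnnotationError(
                f"interval end {end} <= start {start}", path, lineno
            )
        intervals.append((float(start), float(end), label, strand))

    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 3:
                    raise AnnotationError("BED line needs >= 3 fields",
                                          path, lineno)
                if contig is not None and f[0] != contig:
                    continue
                label = f[3] if len(f) > 3 else ""
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
                add(float(f[1]), float(f[2]), label, strand, lineno)
    elif format == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise AnnotationError("GFF3 line needs 9 fields",
                                          path, lineno)
                if contig is not None and f[0] != contig:
                    continue
                label = f[2]
                for part in f[8].split(";"):
                    if part.startswith(("Name=", "ID=")):
                        label = part.split("=", 1)[1]
                        break
                strand = f[6] if f[6] in "+-" else "."
                add(float(f[3]) - 1, float(f[4]), label, strand, lineno)
    elif format == "csv":
        import csv as _csv

        with open(path) as fh:
            reader = _csv.DictReader(fh)
            missing = {"start", "end", "label"} - set(reader.fieldnames or [])
            if missing:
                raise AnnotationError(
                    f"CSV missing columns: {sorted(missing)}", path, 1
                )
            for lineno, row in enumerate(reader, 2):
                if contig is not None and row.get("contig", contig) != contig:
                    continue
                add(float(row["start"]), float(row["end"]),
                    row["label"], row.get("strand", "."), lineno)
    else:
        raise AnnotationError(f"unsupported annotation format {format!r}")
    return AnnotationTrack(intervals, format)


# -- HTTP service -------------------------------------------------------------


def _viewport_from_query(q, store) -> Viewport:
    if "x0" in q:
        return Viewport(
            float(q["x0"][0]), float(q["x1"][0]),
            float(q["y0"][0]), float(q["y1"][0]),
            q.get("y_scale", ["linear"])[0],
        )
    return views.full_viewport(store)


def _grid_payload(grid):
    return {
        "counts": grid.counts.tolist(),
        "x_bin_edges": grid.x_bin_edges.tolist(),
        "y_bin_edges": grid.y_bin_edges.tolist(),
    }


def view_payload(store, name: str, viewport: Viewport,
                 width=400, height=300, y_mode="child",
                 track: AnnotationTrack | None = None) -> dict:
    """JSON-ready payload for one view; the HTTP API returns exactly this."""
    if name == "edges":
        vd = views.edges_view(store, viewport, y_mode=y_mode,
                              width=width, height=height)
    elif name == "mutations":
        vd = views.mutations_view(store, viewport, width=width, height=height)
    elif name == "nodes":
        vd = views.nodes_view(store, viewport, width=width, height=height)
    else:
        raise KeyError(f"unknown view {name!r}")
    payload = {
        "view": vd.view_name,
        "viewport": [viewport.x0, viewport.x1, viewport.y0, viewport.y1],
        "y_scale": vd.y_scale,
        "delta": vd.delta,
        "n_items": vd.n_items,
        "grid": _grid_payload(vd.raster),
        "items": None if vd.items is None else vd.items.tolist(),
        "histograms": {
            k: {"counts": c.tolist(), "bin_edges": e.tolist()}
            for k, (c, e) in vd.histograms.items()
        },
    }
    if track is not None:
        payload["annotations"] = track.clipped(store.sequence_length).query(
            viewport.x0, viewport.x1
        )
    return payload


_DASHBOARD = """<!DOCTYPE html>
<html><head><title>argscope</title></head>
<body>
<h1>argscope ARG browser</h1>
<p>Summary: <code id="summary"></code></p>
<div>
  <img id="edges" alt="edges view"/>
  <img id="mutations" alt="mutations view"/>
  <img id="nodes" alt="nodes view"/>
</div>
<script>
fetch('/api/summary').then(r => r.json()).then(s => {
  document.getElementById('summary').textContent = JSON.stringify(s);
});
for (const v of ['edges', 'mutations', 'nodes']) {
  document.getElementById(v).src = '/raster/' + v + '.png';
}
</script>
</body></html>
"""


class BrowseServer:
    """HTTP wrapper around a read-only browse store."""

    def __init__(self, store: preprocess.BrowseStore,
                 track: AnnotationTrack | None = None,
                 host: str = "127.0.0.1", port: int = 0):
        self.store = store
        self.track = track
        outer = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):
                pass

            def _send(self, body: bytes, content_type: str, status=200):
                self.send_response(status)
                self.send_header("Content-Type", content_type)
                self.send_header("Content-Length", str(len(body)))
                self.end_headers()
                self.wfile.write(body)

            def _send_json(self, obj, status=200):
                self._send(json.dumps(obj).encode(), "application/json",
                           status)

            def do_GET(self):
                try:
                    url = urlparse(self.path)
                    q = parse_qs(url.query)
                    if url.path in ("/", "/index.html"):
                        self._send(_DASHBOARD.encode(), "text/html")
                    elif url.path == "/api/summary":
                        self._send_json(views.summary_view(outer.store))
                    elif url.path.startswith("/api/view/"):
                        name = url.path.rsplit("/", 1)[1]
                        vp = _viewport_from_query(q, outer.store)
                        self._send_json(view_payload(
                            outer.store, name, vp,
                            width=int(q.get("width", [400])[0]),
                            height=int(q.get("height", [300])[0]),
                            y_mode=q.get("y_mode", ["child"])[0],
                            track=outer.track,
                        ))
                    elif url.path.startswith("/raster/"):
                        name = url.path.rsplit("/", 1)[1].removesuffix(".png")
                        vp = _viewport_from_query(q, outer.store)
                        if name == "edges":
                            vd = views.edges_view(outer.store, vp)
                        elif name == "mutations":
                            vd = views.mutations_view(outer.store, vp)
                        elif name == "nodes":
                            vd = views.nodes_view(outer.store, vp)
                        else:
                            self._send_json({"error": "unknown view"}, 404)
                            return
                        self._send(views.render_png_bytes(vd), "image/png")
                    elif url.path == "/api/annotations":
                        track = outer.track
                        ivs = [] if track is None else track.intervals
                        self._send_json({"intervals": ivs})
                    else:
                        self._send_json({"error": "not found"}, 404)
                except BrokenPipeError:
                    pass
                except Exception as err:  # surface errors to the client
                    self._send_json({"error": str(err)}, 500)

        try:
            self.httpd = ThreadingHTTPServer((host, port), Handler)
        except OSError as err:
            raise OSError(f"cannot bind {host}:{port}: {err}") from err
        self.port = self.httpd.server_address[1]
        self._thread: threading.Thread | None = None

    def start_background(self):
        self._thread = threading.Thread(
            target=self.httpd.serve_forever, daemon=True
        )
        self._thread.start()

    def serve_forever(self):
        self.httpd.serve_forever()

    def shutdown(self):
        self.httpd.shutdown()
        self.httpd.server_close()
        if self._thread is not None:
            self._thread.join()


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# -- CLI ----------------------------------------------------------------------


@click.group()
def main():
    """Interactive browser for ancestral recombination graphs."""


@main.command("preprocess")
@click.argument("input_path", type=click.Path(exists=True))
@click.option("-o", "--output", "output_path", required=True,
              type=click.Path())
@click.option("--force", is_flag=True,
              help="Overwrite an existing output file.")
def cli_preprocess(input_path, output_path, force):
    """Augment an ARG file with visualization columns into a browse store."""
    if Path(output_path).exists() and not force:
        click.echo(
            f"error: {output_path} exists; use --force to overwrite",
            err=True,
        )
        sys.exit(1)
    try:
        ts = ts_model.load_tree_sequence(input_path)
        store = preprocess.build_store(ts, source_path=str(input_path))
    except preprocess.ValidationFailure as err:
        click.echo("error: input failed validation:", err=True)
        for v in err.violations:
            click.echo(f"  {v}", err=True)
        sys.exit(1)
    except ts_model.FormatError as err:
        click.echo(f"error: {err}", err=True)
        sys.exit(1)
    preprocess.write_store(store, output_path)
    for key, value in views.summary_view(store).items():
        click.echo(f"{key}: {value}")


@main.command("serve")
@click.argument("store_path", type=click.Path(exists=True))
@click.option("--port", default=8080, show_default=True)
@click.option("--host", default="127.0.0.1", show_default=True)
@click.option("--annotations", "annotation_path", type=click.Path(exists=True))
@click.option("--annotation-format", default="bed",
              type=click.Choice(["bed", "gff3", "csv"]), show_default=True)
@click.option("--contig", default=None)
def cli_serve(store_path, port, host, annotation_path, annotation_format,
              contig):
    """Serve the dashboard for a preprocessed store over HTTP."""
    try:
        store = preprocess.read_store(store_path)
    except preprocess.StoreVersionError as err:
        click.echo(f"error: {err}", err=True)
        sys.exit(1)
    track = None
    if annotation_path:
        track = parse_annotations(annotation_path, annotation_format, contig)
    server = BrowseServer(store, track, host=host, port=port)
    click.echo(f"serving on http://{host}:{server.port}/")
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        server.shutdown()
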