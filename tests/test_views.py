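"""View assembly: segments/points, clipping, linked histograms, table
queries, static export, sweep wedge."""

import numpy as np
import pytest

from argscope import views
from argscope.raster import Viewport
from argscope.views import (
    edges_view,
    mutations_view,
    nodes_view,
    render_static,
    summary_view,
    table_query,
)
from conftest import random_viewport


class TestSummaryView:
    def test_canonical_counts(self, canonical_store):
        s = summary_view(canonical_store)
        assert s == {
            "nodes": 5, "edges": 7, "sites": 2, "mutations": 3, "trees": 2,
            "sequence_length": 10.0,
        }

    def test_round_trip_invariant(self, canonical_store, tmp_path):
        from argscope.preprocess import read_store, write_store

        path = tmp_path / "c.tsb"
        write_store(canonical_store, path)
        assert summary_view(read_store(path)) == summary_view(canonical_store)


class TestEdgesView:
    def test_full_viewport_parent_mode(self, canonical_store):
        vd = edges_view(
            canonical_store, views.full_viewport(canonical_store),
            y_mode="parent",
        )
        assert vd.n_items == 7
        assert set(vd.items[:, 2]) == {1.0, 2.0}

    def test_clipping(self, canonical_store):
        vd = edges_view(
            canonical_store, Viewport(0, 5, 0, 3), y_mode="parent"
        )
        # the (0, 10, 4, 3) edge is clipped to span 5
        spans = vd.items[:, 1] - vd.items[:, 0]
        assert spans.max() == 5.0

    def test_child_mode_all_samples(self):
        from argscope import preprocess, ts_model

        ts = ts_model.TreeSequenceData(
            sequence_length=10.0,
            nodes=ts_model.NodeTable(
                [0.0, 0.0, 1.0], [1, 1, 0], [-1] * 3, [-1] * 3
            ),
            edges=ts_model.EdgeTable([0, 0], [10, 10], [2, 2], [0, 1]),
        )
        store = preprocess.build_store(ts)
        vd = edges_view(store, views.full_viewport(store), y_mode="child")
        assert np.all(vd.items[:, 2] == 0.0)

    def test_linked_histograms_count_in_viewport_items(self, sim_store):
        rng = np.random.default_rng(10)
        t_max = float(sim_store["nodes/time"].max())
        for _ in range(20):
            vp = random_viewport(rng, sim_store.sequence_length, t_max)
            vd = edges_view(sim_store, vp)
            for name, (counts, _) in vd.histograms.items():
                assert counts.sum() == vd.n_items, name

    def test_raster_equals_raw_rasterization(self, sim_store):
        from argscope.raster import rasterize_segments

        vp = views.full_viewport(sim_store)
        vd = edges_view(sim_store, vp, width=40, height=30)
        assert vd.items is not None  # below density threshold
        again = rasterize_segments(vd.items, vp, 40, 30, vd.delta)
        assert np.array_equal(vd.raster.counts, again.counts)


class TestMutationsView:
    def test_full_viewport_points(self, canonical_store):
        vd = mutations_view(
            canonical_store, views.full_viewport(canonical_store)
        )
        assert vd.n_items == 3
        assert sorted(vd.items[:, 0]) == [2.0, 2.0, 7.0]

    def test_x_window_membership(self, canonical_store):
        vd = mutations_view(canonical_store, Viewport(5, 10, 0, 3))
        assert vd.n_items == 1
        assert vd.items[0, 0] == 7.0

    def test_empty_window(self, canonical_store):
        vd = mutations_view(canonical_store, Viewport(3, 4, 0, 3))
        assert vd.n_items == 0
        assert all(c.sum() == 0 for c, _ in vd.histograms.values())

    def test_inheritor_count_is_point_weight(self, canonical_store):
        vd = mutations_view(
            canonical_store, views.full_viewport(canonical_store)
        )
        by_pos = {(p, w) for p, _, w in vd.items}
        assert (2.0, 2.0) in by_pos  # m0: position 2.0, 2 inheritors


class TestNodesView:
    def test_canonical_two_internal_segments(self, canonical_store):
        vd = nodes_view(canonical_store, views.full_viewport(canonical_store))
        assert vd.n_items == 2
        assert {tuple(s[:2]) for s in vd.items} == {(0.0, 10.0)}
        assert sorted(s[2] for s in vd.items) == [1.0, 2.0]

    def test_zero_span_nodes_hidden(self):
        from argscope import preprocess, ts_model

        ts = ts_model.TreeSequenceData(
            sequence_length=10.0,
            nodes=ts_model.NodeTable(
                [0.0, 0.0, 1.0, 4.0], [1, 1, 0, 0], [-1] * 4, [-1] * 4
            ),
            edges=ts_model.EdgeTable([0, 0], [10, 10], [2, 2], [0, 1]),
        )
        store = preprocess.build_store(ts)
        vd = nodes_view(store, views.full_viewport(store))
        assert vd.n_items == 1  # node 3 has no edges: not rendered

    def test_segments_within_sequence_bounds(self, sim_store):
        vd = nodes_view(sim_store, views.full_viewport(sim_store))
        assert np.all(vd.items[:, 0] >= 0)
        assert np.all(vd.items[:, 1] <= sim_store.sequence_length)


class TestTableQuery:
    def test_span_filter_finds_root_edge(self, canonical_store):
        rows = table_query(
            canonical_store, "edges", filters=[("span", ">=", 10)]
        )
        assert len(rows) == 1
        row = rows.iloc[0]
        assert (row.left, row.right, row.parent, row.child) == (0, 10, 4, 3)

    def test_sort_desc_limit_with_id_tiebreak(self, canonical_store):
        rows = table_query(
            canonical_store, "edges", sort=[("area", "desc")], limit=1
        )
        assert rows.iloc[0].area == 10.0
        # ties on area broken by id: the first max-area edge in table order
        full = table_query(canonical_store, "edges",
                           sort=[("area", "desc")])
        top_ids = full[full.area == 10.0].id.tolist()
        assert rows.iloc[0].id == min(top_ids)

    def test_offset_beyond_length_empty(self, canonical_store):
        rows = table_query(canonical_store, "edges", offset=100)
        assert len(rows) == 0

    def test_unknown_column_and_op_named(self, canonical_store):
        with pytest.raises(KeyError, match="nope"):
            table_query(canonical_store, "edges",
                        filters=[("nope", "==", 1)])
        with pytest.raises(ValueError, match="!="):
            table_query(canonical_store, "edges",
                        filters=[("span", "!=", 1)])

    def test_contains_on_string_column(self, canonical_store):
        rows = table_query(
            canonical_store, "mutations",
            filters=[("derived_state", "contains", "T")],
        )
        assert len(rows) == 1


class TestRenderStatic:
    def test_png_nonempty(self, canonical_store, tmp_path):
        vd = edges_view(canonical_store, views.full_viewport(canonical_store))
        path = tmp_path / "edges.png"
        render_static(vd, path, "png")
        assert path.stat().st_size > 0
        assert path.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_byte_deterministic(self, canonical_store, tmp_path):
        vp = views.full_viewport(canonical_store)
        a, b = tmp_path / "a.png", tmp_path / "b.png"
        render_static(edges_view(canonical_store, vp), a, "png")
        render_static(edges_view(canonical_store, vp), b, "png")
        assert a.read_bytes() == b.read_bytes()

    def test_html_export(self, canonical_store, tmp_path):
        vd = mutations_view(canonical_store,
                            views.full_viewport(canonical_store))
        path = tmp_path / "m.html"
        render_static(vd, path, "html")
        assert "data:image/png" in path.read_text()

    def test_unsupported_format(self, canonical_store, tmp_path):
        vd = edges_view(canonical_store, views.full_viewport(canonical_store))
        with pytest.raises(ValueError, match="svg"):
            render_static(vd, tmp_path / "x.svg", "svg")


class TestSweepWedge:
    def test_center_coverage_below_flanks(self, sweep_store):
        w = views.wedge_statistics(sweep_store)
        assert w["center_mean"] < w["flank_mean"]

    def test_wedge_visible_in_png_grid(self, sweep_store, tmp_path):
        vd = edges_view(
            sweep_store, views.full_viewport(sweep_store),
            width=300, height=100,
        )
        render_static(vd, tmp_path / "sweep.png", "png")
        col = vd.raster.counts.sum(axis=0)
        third = len(col) // 3
        center = col[third:2 * third].mean()
        flanks = np.concatenate([col[:third], col[2 * third:]]).mean()
        assert center < flanks


class TestViewportMonotonicity:
    def test_shrinking_never_gains_items(self, sim_store):
        rng = np.random.default_rng(77)
        t_max = float(sim_store["nodes/time"].max())
        full = views.full_viewport(sim_store)
        n_full = mutations_view(sim_store, full).n_items
        for _ in range(20):
            vp = random_viewport(rng, sim_store.sequence_length, t_max)
            assert mutations_view(sim_store, vp).n_items <= n_full
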