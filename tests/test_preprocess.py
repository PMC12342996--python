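"""Feature computation (including the incremental sweep) and the store."""

import numpy as np
import pytest

from argscope import fixtures, preprocess, ts_model
from argscope.preprocess import (
    StoreCorruptionError,
    StoreVersionError,
    ValidationFailure,
    build_store,
    compute_edge_features,
    compute_mutation_features,
    compute_node_spans,
    compute_site_features,
    inheritor_counts_naive,
    read_store,
    write_store,
)


def per_tree_area(ts):
    """Oracle: sum over trees of span x total branch length."""
    bp = ts_model.breakpoints(ts)
    total = 0.0
    for lo, hi in zip(bp, bp[1:]):
        active = (ts.edges.left <= lo) & (ts.edges.right >= hi)
        bl = (
            ts.nodes.time[ts.edges.parent[active]]
            - ts.nodes.time[ts.edges.child[active]]
        ).sum()
        total += (hi - lo) * bl
    return total


class TestEdgeFeatures:
    def test_arithmetic(self):
        ts = ts_model.TreeSequenceData(
            sequence_length=10.0,
            nodes=ts_model.NodeTable([1.0, 2.0], [1, 0], [-1, -1], [-1, -1]),
            edges=ts_model.EdgeTable([0.0], [10.0], [1], [0]),
        )
        ef = compute_edge_features(ts)
        assert ef.branch_length[0] == 1.0
        assert ef.span[0] == 10.0
        assert ef.area[0] == 10.0

    def test_canonical_edge_area(self, canonical):
        ef = compute_edge_features(canonical)
        # edge (0, 5, parent 4 @ t=2, child 2 @ t=0) has area 5 * 2 = 10
        i = np.flatnonzero(
            (canonical.edges.parent == 4) & (canonical.edges.child == 2)
        )[0]
        assert ef.area[i] == 10.0

    def test_canonical_total_area(self, canonical):
        assert compute_edge_features(canonical).area.sum() == 50.0

    @pytest.mark.parametrize("seed", range(50))
    def test_area_conservation_random_args(self, seed):
        ts = fixtures.simulate_wf_arg(
            fixtures.SimParams(n_samples=3 + seed % 10, seed=1000 + seed)
        )
        total = compute_edge_features(ts).area.sum()
        oracle = per_tree_area(ts)
        assert total == pytest.approx(oracle, rel=1e-9)


class TestNodeSpans:
    def test_canonical_node3(self, canonical):
        nf = compute_node_spans(canonical)
        assert nf.span_left[3] == 0.0
        assert nf.span_right[3] == 10.0
        assert nf.span[3] == 10.0

    def test_isolated_node(self):
        ts = ts_model.TreeSequenceData(
            sequence_length=10.0,
            nodes=ts_model.NodeTable(
                [0.0, 0.0, 1.0, 5.0], [1, 1, 0, 0], [-1] * 4, [-1] * 4
            ),
            edges=ts_model.EdgeTable([0, 0], [10, 10], [2, 2], [0, 1]),
        )
        nf = compute_node_spans(ts)
        assert nf.span[3] == 0.0
        assert np.isnan(nf.span_left[3]) and np.isnan(nf.span_right[3])

    def test_every_edge_inside_both_envelopes(self):
        ts = fixtures.simulate_wf_arg(fixtures.SimParams(n_samples=12, seed=2))
        nf = compute_node_spans(ts)
        for i in range(len(ts.edges)):
            for node in (ts.edges.parent[i], ts.edges.child[i]):
                assert nf.span_left[node] <= ts.edges.left[i]
                assert nf.span_right[node] >= ts.edges.right[i]

    def test_node_mutation_counts(self, canonical):
        nf = compute_node_spans(canonical)
        assert nf.num_mutations[3] == 1  # m0
        assert nf.num_mutations[0] == 2  # m1, m2


class TestMutationFeatures:
    def test_canonical_values(self, canonical):
        mf = compute_mutation_features(canonical)
        m = canonical.mutations
        # mutations identified by (site, node); table is site-sorted
        m0 = int(np.flatnonzero((m.site == 0) & (m.node == 3))[0])
        m1 = int(np.flatnonzero(m.site == 1)[0])
        m2 = int(np.flatnonzero((m.site == 0) & (m.node == 0))[0])
        # m0 on node 3 at position 2.0 subtends samples {0, 1}
        assert mf.inheritor_count[m0] == 2
        # m1 on sample node 0 at position 7.0
        assert mf.inheritor_count[m1] == 1
        # m1 imputed time: midpoint of node 0 (t=0) and its local parent 3
        assert mf.time_plotted[m1] == 0.5
        # m0 imputed time: midpoint of node 3 (t=1) and root 4 (t=2)
        assert mf.time_plotted[m0] == 1.5
        assert mf.chain_depth[m0] == 0 and mf.chain_depth[m2] == 1
        assert mf.warnings == []

    def test_local_root_mutation_uses_node_time(self):
        ts = fixtures.canonical_example()
        ts.mutations.node[0] = 4  # the root at both trees
        mf = compute_mutation_features(ts)
        assert mf.inheritor_count[0] == 3
        assert mf.time_plotted[0] == 2.0

    def test_detached_node_warns_not_crashes(self):
        ts = ts_model.TreeSequenceData(
            sequence_length=10.0,
            nodes=ts_model.NodeTable(
                [0.0, 0.0, 1.0, 5.0], [1, 1, 0, 0], [-1] * 4, [-1] * 4
            ),
            edges=ts_model.EdgeTable([0, 0], [10, 10], [2, 2], [0, 1]),
            sites=ts_model.SiteTable([4.0], ["A"]),
            mutations=ts_model.MutationTable(
                [0], [3], ["T"], [-1], [np.nan]
            ),
        )
        mf = compute_mutation_features(ts)
        assert mf.inheritor_count[0] == 0
        assert len(mf.warnings) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_sweep_equals_naive_dfs(self, seed):
        ts = fixtures.simulate_wf_arg(
            fixtures.SimParams(n_samples=4 + seed % 17, seed=2000 + seed)
        )
        mf = compute_mutation_features(ts)
        assert np.array_equal(mf.inheritor_count, inheritor_counts_naive(ts))

    def test_sweep_equals_tskit_oracle(self):
        # independent ecosystem oracle: tskit's own per-tree sample counts
        msprime = pytest.importorskip("msprime")
        tsk = msprime.sim_ancestry(
            8, sequence_length=5e3, recombination_rate=2e-4,
            population_size=50, random_seed=11,
        )
        tsk = msprime.sim_mutations(tsk, rate=2e-4, random_seed=11)
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            p = os.path.join(d, "t.trees")
            tsk.dump(p)
            ts = ts_model.load_tree_sequence(p)
        mf = compute_mutation_features(ts)
        expected = np.zeros(tsk.num_mutations, dtype=int)
        for tree in tsk.trees():
            for site in tree.sites():
                for mut in site.mutations:
                    expected[mut.id] = tree.num_samples(mut.node)
        assert np.array_equal(mf.inheritor_count, expected)


class TestSiteFeatures:
    def test_canonical_counts(self, canonical):
        sf = compute_site_features(canonical)
        assert list(sf.num_mutations) == [2, 1]

    def test_conservation(self, sim_store):
        assert (
            sim_store["sites/num_mutations"].sum()
            == sim_store.counts["mutations"]
        )


class TestStore:
    def test_canonical_summary_counts(self, canonical_store):
        assert canonical_store.counts == {
            "nodes": 5, "edges": 7, "sites": 2, "mutations": 3, "trees": 2,
        }

    def test_empty_mutation_arrays_present(self):
        ts = fixtures.canonical_example()
        ts.mutations = ts_model.MutationTable()
        ts.sites = ts_model.SiteTable()
        store = build_store(ts)
        assert len(store["mutations/inheritor_count"]) == 0
        assert store.counts["mutations"] == 0

    def test_build_deterministic_modulo_timestamp(self, canonical):
        a = build_store(canonical)
        b = build_store(canonical)
        assert a.equals(b)

    def test_invalid_input_aborts_with_violations(self):
        ts = fixtures.canonical_example()
        ts.edges.parent[0] = 99
        with pytest.raises(ValidationFailure) as err:
            build_store(ts)
        assert err.value.violations[0].kind == "edge_node_ref"

    def test_permutation_stability(self):
        ts = fixtures.simulate_wf_arg(fixtures.SimParams(n_samples=10, seed=5))
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ts.edges))
        shuffled = ts_model.TreeSequenceData(
            sequence_length=ts.sequence_length,
            nodes=ts.nodes,
            edges=ts_model.EdgeTable(
                ts.edges.left[perm], ts.edges.right[perm],
                ts.edges.parent[perm], ts.edges.child[perm],
            ),
            sites=ts.sites,
            mutations=ts.mutations,
        )
        assert build_store(ts).equals(build_store(shuffled))

    def test_round_trip_bit_identical(self, canonical_store, tmp_path):
        path = tmp_path / "c.tsb"
        write_store(canonical_store, path)
        assert read_store(path).equals(canonical_store)

    def test_round_trip_simulated(self, sim_store, tmp_path):
        path = tmp_path / "s.tsb"
        write_store(sim_store, path)
        assert read_store(path).equals(sim_store)

    def test_missing_key_is_corruption_error(self, canonical_store, tmp_path):
        import zipfile

        path = tmp_path / "c.tsb"
        write_store(canonical_store, path)
        tampered = tmp_path / "bad.tsb"
        with zipfile.ZipFile(path) as zin, \
                zipfile.ZipFile(tampered, "w") as zout:
            for item in zin.infolist():
                if item.filename.startswith("edges/area/"):
                    continue
                zout.writestr(item, zin.read(item.filename))
        with pytest.raises(StoreCorruptionError, match="edges/area"):
            read_store(tampered)

    def test_version_mismatch_rejected(self, canonical_store, tmp_path,
                                       monkeypatch):
        path = tmp_path / "c.tsb"
        store = canonical_store
        store.metadata["format_version"] = "99.0"
        write_store(store, path)
        with pytest.raises(StoreVersionError, match="99.0"):
            read_store(path)

    def test_compression_beats_raw_bytes(self, tmp_path):
        ts = fixtures.simulate_wf_arg(
            fixtures.SimParams(n_samples=100, sequence_length=500.0, seed=8)
        )
        store = build_store(ts)
        path = tmp_path / "big.tsb"
        write_store(store, path)
        raw = sum(a.nbytes for a in store.arrays.values())
        assert path.stat().st_size < raw
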