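"""Augment ARG tables with visualization-ready feature columns and persist
them in a compressed keyed-array container (the browse store).

The centrepiece is the incremental local-tree sweep used to count, for every
mutation, how many sample genomes inherit it: a single left-to-right pass
over the genome maintains the current tree as a parent array plus per-node
subtree sample counts, updating both as edges are inserted and removed at
breakpoints.  This turns what would be an O(sites × samples) recomputation
into an O(edges + mutations) pass, which is what makes genome-scale ARGs
browsable.
"""

from __future__ import annotations

import datetime
import json
import uuid
from dataclasses import dataclass, field

import numpy as np

from . import ts_model
from .ts_model import NULL, TreeSequenceData, Violation

FORMAT_VERSION = "1.0"


class StoreVersionError(RuntimeError):
    """Store written by an unsupported format version."""


class StoreCorruptionError(RuntimeError):
    """A required array key is missing from the store."""


class ValidationFailure(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "input failed validation: "
            + "; ".join(str(v) for v in violations[:10])
            + ("..." if len(violations) > 10 else "")
        )


@dataclass
class EdgeFeatures:
    branch_length: np.ndarray  # time(parent) - time(child)
    span: np.ndarray  # right - left
    area: np.ndarray  # span * branch_length


@dataclass
class NodeFeatures:
    span_left: np.ndarray  # NaN for nodes in no edge
    span_right: np.ndarray
    span: np.ndarray  # 0 for nodes in no edge
    num_mutations: np.ndarray


@dataclass
class MutationFeatures:
    position: np.ndarray
    inheritor_count: np.ndarray
    time_plotted: np.ndarray
    chain_depth: np.ndarray
    warnings: list[str] = field(default_factory=list)


@dataclass
class SiteFeatures:
    num_mutations: np.ndarray


def compute_edge_features(ts: TreeSequenceData) -> EdgeFeatures:
    e = ts.edges
    branch_length = ts.nodes.time[e.parent] - ts.nodes.time[e.child]
    span = e.right - e.left
    return EdgeFeatures(branch_length, span, span * branch_length)


def compute_node_spans(ts: TreeSequenceData) -> NodeFeatures:
    """Genomic span envelope of each node over all edges it participates in,
    as parent or child.  Nodes appearing in no edge get NaN bounds, span 0.
    """
    n = len(ts.nodes)
    span_left = np.full(n, np.inf)
    span_right = np.full(n, -np.inf)
    for which in (ts.edges.parent, ts.edges.child):
        np.minimum.at(span_left, which, ts.edges.left)
        np.maximum.at(span_right, which, ts.edges.right)
    isolated = ~np.isfinite(span_left)
    span = np.where(isolated, 0.0, span_right - span_left)
    span_left[isolated] = np.nan
    span_right[isolated] = np.nan
    num_mutations = np.bincount(
        ts.mutations.node, minlength=n
    ).astype(np.int64) if len(ts.mutations) else np.zeros(n, np.int64)
    return NodeFeatures(span_left, span_right, span, num_mutations)


def compute_site_features(ts: TreeSequenceData) -> SiteFeatures:
    counts = np.bincount(
        ts.mutations.site, minlength=len(ts.sites)
    ).astype(np.int64) if len(ts.mutations) else np.zeros(len(ts.sites),
                                                          np.int64)
    return SiteFeatures(counts)


def _edge_orders(ts: TreeSequenceData):
    """Insertion and removal orders of the incremental sweep.

    Insertion by (left, parent time, parent id, child id); removal by
    (right, -parent time, parent id, child id): children detach before
    their ancestors, keeping subtree counts consistent mid-update.
    """
    e = ts.edges
    pt = ts.nodes.time[e.parent]
    ins = np.lexsort((e.child, e.parent, pt, e.left))
    rem = np.lexsort((e.child, e.parent, -pt, e.right))
    return ins, rem


def compute_mutation_features(ts: TreeSequenceData) -> MutationFeatures:
    """Per-mutation features via one incremental left-to-right tree sweep.

    For each mutation: the number of samples in the subtree below its node
    in the local tree at its site; a plotted time (given, or imputed as the
    midpoint of the branch it sits on; the node's own time at local roots);
    and the depth of its parent-link chain at the site.

    A mutation whose node is not present in the local tree (no parent, no
    samples beneath, not itself a sample) gets inheritor_count 0 and a
    warning record instead of an error.
    """
    n_nodes = len(ts.nodes)
    n_mut = len(ts.mutations)
    e = ts.edges
    is_sample = ts.nodes.is_sample

    parent = np.full(n_nodes, NULL, np.int64)
    count = np.where(is_sample, 1, 0).astype(np.int64)

    inheritor = np.zeros(n_mut, np.int64)
    time_plotted = np.array(ts.mutations.time, np.float64, copy=True)
    warnings: list[str] = []

    # mutations grouped by site, sites by position (table order)
    site_pos = ts.sites.position
    mut_by_site: list[list[int]] = [[] for _ in range(len(ts.sites))]
    for j in range(n_mut):
        mut_by_site[ts.mutations.site[j]].append(j)

    ins, rem = _edge_orders(ts)
    ni, nr = 0, 0
    si = 0
    n_edges = len(e)

    def _propagate(u, delta):
        while u != NULL:
            count[u] += delta
            u = parent[u]

    x = 0.0
    while True:
        # tree transition at x: detach leaving edges, then attach entering
        while nr < n_edges and e.right[rem[nr]] == x:
            i = rem[nr]
            parent[e.child[i]] = NULL
            _propagate(e.parent[i], -count[e.child[i]])
            nr += 1
        while ni < n_edges and e.left[ins[ni]] == x:
            i = ins[ni]
            parent[e.child[i]] = e.parent[i]
            _propagate(e.parent[i], count[e.child[i]])
            ni += 1
        x_next = ts.sequence_length
        if ni < n_edges:
            x_next = min(x_next, e.left[ins[ni]])
        if nr < n_edges:
            x_next = min(x_next, e.right[rem[nr]])
        # visit every site inside the current tree interval [x, x_next)
        while si < len(site_pos) and site_pos[si] < x_next:
            for j in mut_by_site[si]:
                u = int(ts.mutations.node[j])
                inheritor[j] = count[u]
                present = is_sample[u] or count[u] > 0 or parent[u] != NULL
                if not present:
                    inheritor[j] = 0
                    warnings.append(
                        f"mutation {j}: node {u} not in local tree at "
                        f"position {site_pos[si]}"
                    )
                if np.isnan(time_plotted[j]):
                    p = parent[u]
                    if p == NULL:  # local root: no branch above
                        time_plotted[j] = ts.nodes.time[u]
                    else:
                        time_plotted[j] = (
                            ts.nodes.time[u] + ts.nodes.time[p]
                        ) / 2
            si += 1
        if x_next >= ts.sequence_length and si >= len(site_pos):
            break
        x = x_next

    chain_depth = np.zeros(n_mut, np.int64)
    for j in range(n_mut):
        p, d = ts.mutations.parent[j], 0
        while p != NULL:
            d += 1
            p = ts.mutations.parent[p]
        chain_depth[j] = d

    return MutationFeatures(
        position=site_pos[ts.mutations.site] if n_mut else np.empty(0),
        inheritor_count=inheritor,
        time_plotted=time_plotted,
        chain_depth=chain_depth,
        warnings=warnings,
    )


def inheritor_counts_naive(ts: TreeSequenceData) -> np.ndarray:
    """Independent per-site recomputation of inheritor counts (DFS oracle).

    Rebuilds the local tree at each mutated site from scratch and counts
    samples beneath the mutation's node.  O(sites × edges): test/diagnostic
    use only.
    """
    out = np.zeros(len(ts.mutations), np.int64)
    is_sample = ts.nodes.is_sample
    for j in range(len(ts.mutations)):
        pos = ts.sites.position[ts.mutations.site[j]]
        active = (ts.edges.left <= pos) & (pos < ts.edges.right)
        children: dict[int, list[int]] = {}
        for i in np.flatnonzero(active):
            children.setdefault(int(ts.edges.parent[i]), []).append(
                int(ts.edges.child[i])
            )
        stack = [int(ts.mutations.node[j])]
        n = 0
        while stack:
            u = stack.pop()
            if is_sample[u]:
                n += 1
            stack.extend(children.get(u, ()))
        out[j] = n
    return out


# -- the store ----------------------------------------------------------------

_RAW_KEYS = {
    "nodes": ["time", "flags", "population", "individual"],
    "edges": ["left", "right", "parent", "child"],
    "sites": ["position"],
    "mutations": ["site", "node", "parent", "time"],
}
_FEATURE_KEYS = {
    "edges": ["branch_length", "span", "area"],
    "nodes": ["span_left", "span_right", "span", "num_mutations"],
    "mutations": ["position", "inheritor_count", "time_plotted",
                  "chain_depth"],
    "sites": ["num_mutations"],
}
_STRING_KEYS = {"sites": ["ancestral_state"], "mutations": ["derived_state"]}


@dataclass
class BrowseStore:
    """All raw columns + feature columns, keyed ``table/column``, plus
    provenance metadata and summary counts."""

    sequence_length: float
    arrays: dict[str, np.ndarray]
    strings: dict[str, np.ndarray]  # object arrays of str
    counts: dict[str, int]
    metadata: dict

    def __getitem__(self, key: str) -> np.ndarray:
        if key in self.arrays:
            return self.arrays[key]
        return self.strings[key]

    @property
    def num_samples(self) -> int:
        return int(np.count_nonzero(self.arrays["nodes/flags"]
                                    & ts_model.NODE_IS_SAMPLE))

    def equals(self, other: "BrowseStore") -> bool:
        """Equality of all arrays, counts and sequence length; timestamps
        and other provenance metadata are excluded."""
        if self.sequence_length != other.sequence_length:
            return False
        if self.counts != other.counts:
            return False
        if set(self.arrays) != set(other.arrays):
            return False
        for k, a in self.arrays.items():
            if a.dtype != other.arrays[k].dtype:
                return False
            if not np.array_equal(a, other.arrays[k], equal_nan=True):
                return False
        for k, s in self.strings.items():
            if list(s) != list(other.strings[k]):
                return False
        return True


def build_store(ts: TreeSequenceData, source_path: str | None = None
                ) -> BrowseStore:
    """Validate, compute all feature columns, and assemble the store."""
    violations = ts_model.validate(ts)
    if violations:
        raise ValidationFailure(violations)

    ef = compute_edge_features(ts)
    nf = compute_node_spans(ts)
    mf = compute_mutation_features(ts)
    sf = compute_site_features(ts)

    arrays = {
        "nodes/time": ts.nodes.time,
        "nodes/flags": ts.nodes.flags,
        "nodes/population": ts.nodes.population,
        "nodes/individual": ts.nodes.individual,
        "edges/left": ts.edges.left,
        "edges/right": ts.edges.right,
        "edges/parent": ts.edges.parent,
        "edges/child": ts.edges.child,
        "sites/position": ts.sites.position,
        "mutations/site": ts.mutations.site,
        "mutations/node": ts.mutations.node,
        "mutations/parent": ts.mutations.parent,
        "mutations/time": ts.mutations.time,
        "edges/branch_length": ef.branch_length,
        "edges/span": ef.span,
        "edges/area": ef.area,
        "nodes/span_left": nf.span_left,
        "nodes/span_right": nf.span_right,
        "nodes/span": nf.span,
        "nodes/num_mutations": nf.num_mutations,
        "mutations/position": mf.position,
        "mutations/inheritor_count": mf.inheritor_count,
        "mutations/time_plotted": mf.time_plotted,
        "mutations/chain_depth": mf.chain_depth,
        "sites/num_mutations": sf.num_mutations,
    }
    strings = {
        "sites/ancestral_state": ts.sites.ancestral_state,
        "mutations/derived_state": ts.mutations.derived_state,
    }
    counts = {
        "nodes": len(ts.nodes),
        "edges": len(ts.edges),
        "sites": len(ts.sites),
        "mutations": len(ts.mutations),
        "trees": ts_model.num_trees(ts),
    }
    metadata = {
        "format_version": FORMAT_VERSION,
        "source_path": source_path or ts.metadata.get("source_path"),
        "source_uuid": str(uuid.uuid5(
            uuid.NAMESPACE_URL, json.dumps(counts, sort_keys=True)
        )),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "counts": counts,
        "warnings": mf.warnings,
    }
    return BrowseStore(
        sequence_length=float(ts.sequence_length),
        arrays=arrays,
        strings=strings,
        counts=counts,
        metadata=metadata,
    )


def _expected_keys(counts) -> list[str]:
    keys = []
    for table, cols in list(_RAW_KEYS.items()) + list(_FEATURE_KEYS.items()):
        keys += [f"{table}/{c}" for c in cols]
    for table, cols in _STRING_KEYS.items():
        for c in cols:
            keys += [f"{table}/{c}__bytes", f"{table}/{c}__offsets"]
    return keys


def _pack_strings(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Arrow-style packing: concatenated UTF-8 bytes + int64 offsets."""
    encoded = [str(v).encode() for v in values]
    offsets = np.zeros(len(encoded) + 1, np.int64)
    np.cumsum([len(b) for b in encoded], out=offsets[1:])
    data = np.frombuffer(b"".join(encoded), np.uint8).copy()
    return data, offsets


def _unpack_strings(data: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    buf = data.tobytes()
    return np.asarray(
        [buf[offsets[i]:offsets[i + 1]].decode()
         for i in range(len(offsets) - 1)],
        object,
    )


def write_store(store: BrowseStore, path) -> None:
    """Write the store as a single-file zip archive of zstd-compressed
    chunked arrays plus one JSON metadata document (in the root attrs)."""
    import zarr

    zstore = zarr.storage.ZipStore(str(path), mode="w")
    try:
        root = zarr.create_group(store=zstore, attributes={
            "metadata": json.loads(json.dumps(store.metadata)),
            "sequence_length": store.sequence_length,
            "counts": store.counts,
        })
        for key, arr in store.arrays.items():
            a = root.create_array(
                key, shape=arr.shape, dtype=arr.dtype,
                chunks=(max(1, min(len(arr), 1 << 16)),),
            )
            if len(arr):
                a[:] = arr
        for key, values in store.strings.items():
            data, offsets = _pack_strings(values)
            for suffix, arr in (("__bytes", data), ("__offsets", offsets)):
                a = root.create_array(
                    key + suffix, shape=arr.shape, dtype=arr.dtype,
                    chunks=(max(1, min(len(arr), 1 << 20)),),
                )
                if len(arr):
                    a[:] = arr
    finally:
        zstore.close()


def read_store(path) -> BrowseStore:
    """Read a store written by :func:`write_store`.

    Never needs the original tree sequence file.  Raises
    :class:`StoreVersionError` on a format-version mismatch and
    :class:`StoreCorruptionError` naming the first missing key.
    """
    import zarr

    zstore = zarr.storage.ZipStore(str(path), mode="r")
    try:
        root = zarr.open_group(store=zstore, mode="r")
        metadata = dict(root.attrs["metadata"])
        version = metadata.get("format_version")
        if version != FORMAT_VERSION:
            raise StoreVersionError(
                f"store format version {version!r} is not supported "
                f"(expected {FORMAT_VERSION})"
            )
        counts = dict(root.attrs["counts"])
        present = set()

        def walk(g, prefix=""):
            for name, item in g.members():
                full = f"{prefix}{name}"
                if hasattr(item, "members"):
                    walk(item, full + "/")
                else:
                    present.add(full)

        walk(root)
        for key in _expected_keys(counts):
            if key not in present:
                raise StoreCorruptionError(
                    f"store is corrupt: missing array {key!r}"
                )
        arrays, strings = {}, {}
        for table, cols in list(_RAW_KEYS.items()) + list(
                _FEATURE_KEYS.items()):
            for c in cols:
                arrays[f"{table}/{c}"] = root[f"{table}/{c}"][:]
        for table, cols in _STRING_KEYS.items():
            for c in cols:
                strings[f"{table}/{c}"] = _unpack_strings(
                    root[f"{table}/{c}__bytes"][:],
                    root[f"{table}/{c}__offsets"][:],
                )
        return BrowseStore(
            sequence_length=float(root.attrs["sequence_length"]),
            arrays=arrays,
            strings=strings,
            counts=counts,
            metadata=metadata,
        )
    finally:
        zstore.close()
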