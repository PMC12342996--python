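"""Succinct tree sequence data model: tables, validation, loading.

An ancestral recombination graph (ARG) is encoded as four tables — nodes,
edges, sites and mutations — plus a sequence length, following the tskit
table conventions.  All genome coordinates are 0-based, half-open
``[left, right)``.  Missing integer references are ``-1``; unknown mutation
times are NaN.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NULL = -1

#: Node flag bit marking a sample node (tskit convention).
NODE_IS_SAMPLE = 1


class FormatError(ValueError):
    """Raised when an input file cannot be read as a tree sequence."""


class ParseError(ValueError):
    """Raised on malformed text-table input; carries the offending line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


@dataclass(frozen=True)
class Violation:
    """One invariant failure: which rule, in which table, at which row."""

    kind: str
    table: str
    row: int

    def __str__(self):
        return f"{self.kind} ({self.table} table, row {self.row})"


def _col(values, dtype):
    return np.ascontiguousarray(np.asarray(values, dtype=dtype))


@dataclass
class NodeTable:
    time: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    flags: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    population: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    individual: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __len__(self):
        return len(self.time)

    @property
    def is_sample(self) -> np.ndarray:
        return (self.flags & NODE_IS_SAMPLE) != 0


@dataclass
class EdgeTable:
    left: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    right: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    parent: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    child: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __len__(self):
        return len(self.left)


@dataclass
class SiteTable:
    position: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))
    ancestral_state: np.ndarray = field(
        default_factory=lambda: np.empty(0, object)
    )

    def __len__(self):
        return len(self.position)


@dataclass
class MutationTable:
    site: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    node: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    derived_state: np.ndarray = field(default_factory=lambda: np.empty(0, object))
    parent: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    time: np.ndarray = field(default_factory=lambda: np.empty(0, np.float64))

    def __len__(self):
        return len(self.site)


@dataclass
class TreeSequenceData:
    """The four ARG tables plus sequence length and provenance metadata."""

    sequence_length: float
    nodes: NodeTable = field(default_factory=NodeTable)
    edges: EdgeTable = field(default_factory=EdgeTable)
    sites: SiteTable = field(default_factory=SiteTable)
    mutations: MutationTable = field(default_factory=MutationTable)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.nodes
        self.nodes = NodeTable(
            _col(n.time, np.float64),
            _col(n.flags, np.int64),
            _col(n.population, np.int64),
            _col(n.individual, np.int64),
        )
        e = self.edges
        self.edges = EdgeTable(
            _col(e.left, np.float64),
            _col(e.right, np.float64),
            _col(e.parent, np.int64),
            _col(e.child, np.int64),
        )
        s = self.sites
        self.sites = SiteTable(
            _col(s.position, np.float64),
            np.asarray([str(x) for x in s.ancestral_state], object),
        )
        m = self.mutations
        self.mutations = MutationTable(
            _col(m.site, np.int64),
            _col(m.node, np.int64),
            np.asarray([str(x) for x in m.derived_state], object),
            _col(m.parent, np.int64),
            _col(m.time, np.float64),
        )
        self.sort_edges()
        self.sort_mutations()

    def sort_edges(self):
        """Sort edges into canonical order: (left, parent time, parent, child).

        Input tables need not be pre-sorted; sorting here makes downstream
        sweeps deterministic.  Records the fact in metadata.
        """
        e = self.edges
        if len(e) == 0:
            return
        pt = np.zeros(len(e))
        valid = (e.parent >= 0) & (e.parent < len(self.nodes))
        pt[valid] = self.nodes.time[e.parent[valid]]
        order = np.lexsort((e.child, e.parent, pt, e.left))
        if not np.array_equal(order, np.arange(len(e))):
            self.edges = EdgeTable(
                e.left[order], e.right[order], e.parent[order], e.child[order]
            )
            self.metadata.setdefault("edges_resorted", True)

    def sort_mutations(self):
        """Stable-sort mutations by site, remapping parent links.

        Matches the tskit requirement that mutations at one site are
        contiguous; stability keeps parents before children.
        """
        m = self.mutations
        if len(m) == 0:
            return
        order = np.argsort(m.site, kind="stable")
        if np.array_equal(order, np.arange(len(m))):
            return
        inverse = np.empty(len(m), np.int64)
        inverse[order] = np.arange(len(m))
        new_parent = np.where(
            m.parent[order] == NULL, NULL, inverse[m.parent[order]]
        )
        self.mutations = MutationTable(
            m.site[order], m.node[order], m.derived_state[order],
            new_parent, m.time[order],
        )
        self.metadata.setdefault("mutations_resorted", True)

    def equals(self, other: "TreeSequenceData") -> bool:
        """Field-by-field table equality (metadata excluded)."""
        if self.sequence_length != other.sequence_length:
            return False
        for name in ("nodes", "edges", "sites", "mutations"):
            a, b = getattr(self, name), getattr(other, name)
            for f in dataclasses.fields(a):
                x, y = getattr(a, f.name), getattr(b, f.name)
                if len(x) != len(y):
                    return False
                if x.dtype == object:
                    if not all(p == q for p, q in zip(x, y)):
                        return False
                elif not np.array_equal(x, y, equal_nan=True):
                    return False
        return True

    @property
    def num_samples(self) -> int:
        return int(np.count_nonzero(self.nodes.is_sample))

    @property
    def samples(self) -> np.ndarray:
        return np.flatnonzero(self.nodes.is_sample)


# -- validation ---------------------------------------------------------------


def validate(ts: TreeSequenceData) -> list[Violation]:
    """Check every table invariant; return a list of violations (never raise).

    Each violation carries a stable ``kind`` string, the table name and the
    row index.  A row that fails one rule is not re-checked against rules
    that depend on it (e.g. an edge with an out-of-range parent id is not
    additionally checked for time ordering), so a single-field corruption
    yields a single violation.
    """
    v: list[Violation] = []
    n_nodes = len(ts.nodes)
    L = ts.sequence_length

    for i in range(n_nodes):
        t = ts.nodes.time[i]
        if not np.isfinite(t) or t < 0:
            v.append(Violation("node_time", "nodes", i))

    e = ts.edges
    edge_ok = np.ones(len(e), bool)
    for i in range(len(e)):
        if not (0 <= e.parent[i] < n_nodes and 0 <= e.child[i] < n_nodes):
            v.append(Violation("edge_node_ref", "edges", i))
            edge_ok[i] = False
        elif e.parent[i] == e.child[i]:
            v.append(Violation("edge_self_loop", "edges", i))
            edge_ok[i] = False
        elif not (0 <= e.left[i] < e.right[i] <= L):
            v.append(Violation("edge_interval", "edges", i))
            edge_ok[i] = False
        elif not ts.nodes.time[e.parent[i]] > ts.nodes.time[e.child[i]]:
            v.append(Violation("edge_time_order", "edges", i))
            edge_ok[i] = False
    # per (parent, child) pair, intervals must not overlap
    pairs: dict[tuple[int, int], list[tuple[float, float, int]]] = {}
    for i in np.flatnonzero(edge_ok):
        pairs.setdefault((int(e.parent[i]), int(e.child[i])), []).append(
            (float(e.left[i]), float(e.right[i]), int(i))
        )
    for ivals in pairs.values():
        ivals.sort()
        for (l0, r0, _), (l1, _, i1) in zip(ivals, ivals[1:]):
            if l1 < r0:
                v.append(Violation("edge_overlap", "edges", i1))

    s = ts.sites
    site_ok = np.ones(len(s), bool)
    for i in range(len(s)):
        if not (0 <= s.position[i] < L):
            v.append(Violation("site_position", "sites", i))
            site_ok[i] = False
        elif i > 0 and site_ok[i - 1] and not s.position[i] > s.position[i - 1]:
            v.append(Violation("site_order", "sites", i))

    m = ts.mutations
    for i in range(len(m)):
        if not (0 <= m.site[i] < len(s)):
            v.append(Violation("mutation_site_ref", "mutations", i))
        elif not (0 <= m.node[i] < n_nodes):
            v.append(Violation("mutation_node_ref", "mutations", i))
        elif m.parent[i] != NULL:
            p = m.parent[i]
            if not (0 <= p < len(m)) or p >= i:
                v.append(Violation("mutation_parent_order", "mutations", i))
            elif m.site[p] != m.site[i]:
                v.append(Violation("mutation_parent_site", "mutations", i))
    return v


# -- num_trees ----------------------------------------------------------------


def breakpoints(ts: TreeSequenceData) -> np.ndarray:
    """Sorted union of {0, sequence_length} with all edge lefts and rights."""
    return np.unique(
        np.concatenate(
            [[0.0, ts.sequence_length], ts.edges.left, ts.edges.right]
        )
    )


def num_trees(ts: TreeSequenceData) -> int:
    """Number of local trees: intervals of the breakpoint partition.

    Edge-free gaps count as (empty) trees, matching how a browser must tile
    the genome axis.  An ARG with no edges has zero trees.
    """
    if len(ts.edges) == 0:
        return 0
    return len(breakpoints(ts)) - 1


# -- standard format ----------------------------------------------------------


def load_tree_sequence(path) -> TreeSequenceData:
    """Load a tskit ``.trees`` file into a :class:`TreeSequenceData`."""
    import tskit

    path = Path(path)
    try:
        tsk = tskit.load(str(path))
    except Exception as err:  # tskit raises various kinds on bad input
        raise FormatError(f"cannot read tree sequence file {path}: {err}") from err
    if tsk.num_nodes == 0:
        raise FormatError(f"{path}: empty node table")
    t = tsk.tables
    mut_time = np.array(t.mutations.time, np.float64, copy=True)
    mut_time[tskit.is_unknown_time(t.mutations.time)] = np.nan
    ts = TreeSequenceData(
        sequence_length=float(tsk.sequence_length),
        nodes=NodeTable(
            t.nodes.time,
            t.nodes.flags.astype(np.int64),
            t.nodes.population.astype(np.int64),
            t.nodes.individual.astype(np.int64),
        ),
        edges=EdgeTable(t.edges.left, t.edges.right, t.edges.parent, t.edges.child),
        sites=SiteTable(
            t.sites.position,
            np.asarray([s.ancestral_state for s in t.sites], object),
        ),
        mutations=MutationTable(
            t.mutations.site,
            t.mutations.node,
            np.asarray([m.derived_state for m in t.mutations], object),
            t.mutations.parent,
            mut_time,
        ),
        metadata={"source_path": str(path)},
    )
    return ts


def to_tskit(ts: TreeSequenceData):
    """Convert to a ``tskit.TreeSequence`` (for writing ``.trees`` files)."""
    import tskit

    tables = tskit.TableCollection(sequence_length=ts.sequence_length)
    for i in range(len(ts.nodes)):
        tables.nodes.add_row(
            flags=int(ts.nodes.flags[i]),
            time=float(ts.nodes.time[i]),
            population=int(ts.nodes.population[i]),
            individual=int(ts.nodes.individual[i]),
        )
    for i in range(len(ts.edges)):
        tables.edges.add_row(
            left=float(ts.edges.left[i]),
            right=float(ts.edges.right[i]),
            parent=int(ts.edges.parent[i]),
            child=int(ts.edges.child[i]),
        )
    for i in range(len(ts.sites)):
        tables.sites.add_row(
            position=float(ts.sites.position[i]),
            ancestral_state=str(ts.sites.ancestral_state[i]),
        )
    for i in range(len(ts.mutations)):
        t = ts.mutations.time[i]
        tables.mutations.add_row(
            site=int(ts.mutations.site[i]),
            node=int(ts.mutations.node[i]),
            derived_state=str(ts.mutations.derived_state[i]),
            parent=int(ts.mutations.parent[i]),
            time=tskit.UNKNOWN_TIME if np.isnan(t) else float(t),
        )
    tables.sort()
    return tables.tree_sequence()


def write_tree_sequence(ts: TreeSequenceData, path) -> None:
    to_tskit(ts).dump(str(path))


# -- text dialect -------------------------------------------------------------

_TEXT_COLUMNS = {
    "nodes": ["time", "flags", "population", "individual"],
    "edges": ["left", "right", "parent", "child"],
    "sites": ["position", "ancestral_state"],
    "mutations": ["site", "node", "derived_state", "parent", "time"],
}
_STRING_COLUMNS = {"ancestral_state", "derived_state"}
_INT_COLUMNS = {
    "flags", "population", "individual", "parent", "child", "site", "node",
}


def _read_text_table(path, table: str) -> dict[str, np.ndarray]:
    path = Path(path)
    want = _TEXT_COLUMNS[table]
    with open(path) as fh:
        header = fh.readline().split()
        for col in want:
            if col not in header:
                raise ParseError(
                    f"{table} table missing column {col!r}", path, 1
                )
        idx = {c: header.index(c) for c in want}
        out: dict[str, list] = {c: [] for c in want}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < len(header):
                raise ParseError(
                    f"{table} table: expected {len(header)} fields, "
                    f"got {len(fields)}", path, lineno,
                )
            for c in want:
                raw = fields[idx[c]]
                if c in _STRING_COLUMNS:
                    out[c].append(raw)
                    continue
                try:
                    val = float(raw)
                except ValueError:
                    raise ParseError(
                        f"{table} table: non-numeric value {raw!r} "
                        f"in column {c!r}", path, lineno,
                    ) from None
                out[c].append(val)
    arrays = {}
    for c in want:
        if c in _STRING_COLUMNS:
            arrays[c] = np.asarray(out[c], object)
        elif c in _INT_COLUMNS:
            a = np.asarray(out[c], np.float64)
            arrays[c] = np.where(np.isnan(a), NULL, a).astype(np.int64)
        else:
            arrays[c] = np.asarray(out[c], np.float64)
    return arrays


def load_text_tables(
    node_path, edge_path, site_path, mutation_path, sequence_length: float
) -> TreeSequenceData:
    """Read the four-file TSV dialect (header rows; missing = -1 or NaN).

    Parsing is separate from validation: structurally well-formed but
    semantically invalid rows (e.g. left > right) load fine and are flagged
    by :func:`validate`.
    """
    n = _read_text_table(node_path, "nodes")
    e = _read_text_table(edge_path, "edges")
    s = _read_text_table(site_path, "sites")
    m = _read_text_table(mutation_path, "mutations")
    return TreeSequenceData(
        sequence_length=float(sequence_length),
        nodes=NodeTable(n["time"], n["flags"], n["population"], n["individual"]),
        edges=EdgeTable(e["left"], e["right"], e["parent"], e["child"]),
        sites=SiteTable(s["position"], s["ancestral_state"]),
        mutations=MutationTable(
            m["site"], m["node"], m["derived_state"], m["parent"], m["time"]
        ),
    )


def write_text_tables(ts: TreeSequenceData, directory) -> dict[str, Path]:
    """Write the text dialect; returns the four paths keyed by table name."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for table in _TEXT_COLUMNS:
        cols = _TEXT_COLUMNS[table]
        tab = getattr(ts, table)
        path = directory / f"{table}.tsv"
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for i in range(len(tab)):
                row = []
                for c in cols:
                    val = getattr(tab, c)[i]
                    if c in _STRING_COLUMNS:
                        row.append(str(val))
                    elif c in _INT_COLUMNS:
                        row.append(str(int(val)))
                    else:
                        row.append(repr(float(val)))
                fh.write("\t".join(row) + "\n")
        paths[table] = path
    return paths
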